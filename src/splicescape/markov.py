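"""Homogeneous fourth-order Markov models of nucleotide composition.

Two models are fit per species — one on intron sequences (P_I) and one on
the whole genome (P_G) — and the per-nucleotide log-odds
``log2(P_I(s)/P_G(s)) / len(s)`` measures intronic compositional bias,
which at order 4 is essentially a 5-mer statistic.  The first four
positions of a sequence are scored with ramp-up models of orders 0-3 so
that every sequence of length >= 1 has a well-defined probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pwm import ALPHABET, encode

ORDER = 4
N_CONTEXTS = 4 ** ORDER  # 256


@dataclass
class MarkovModel:
    """Fourth-order nucleotide Markov chain with low-order ramp tables.

    ``cond`` is the 256 x 4 table P(base | preceding 4-mer); ``ramps[o]``
    is the 4**o x 4 table used for position o (0-based) of a sequence.
    """

    cond: np.ndarray
    ramps: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond, dtype=float)
        if self.cond.shape != (N_CONTEXTS, 4):
            raise ValueError("cond must be 256 x 4")
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("conditional rows must sum to 1")
        if not self.ramps:
            self.ramps = self._ramps_from_stationary()
        for o, t in enumerate(self.ramps):
            if t.shape != (4 ** o, 4):
                raise ValueError(f"ramp table {o} has wrong shape {t.shape}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(cls, seqs: list[str], pseudo_count: float = 0.5) -> "MarkovModel":
        """Maximum-likelihood fit (with additive smoothing) from sequences.

        Ramp tables for the first four positions are derived from the
        stationary law of the fitted chain rather than from the (few)
        sequence starts.
        """
        counts = np.full((N_CONTEXTS, 4), pseudo_count)
        for s in seqs:
            codes = encode(s)
            n = len(codes)
            if n < ORDER + 1:
                continue
            valid = codes >= 0
            ctx = 0
            run = 0
            for i in range(n):
                if not valid[i]:
                    run = 0
                    ctx = 0
                    continue
                if run >= ORDER:
                    counts[ctx, codes[i]] += 1
                run += 1
                ctx = (ctx * 4 + int(codes[i])) % N_CONTEXTS
        cond = counts / counts.sum(axis=1, keepdims=True)
        return cls(cond=cond)

    @classmethod
    def iid(cls, probs: np.ndarray) -> "MarkovModel":
        """Zeroth-order (i.i.d.) composition expressed as an order-4 model."""
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        cond = np.tile(probs, (N_CONTEXTS, 1))
        ramps = [np.tile(probs, (4 ** o, 1)) for o in range(ORDER)]
        return cls(cond=cond, ramps=ramps)

    @classmethod
    def gc_biased(cls, gc: float) -> "MarkovModel":
        """i.i.d. model with the given G+C fraction, strand-symmetric."""
        at = (1.0 - gc) / 2.0
        return cls.iid(np.array([at, gc / 2.0, gc / 2.0, at]))

    # -- stationary statistics --------------------------------------------

    def stationary_context_probs(self, tol: float = 1e-12, max_iter: int = 2000) -> np.ndarray:
        """Stationary distribution over 4-mer contexts (power iteration)."""
        pi = np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)
        for _ in range(max_iter):
            nxt = np.zeros(N_CONTEXTS)
            # context abcd --(e)--> bcde
            for b in range(4):
                # new context = (old % 64) * 4 + b
                dest = (np.arange(N_CONTEXTS) % (4 ** (ORDER - 1))) * 4 + b
                np.add.at(nxt, dest, pi * self.cond[:, b])
            if np.abs(nxt - pi).sum() < tol:
                pi = nxt
                break
            pi = nxt
        return pi / pi.sum()

    def kmer_probs(self, k: int = 5) -> np.ndarray:
        """Stationary probabilities of all 4**k k-mers (k >= ORDER)."""
        if k < ORDER:
            raise ValueError("k must be >= model order")
        pi = self.stationary_context_probs()
        probs = pi.copy()
        cur_k = ORDER
        while cur_k < k:
            n = len(probs)
            ext = np.zeros(n * 4)
            ctx = np.arange(n) % N_CONTEXTS  # trailing 4-mer of each k-mer
            for b in range(4):
                ext[np.arange(n) * 4 + b] = probs * self.cond[ctx, b]
            probs = ext
            cur_k += 1
        return probs

    def _ramps_from_stationary(self) -> list[np.ndarray]:
        """Derive order 0-3 ramp tables by marginalising the stationary law."""
        pi4 = self.stationary_context_probs()  # P(4-mer)
        ramps: list[np.ndarray] = []
        for o in range(ORDER):
            # stationary (o+1)-mer law: sum pi4 over 4-mers sharing the suffix,
            # then condition on the length-o prefix
            jm = np.zeros(4 ** (o + 1))
            idx = np.arange(N_CONTEXTS) % (4 ** (o + 1))
            np.add.at(jm, idx, pi4)
            jm = jm.reshape(4 ** o, 4)
            rows = jm.sum(axis=1, keepdims=True)
            rows = np.where(rows <= 0, 1.0, rows)
            table = jm / rows
            ramps.append(table)
        return ramps

    # -- scoring and sampling ----------------------------------------------

    def log2_prob(self, seq: str) -> float:
        """log2 probability of a sequence, ramping through orders 0-3.

        Ambiguous bases contribute 0 (and reset the context).
        """
        codes = encode(seq)
        if len(codes) == 0:
            raise ValueError("empty sequence")
        total = 0.0
        run = 0  # length of current unambiguous run
        ctx = 0
        for b in codes:
            if b < 0:
                run = 0
                ctx = 0
                continue
            o = min(run, ORDER)
            table = self.cond if o == ORDER else self.ramps[o]
            total += np.log2(table[ctx % (4 ** o), b])
            run += 1
            ctx = (ctx * 4 + b) % N_CONTEXTS
        return float(total)

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Sample a sequence, starting from the ramp tables."""
        return self.sample_many([length], rng)[0]

    def sample_many(self, lengths: list[int], rng: np.random.Generator) -> list[str]:
        """Sample several sequences; a single pass of pre-drawn uniforms."""
        total = int(sum(lengths))
        cum = np.cumsum(self.cond, axis=1)
        ramp_cum = [np.cumsum(t, axis=1) for t in self.ramps]
        u = rng.random(total)
        out: list[str] = []
        pos = 0
        for L in lengths:
            chars = []
            ctx = 0
            for i in range(L):
                o = min(i, ORDER)
                row = cum[ctx] if o == ORDER else ramp_cum[o][ctx % (4 ** o)]
                b = int(np.searchsorted(row, u[pos], side="right"))
                b = min(b, 3)
                pos += 1
                chars.append(ALPHABET[b])
                ctx = (ctx * 4 + b) % N_CONTEXTS
            out.append("".join(chars))
        return out
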