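"""Position weight matrices for splice-site and branch-point motifs.

A :class:`PWMProfile` stores per-position base frequencies ``f[k, j]``
(rows A, C, G, T; columns are motif positions) together with a background
mononucleotide distribution ``F``.  Log-odds entries are
``log2((f + eps) / (F + eps))`` with a small pseudo-count ``eps``; a motif
segment is scored by summing the log-odds entries of its bases, and the
information content of a profile is its relative entropy against the
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: canonical row order of every frequency matrix in this package
ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_PSEUDO_COUNT = 1e-4

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as integer codes A=0 C=1 G=2 T=3; other -> -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, b in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(b, -1)
    return out


@dataclass
class PWMProfile:
    """Per-position base frequencies plus background, scored as log-odds.

    Parameters
    ----------
    freqs:
        4 x w column-stochastic matrix (rows A, C, G, T).
    background:
        Background base distribution (length 4, sums to 1).
    pseudo_count:
        Pseudo-count added to both numerator and denominator of the
        log-odds ratio.
    offsets:
        Position of each column relative to the biological anchor
        (junction for splice sites, motif start for BP); optional.
    name:
        Free-text label.
    """

    freqs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    offsets: tuple[int, ...] | None = None
    name: str = ""
    _lo_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._lo_cache = None
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != 4:
            raise ValueError("freqs must be a 4 x w matrix (rows A, C, G, T)")
        if self.background.shape != (4,):
            raise ValueError("background must have length 4")
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM columns must sum to 1, got {colsums}")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.offsets is not None and len(self.offsets) != self.width:
            raise ValueError("offsets length must equal PWM width")

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x w matrix of log2((f + eps)/(F + eps)) entries (cached)."""
        if self._lo_cache is None:
            eps = self.pseudo_count
            self._lo_cache = np.log2(
                (self.freqs + eps) / (self.background[:, None] + eps))
        return self._lo_cache

    def score(self, segment: str) -> float:
        """Log-odds score (bits) of a segment of length ``width``.

        Ambiguous bases (anything outside ACGT) contribute 0 for their
        column.
        """
        if len(segment) != self.width:
            raise ValueError(
                f"segment length {len(segment)} != PWM width {self.width}"
            )
        lo = self.log_odds()
        codes = encode(segment)
        valid = codes >= 0
        cols = np.nonzero(valid)[0]
        return float(lo[codes[valid], cols].sum())

    def score_many(self, codes: np.ndarray) -> np.ndarray:
        """Score an (n, w) array of integer-encoded segments; -1 codes add 0."""
        lo = self.log_odds()
        n, w = codes.shape
        if w != self.width:
            raise ValueError("segment width mismatch")
        out = np.zeros(n)
        for j in range(w):
            c = codes[:, j]
            ok = c >= 0
            out[ok] += lo[c[ok], j]
        return out

    def information_content(self) -> float:
        """Relative entropy (bits) of the profile against its background.

        Under positional independence the relative entropy over the full
        sequence space factorises into a per-column sum
        ``sum_j sum_k f[k,j] log2(f[k,j] / F[k])``.  Terms with
        ``f[k,j] == 0`` contribute 0; a zero background entry is guarded
        with the pseudo-count.
        """
        f = self.freqs
        F = self.background[:, None].repeat(self.width, axis=1)
        F = np.where(F <= 0.0, self.pseudo_count, F)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0.0, f * np.log2(np.where(f > 0.0, f, 1.0) / F), 0.0)
        return float(terms.sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[k] for k in self.freqs.argmax(axis=0))

    def consensus_score(self) -> float:
        """Sum over columns of the maximal log-odds entry."""
        return float(self.log_odds().max(axis=0).sum())

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        """Draw n motif instances column-independently from the frequencies."""
        cols = [rng.choice(4, size=n, p=self.freqs[:, j] / self.freqs[:, j].sum())
                for j in range(self.width)]
        mat = np.stack(cols, axis=1)
        return ["".join(ALPHABET[k] for k in row) for row in mat]

    def with_background(self, background: np.ndarray) -> "PWMProfile":
        return replace(self, background=np.asarray(background, dtype=float))

    # -- exchange format: TSV with a header row of position offsets --------

    def to_tsv(self, path: str | Path) -> None:
        offs = self.offsets if self.offsets is not None else tuple(range(self.width))
        with open(path, "w") as fh:
            if self.name:
                fh.write(f"# {self.name}\n")
            fh.write("base\t" + "\t".join(str(o) for o in offs) + "\n")
            for k, b in enumerate(ALPHABET):
                fh.write(b + "\t" + "\t".join(f"{v:.6g}" for v in self.freqs[k]) + "\n")
            fh.write("background\t" + "\t".join(f"{v:.6g}" for v in self.background[:1].repeat(self.width)) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, background: np.ndarray | None = None,
                 pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> "PWMProfile":
        rows: dict[str, list[float]] = {}
        offsets: tuple[int, ...] | None = None
        name = ""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    name = line.lstrip("# ").strip()
                    continue
                parts = line.split("\t")
                if parts[0] == "base":
                    try:
                        offsets = tuple(int(x) for x in parts[1:])
                    except ValueError:
                        offsets = None
                    continue
                if parts[0] == "background":
                    continue
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        freqs = np.array([rows[b] for b in ALPHABET])
        bg = UNIFORM_BACKGROUND.copy() if background is None else background
        return cls(freqs=freqs, background=bg, pseudo_count=pseudo_count,
                   offsets=offsets, name=name)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str],
                       background: np.ndarray | None = None,
                       pseudo_count: float = DEFAULT_PSEUDO_COUNT,
                       offsets: Sequence[int] | None = None,
                       name: str = "") -> "PWMProfile":
        """Empirical position-frequency matrix from equal-length sequences.

        Ambiguous bases are ignored per column (frequencies renormalised
        over observed ACGT counts).
        """
        seqs = list(seqs)
        if not seqs:
            raise ValueError("no sequences supplied")
        w = len(seqs[0])
        counts = np.zeros((4, w))
        for s in seqs:
            if len(s) != w:
                raise ValueError("sequences must have equal length")
            codes = encode(s)
            for j, c in enumerate(codes):
                if c >= 0:
                    counts[c, j] += 1
        colsums = counts.sum(axis=0)
        if np.any(colsums == 0):
            raise ValueError("a column has no unambiguous bases")
        freqs = counts / colsums
        bg = UNIFORM_BACKGROUND.copy() if background is None else background
        return cls(freqs=freqs, background=bg, pseudo_count=pseudo_count,
                   offsets=tuple(offsets) if offsets is not None else None,
                   name=name)


def genome_background(seqs: Iterable[str]) -> np.ndarray:
    """Strand-symmetric genome-wide mononucleotide frequencies.

    Counts both strands (equivalently, averages complementary bases) so the
    background carries no strand information.
    """
    counts = np.zeros(4)
    for s in seqs:
        codes = encode(s)
        codes = codes[codes >= 0]
        counts += np.bincount(codes, minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases in background sequences")
    # strand symmetrisation: A<->T, C<->G
    sym = np.array([counts[0] + counts[3], counts[1] + counts[2],
                    counts[2] + counts[1], counts[3] + counts[0]]) / (2 * total)
    return sym
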