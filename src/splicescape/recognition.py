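"""Decomposition of short-intron recognition accuracy into feature shares.

For each real short intron, every candidate donor/acceptor dinucleotide
pair in a window around the true intron (canonical GY-AG or AT-AC pairing,
implied length within the short-intron range) is scored with a chosen
subset of the five features, always including both splice sites.  The
recognition accuracy Ac of a feature subset is the fraction of introns
whose true boundaries win the argmax; the transformed accuracy
``TAc = -log2(1 - Ac)`` turns accuracy gains into additive bits.  The
contribution of BP / length / composition is the (non-negative) TAc gain
of adding that feature to the splice sites; the information deficit is the
gap between the TAc of 98% accuracy and the best subset's TAc.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intronset import IntronRecord
from .scores import SpeciesProfiles, length_score
from .signals import find_ppt, scan_bp

logger = logging.getLogger(__name__)

FEATURES_EXTRA = ("BP", "length", "composition")

ACCURACY_TARGET = 0.98
NECESSARY_AMOUNT = -math.log2(1.0 - ACCURACY_TARGET)  # TAc of 98% accuracy

_PAIR_RULE = {"GT": "AG", "GC": "AG", "AT": "AC"}


def transformed_accuracy(ac: float, cap: float = NECESSARY_AMOUNT) -> float:
    """TAc = -log2(1 - Ac); Ac = 1 saturates at the necessary amount."""
    if not 0.0 <= ac <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if ac >= 1.0:
        return cap
    return -math.log2(1.0 - ac)


@dataclass
class CandidatePair:
    """One candidate splice pair within an intron's evaluation region.

    ``donor`` / ``acceptor_end`` are region-local indices: the candidate
    intron is ``region[donor:acceptor_end]``.
    """

    donor: int
    acceptor_end: int
    subtype: str
    is_true: bool = False
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.acceptor_end - self.donor


def evaluation_region(rec: IntronRecord, margin: int = 100) -> tuple[str, int, int]:
    """(region, true donor index, true acceptor end index) for one intron.

    The region extends up to ``margin`` nt into each exon flank; shorter
    flanks truncate it with a warning.
    """
    up = rec.upstream_exon_flank[-margin:]
    down = rec.downstream_exon_flank[:margin]
    if len(up) < margin or len(down) < margin:
        logger.debug("intron %s: margins truncated to %d/%d nt",
                     rec.intron_id, len(up), len(down))
    region = up + rec.sequence + down
    return region, len(up), len(up) + rec.length


def enumerate_candidates(region: str, true_donor: int, true_acceptor_end: int,
                         length_range: tuple[int, int]) -> list[CandidatePair]:
    """All canonical candidate pairs within the region, true pair marked.

    Donor dinucleotides GT/GC pair with acceptor AG, and AT with AC; the
    implied intron length must fall within ``length_range`` (inclusive).
    Candidates are ordered by (donor, acceptor) position.
    """
    lo, hi = length_range
    region = region.upper()
    n = len(region)
    donors: dict[str, list[int]] = {"GT": [], "GC": [], "AT": []}
    acceptors: dict[str, list[int]] = {"AG": [], "AC": []}
    for i in range(n - 1):
        di = region[i:i + 2]
        if di in donors:
            donors[di].append(i)
        if di in acceptors:
            acceptors[di].append(i + 2)  # end index (exclusive)
    out: list[CandidatePair] = []
    for ddi, positions in donors.items():
        adi = _PAIR_RULE[ddi]
        ends = acceptors[adi]
        for p in positions:
            for q in ends:
                if lo <= q - p <= hi:
                    out.append(CandidatePair(
                        donor=p, acceptor_end=q, subtype=f"{ddi}-{adi}",
                        is_true=(p == true_donor and q == true_acceptor_end)))
    out.sort(key=lambda c: (c.donor, c.acceptor_end))
    return out


class _CompositionPrefix:
    """O(1) fourth-order Markov log-probabilities of region substrings.

    For a substring [p, q) the full-order terms at positions p+4..q-1 use
    the same context inside the region as inside the substring, so they
    come from a prefix sum; only the four ramp positions are evaluated per
    candidate.  Falls back to the scalar path when the region contains
    ambiguous bases.
    """

    def __init__(self, region: str, model) -> None:
        from .pwm import encode

        self.model = model
        self.region = region
        codes = encode(region)
        self.codes = codes
        self.ok = bool((codes >= 0).all()) and len(codes) >= 5
        if not self.ok:
            return
        c = codes
        ctx = c[:-4] * 64 + c[1:-3] * 16 + c[2:-2] * 4 + c[3:-1]
        terms = np.zeros(len(c))
        terms[4:] = np.log2(model.cond)[ctx, c[4:]]
        self.prefix = np.concatenate([[0.0], np.cumsum(terms)])
        self.log_ramps = [np.log2(t) for t in model.ramps]

    def log2_prob(self, p: int, q: int) -> float:
        if not self.ok:
            return self.model.log2_prob(self.region[p:q])
        c = self.codes
        total = 0.0
        ctx = 0
        for j in range(min(4, q - p)):
            total += self.log_ramps[j][ctx, c[p + j]]
            ctx = ctx * 4 + int(c[p + j])
        if q - p > 4:
            total += float(self.prefix[q] - self.prefix[p + 4])
        return total


def score_candidates(candidates: list[CandidatePair], region: str,
                     profiles: SpeciesProfiles) -> None:
    """Fill each candidate's five feature scores in place.

    Splice-site windows that would run off the region score 0 for the
    missing part (PWM columns outside the region are skipped via N
    padding).  BP and PPT are recomputed on the candidate's own implied
    intron; since their search windows are anchored at the 3' end, results
    are cached per acceptor position (and per length for introns shorter
    than the windows).
    """
    region = region.upper()
    n = len(region)
    comp_i = _CompositionPrefix(region, profiles.intron_markov)
    comp_g = _CompositionPrefix(region, profiles.genome_markov)
    donor_scores: dict[int, float] = {}
    acceptor_scores: dict[int, float] = {}
    bp_cache: dict[tuple[int, int], float] = {}
    for cand in candidates:
        p, q = cand.donor, cand.acceptor_end
        if p not in donor_scores:
            donor_scores[p] = profiles.donor_pwm.score(
                _padded(region, p - 3, p + 6, n))
        if q not in acceptor_scores:
            acceptor_scores[q] = profiles.acceptor_pwm.score(
                _padded(region, q - 13, q + 1, n))
        key = (q, min(q - p, 102))
        if key not in bp_cache:
            intron_seq = region[p:q]
            ppt = find_ppt(intron_seq)
            bp = scan_bp(intron_seq, profiles.core_bp, ppt=ppt)
            bp_cache[key] = (profiles.bp_profile.score(bp.heptamer)
                             if bp.present and len(bp.heptamer) == 7 else 0.0)
        cand.scores = {
            "5ss": donor_scores[p],
            "3ss": acceptor_scores[q],
            "BP": bp_cache[key],
            "length": length_score(cand.length, profiles.length_model),
            "composition": (comp_i.log2_prob(p, q) -
                            comp_g.log2_prob(p, q)) / (q - p),
        }


def _padded(region: str, start: int, end: int, n: int) -> str:
    pre = "N" * max(0, -start)
    post = "N" * max(0, end - n)
    return pre + region[max(0, start):min(end, n)] + post


def prepare_regions(introns: Sequence[IntronRecord],
                    profiles: SpeciesProfiles,
                    length_range: tuple[int, int],
                    margin: int = 100) -> list[list[CandidatePair]]:
    """Enumerate and score the candidate sets of every intron once."""
    prepared = []
    for rec in introns:
        region, td, ta = evaluation_region(rec, margin=margin)
        cands = enumerate_candidates(region, td, ta, length_range)
        if not any(c.is_true for c in cands):
            # true pair outside the length range or non-canonical; count as a
            # guaranteed miss rather than dropping the intron
            cands.append(CandidatePair(donor=td, acceptor_end=ta,
                                       subtype=rec.subtype, is_true=True))
            cands.sort(key=lambda c: (c.donor, c.acceptor_end))
        score_candidates(cands, region, profiles)
        prepared.append(cands)
    return prepared


def accuracy_from_prepared(prepared: list[list[CandidatePair]],
                           feature_subset: Sequence[str]) -> float:
    """Ac of a feature subset over pre-scored candidate sets.

    The predicted pair is the highest splicing score; ties resolve to the
    candidate with the 5'-most donor, then the 5'-most acceptor (candidate
    lists are position-sorted, so the first maximal candidate wins).
    """
    subset = list(feature_subset)
    if not {"5ss", "3ss"} <= set(subset):
        raise ValueError("feature subset must contain both splice sites")
    if not prepared:
        raise ValueError("no introns to evaluate")
    hits = 0
    for cands in prepared:
        best = None
        best_score = -math.inf
        for c in cands:
            s = sum(c.scores[f] for f in subset)
            if s > best_score:
                best_score = s
                best = c
        if best is not None and best.is_true:
            hits += 1
    return hits / len(prepared)


def recognition_accuracy(introns: Sequence[IntronRecord],
                         feature_subset: Sequence[str],
                         profiles: SpeciesProfiles,
                         length_range: tuple[int, int] = (31, 250),
                         margin: int = 100) -> float:
    """Ac of one feature subset (profiles from all introns; see module doc)."""
    prepared = prepare_regions(introns, profiles, length_range, margin)
    return accuracy_from_prepared(prepared, feature_subset)


@dataclass
class ContributionResult:
    """Per-feature contributions to short-intron recognition for one species."""

    species: str
    accuracies: dict[str, float]        # subset key -> Ac
    tacs: dict[str, float]              # subset key -> TAc (bits)
    contributions: dict[str, float]     # feature -> bits (>= 0)
    necessary_amount: float
    information_deficit: float
    information_shares: dict[str, float]

    def share_vector(self, order: Sequence[str] = ("5ss", "3ss", "BP", "length",
                                                   "composition", "deficit")) -> np.ndarray:
        return np.array([self.information_shares[k] for k in order])


def _subset_key(extra: Sequence[str]) -> str:
    return "+".join(["5ss", "3ss", *extra])


def contribution_decomposition(introns: Sequence[IntronRecord],
                               profiles: SpeciesProfiles,
                               length_range: tuple[int, int] = (31, 250),
                               margin: int = 100,
                               species: str = "") -> ContributionResult:
    """Ac/TAc over all splice-site-anchored feature subsets, plus shares.

    All subsets contain both splice sites.  The BP / length / composition
    contribution is the clipped TAc gain over the splice-site-only subset;
    the joint splice-site TAc is split between 5'ss and 3'ss in proportion
    to their profile information contents (the decomposition of a jointly
    measured quantity; see the methods note).  The deficit is the gap
    between the 98%-accuracy TAc and the best subset's TAc, floored at 0.
    Shares are fractions of the necessary amount; the deficit share is
    chosen so the six shares sum to 1 (renormalised in the saturated case
    where attributed shares already exceed 1).
    """
    prepared = prepare_regions(introns, profiles, length_range, margin)

    accuracies: dict[str, float] = {}
    tacs: dict[str, float] = {}
    for r in range(len(FEATURES_EXTRA) + 1):
        for extra in itertools.combinations(FEATURES_EXTRA, r):
            key = _subset_key(extra)
            ac = accuracy_from_prepared(prepared, ["5ss", "3ss", *extra])
            accuracies[key] = ac
            tacs[key] = transformed_accuracy(ac)

    base = tacs[_subset_key(())]
    contributions = {
        f: max(0.0, tacs[_subset_key((f,))] - base) for f in FEATURES_EXTRA}
    best = max(tacs.values())
    deficit = max(0.0, NECESSARY_AMOUNT - best)

    ic = profiles.information_contents()
    ic_total = ic["5ss"] + ic["3ss"]
    w5 = ic["5ss"] / ic_total if ic_total > 0 else 0.5
    contributions_full = {
        "5ss": base * w5,
        "3ss": base * (1 - w5),
        **contributions,
    }
    shares = {k: v / NECESSARY_AMOUNT for k, v in contributions_full.items()}
    attributed = sum(shares.values())
    if attributed <= 1.0:
        shares["deficit"] = 1.0 - attributed
    else:
        shares = {k: v / attributed for k, v in shares.items()}
        shares["deficit"] = 0.0
    return ContributionResult(
        species=species or (introns[0].species if introns else ""),
        accuracies=accuracies, tacs=tacs, contributions=contributions_full,
        necessary_amount=NECESSARY_AMOUNT, information_deficit=deficit,
        information_shares=shares)
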