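"""Detection of splicing signals: PPT, branch point, and splice-site PWMs.

The polypyrimidine tract (PPT) is located by a greedy backward scan within
50 nt upstream of the 3' splice site: starting at the last pyrimidine
dinucleotide, pyrimidines add +1.0 and purines -1.5, the scan stops once
the running score drops 2 or more below its maximum, and the tract start is
the position of the maximal score.  The branch point (BP) is the best
core-matrix 5-mer upstream of the PPT start (within 100 nt of the 3'ss),
accepted when its score exceeds 1.85 bits; the accepted signal is the 5-mer
plus its upstream 2-mer (a heptamer), and the per-species BP profile is the
4 x 7 position-frequency matrix of all accepted heptamers.

Splice-site profiles are built from gap-less junction alignments: donor
positions -3..+6 around the exon|intron junction (4 x 9) and acceptor
positions -13..+1 around the intron|exon junction (4 x 14), with the
genome-wide base composition as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .intronset import IntronRecord
from .pwm import PWMProfile

logger = logging.getLogger(__name__)

PPT_WINDOW = 50            # nt upstream of the 3'ss searched for the PPT
PPT_SCORE_PY = 1.0
PPT_SCORE_PU = -1.5
PPT_STOP_DROP = 2.0
PPT_MIN_CT_FRACTION = 0.5

BP_WINDOW = 100            # nt upstream of the 3'ss searched for the BP
BP_CORE_WIDTH = 5
BP_PROFILE_WIDTH = 7
BP_SCORE_THRESHOLD = 1.85  # bits

# terminal dinucleotide of the intron is treated as part of the 3'ss motif,
# so upstream searches end 2 nt before the intron end by default
TERMINAL_EXCLUDE = 2

DONOR_OFFSETS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)
ACCEPTOR_OFFSETS = (-13, -12, -11, -10, -9, -8, -7, -6, -5, -4, -3, -2, -1, 1)

_PYRIMIDINES = frozenset("CT")


@dataclass
class PPTAnnotation:
    """Detected polypyrimidine tract, positions relative to the intron end.

    ``start`` and ``end`` are negative offsets from the 3' end of the
    intron (-1 is the last intron base), inclusive on both sides.
    """

    present: bool
    start: int = 0
    end: int = 0
    ppt_score: float = 0.0
    length: int = 0
    ct_fraction: float = 0.0


@dataclass
class BPAnnotation:
    """Detected branch-point signal.

    ``position`` is the negative offset (from the intron 3' end) of the
    first base of the core 5-mer; ``heptamer`` is the 5-mer plus its
    upstream 2-mer.
    """

    present: bool
    position: int = 0
    heptamer: str = ""
    core_score: float = float("-inf")


def find_ppt(intron: IntronRecord | str,
             window: int = PPT_WINDOW,
             terminal_exclude: int = TERMINAL_EXCLUDE,
             min_ct_fraction: float = PPT_MIN_CT_FRACTION) -> PPTAnnotation:
    """Locate the PPT within ``window`` nt upstream of the 3' splice site.

    The search region excludes the intron's terminal dinucleotide (part of
    the 3'ss motif).  Absent any pyrimidine dinucleotide in the region, or
    if the best tract is less than half pyrimidine, the intron is reported
    as lacking a PPT.
    """
    seq = intron.sequence if isinstance(intron, IntronRecord) else intron
    seq = seq.upper()
    L = len(seq)
    hi = L - terminal_exclude            # exclusive end of the search region
    lo = max(0, hi - window)
    if hi - lo < 2:
        return PPTAnnotation(present=False)

    # last pyrimidine dinucleotide in [lo, hi)
    end_idx = -1
    for i in range(hi - 2, lo - 1, -1):
        if seq[i] in _PYRIMIDINES and seq[i + 1] in _PYRIMIDINES:
            end_idx = i + 1              # 3' base of the dinucleotide
            break
    if end_idx < 0:
        return PPTAnnotation(present=False)

    # backward scan accumulating +1.0 / -1.5; stop on a drop >= 2 from the max
    score = 0.0
    best = float("-inf")
    best_idx = end_idx
    for i in range(end_idx, lo - 1, -1):
        score += PPT_SCORE_PY if seq[i] in _PYRIMIDINES else PPT_SCORE_PU
        if score >= best:                # ties -> 5'-most position (longest tract)
            best = score
            best_idx = i
        elif best - score >= PPT_STOP_DROP:
            break

    tract = seq[best_idx:end_idx + 1]
    ct = sum(1 for b in tract if b in _PYRIMIDINES) / len(tract)
    if ct < min_ct_fraction:
        return PPTAnnotation(present=False)
    return PPTAnnotation(present=True,
                         start=best_idx - L, end=end_idx - L,
                         ppt_score=best, length=len(tract), ct_fraction=ct)


def load_default_core_bp() -> PWMProfile:
    """Packaged default 4 x 5 core branch-point matrix.

    A synthetic default with a CTAAC-like consensus (branch adenosine at
    position 4); users with an organism-specific core matrix should load
    their own TSV instead.
    """
    ref = resources.files("splicescape.data") / "core_bp_synthetic.tsv"
    with resources.as_file(ref) as path:
        return PWMProfile.from_tsv(path)


def scan_bp(intron: IntronRecord | str,
            core_pwm: PWMProfile,
            ppt: PPTAnnotation | None = None,
            window: int = BP_WINDOW,
            terminal_exclude: int = TERMINAL_EXCLUDE,
            threshold: float = BP_SCORE_THRESHOLD,
            require_ppt: bool = True) -> BPAnnotation:
    """Score every core 5-mer upstream of the PPT start within the BP window.

    A functional BP is assumed to precede a functional PPT, so by default
    no PPT means no BP call (``require_ppt=False`` scans the full window
    instead).  The maximal-scoring 5-mer is accepted when it exceeds the
    bit threshold; ties resolve to the 3'-most position.  Candidates whose
    upstream 2-mer would run off the intron 5' end are skipped.
    """
    if core_pwm.width != BP_CORE_WIDTH:
        raise ValueError("core BP matrix must have width 5")
    seq = intron.sequence if isinstance(intron, IntronRecord) else intron
    seq = seq.upper()
    L = len(seq)
    if ppt is None:
        ppt = find_ppt(seq, terminal_exclude=terminal_exclude)
    if require_ppt and not ppt.present:
        return BPAnnotation(present=False)

    hi = L - terminal_exclude
    lo = max(0, hi - window)
    # candidate 5-mer *start* positions lie upstream of the PPT start (the
    # 5-mer itself may overlap the tract, as a real BP trails into the PPT)
    limit = ((L + ppt.start) if (require_ppt and ppt.present)
             else hi - BP_CORE_WIDTH + 1)
    first = max(lo, 2)
    last = min(limit, hi - BP_CORE_WIDTH + 1)   # exclusive
    if last <= first:
        return BPAnnotation(present=False)
    from .pwm import encode

    codes = encode(seq[first:last + BP_CORE_WIDTH - 1])
    lo_mat = core_pwm.log_odds()
    scores = np.zeros(last - first)
    for j in range(BP_CORE_WIDTH):
        c = codes[j:j + last - first]
        ok = c >= 0
        scores[ok] += lo_mat[c[ok], j]
    # ties -> 3'-most position
    best_rel = int(len(scores) - 1 - np.argmax(scores[::-1]))
    best_score = float(scores[best_rel])
    best_pos = first + best_rel
    if best_score <= threshold:
        return BPAnnotation(present=False)
    return BPAnnotation(present=True, position=best_pos - L,
                        heptamer=seq[best_pos - 2:best_pos + BP_CORE_WIDTH],
                        core_score=best_score)


def build_bp_profile(introns: Sequence[IntronRecord],
                     core_pwm: PWMProfile,
                     background: np.ndarray | None = None,
                     min_accepted: int = 100,
                     **scan_kwargs) -> tuple[PWMProfile, list[BPAnnotation]]:
    """Species-level 4 x 7 BP profile from all accepted heptamers."""
    annots = []
    heptamers = []
    for rec in introns:
        ann = scan_bp(rec, core_pwm, **scan_kwargs)
        annots.append(ann)
        if ann.present and len(ann.heptamer) == BP_PROFILE_WIDTH:
            heptamers.append(ann.heptamer)
    if not heptamers:
        raise ValueError("no intron yielded an accepted BP heptamer")
    if len(heptamers) < min_accepted:
        logger.warning("only %d BP-positive introns; profile may be noisy",
                       len(heptamers))
    profile = PWMProfile.from_sequences(
        heptamers, background=background,
        offsets=tuple(range(-2, BP_CORE_WIDTH)), name="BP")
    return profile, annots


def build_ss_pwm(introns: Sequence[IntronRecord],
                 side: str,
                 background: np.ndarray | None = None) -> PWMProfile:
    """Donor (4 x 9, positions -3..+6) or acceptor (4 x 14, -13..+1) profile.

    The junction alignment is gap-less by construction.  Introns with
    insufficient flank or too few intronic nt for the motif window are
    skipped with a logged count.
    """
    if side not in ("donor", "acceptor"):
        raise ValueError("side must be 'donor' or 'acceptor'")
    windows = []
    skipped = 0
    for rec in introns:
        w = junction_window(rec, side)
        if w is None:
            skipped += 1
            continue
        windows.append(w)
    if skipped:
        logger.warning("%d introns skipped building the %s profile", skipped, side)
    if not windows:
        raise ValueError(f"no introns usable for the {side} profile")
    offsets = DONOR_OFFSETS if side == "donor" else ACCEPTOR_OFFSETS
    return PWMProfile.from_sequences(windows, background=background,
                                     offsets=offsets, name=side)


def junction_window(rec: IntronRecord, side: str) -> str | None:
    """Motif window around one junction, or None if context is insufficient."""
    if side == "donor":
        if len(rec.upstream_exon_flank) < 3 or rec.length < 6:
            return None
        w = rec.upstream_exon_flank[-3:] + rec.sequence[:6]
    else:
        if len(rec.downstream_exon_flank) < 1 or rec.length < 13:
            return None
        w = rec.sequence[-13:] + rec.downstream_exon_flank[:1]
    return None if "N" in w else w


def annotate_introns(introns: Sequence[IntronRecord],
                     core_pwm: PWMProfile,
                     **scan_kwargs) -> list[tuple[PPTAnnotation, BPAnnotation]]:
    """Per-intron (PPT, BP) annotations with the default scan settings."""
    out = []
    for rec in introns:
        ppt = find_ppt(rec)
        out.append((ppt, scan_bp(rec, core_pwm, ppt=ppt, **scan_kwargs)))
    return out
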