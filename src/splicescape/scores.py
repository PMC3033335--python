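"""The five per-intron information scores and motif information contents.

Each intron receives five log-odds scores, all in bits:

* ``IS_5ss`` / ``IS_3ss`` — PWM score of the donor / acceptor junction
  window against the species profile;
* ``IS_BP`` — PWM score of the detected branch-point heptamer against the
  species 4 x 7 BP profile (0 when no BP is detected);
* ``IS_length`` — ``log2(f(l)/c)`` under the fitted Frechet-mixture length
  density against the uniform competitor ``c``;
* ``IS_composition`` — per-nucleotide fourth-order Markov log-odds of
  intronic vs genomic composition.

The information content of a motif profile is its relative entropy against
the background, which under positional independence is a per-column sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intronset import IntronRecord
from .lengths import LengthModel, fit_length_model  # noqa: F401  (re-export)
from .markov import MarkovModel
from .pwm import PWMProfile
from .signals import (BPAnnotation, PPTAnnotation, annotate_introns,
                      build_bp_profile, build_ss_pwm, junction_window)

logger = logging.getLogger(__name__)

FEATURES = ("5ss", "3ss", "BP", "length", "composition")

SHORT_INTRON_THRESHOLD_DEFAULT = 250  # nt


def pwm_score(segment: str, pwm: PWMProfile) -> float:
    """Log-odds score (bits) of a motif-width segment; N columns add 0."""
    return pwm.score(segment)


def information_content(pwm: PWMProfile) -> float:
    """Relative entropy (bits) of a motif profile against its background."""
    return pwm.information_content()


def length_score(l: int, model: LengthModel) -> float:
    """log2(f(l)/c); out-of-range lengths get the worst in-range score."""
    score, in_range = model.score(l)
    if not in_range:
        logger.debug("length %d outside [%d, %d); penalised",
                     l, model.l_min, model.l_max)
    return score


def fit_markov(seqs: Sequence[str], order: int = 4,
               pseudo_count: float = 0.5) -> MarkovModel:
    """Fit the homogeneous fourth-order composition model.

    Warns when the training material is thin relative to the 4**5
    parameter space.
    """
    if order != 4:
        raise ValueError("only the fourth-order model is supported")
    total = sum(len(s) for s in seqs)
    if total < 10 * 4 ** 5:
        logger.warning("only %d nt of training sequence; 5-mer estimates "
                       "may be unstable", total)
    return MarkovModel.from_sequences(list(seqs), pseudo_count=pseudo_count)


def composition_score(seq: str, p_intron: MarkovModel,
                      p_genome: MarkovModel) -> float:
    """Per-nucleotide compositional log-odds (bits/nt)."""
    if not seq:
        raise ValueError("empty sequence")
    return (p_intron.log2_prob(seq) - p_genome.log2_prob(seq)) / len(seq)


def short_intron_threshold(models: Sequence[LengthModel],
                           quantile: float = 0.95) -> int:
    """Quantile of the averaged short-component length distribution.

    The per-species fitted short components are discretised on a common
    integer grid, averaged with equal species weights, and the requested
    quantile of the average distribution is returned (the pipeline default
    is a fixed 250 nt unless this data-driven threshold is requested).
    """
    if not models:
        raise ValueError("at least one length model required")
    lo = min(m.l_min for m in models)
    hi = max(int(np.ceil(m.short.quantile(0.999))) for m in models)
    hi = max(hi, lo + 2)
    grid = np.arange(lo, hi + 1, dtype=float)
    avg = np.zeros(len(grid) - 1)
    for m in models:
        cdf = m.short.cdf(grid)
        pmf = np.diff(cdf)
        total = pmf.sum()
        if total <= 0:
            raise ValueError("a short component has no mass on the grid")
        avg += pmf / total
    avg /= len(models)
    cum = np.cumsum(avg)
    idx = int(np.searchsorted(cum, quantile * cum[-1]))
    return int(lo + idx)


# ---------------------------------------------------------------------------
# species-level profile bundle


@dataclass
class SpeciesProfiles:
    """Everything needed to score introns of one species."""

    species: str
    donor_pwm: PWMProfile
    acceptor_pwm: PWMProfile
    bp_profile: PWMProfile
    core_bp: PWMProfile
    length_model: LengthModel
    intron_markov: MarkovModel
    genome_markov: MarkovModel
    background: np.ndarray

    def information_contents(self) -> dict[str, float]:
        return {"5ss": self.donor_pwm.information_content(),
                "3ss": self.acceptor_pwm.information_content(),
                "BP": self.bp_profile.information_content()}


def build_species_profiles(introns: Sequence[IntronRecord],
                           background: np.ndarray,
                           core_bp: PWMProfile,
                           genome_seqs: Sequence[str],
                           species: str = "",
                           length_fit_seed: int = 0) -> SpeciesProfiles:
    """Fit all five feature models of a species from its introns + genome."""
    donor = build_ss_pwm(introns, "donor", background=background)
    acceptor = build_ss_pwm(introns, "acceptor", background=background)
    bp_profile, _ = build_bp_profile(introns, core_bp, background=background)
    lengths = np.array([r.length for r in introns])
    length_model = fit_length_model(lengths, seed=length_fit_seed)
    intron_markov = fit_markov([r.sequence for r in introns])
    genome_markov = fit_markov(list(genome_seqs))
    return SpeciesProfiles(
        species=species or (introns[0].species if introns else ""),
        donor_pwm=donor, acceptor_pwm=acceptor, bp_profile=bp_profile,
        core_bp=core_bp, length_model=length_model,
        intron_markov=intron_markov, genome_markov=genome_markov,
        background=background)


def score_intron(rec: IntronRecord, profiles: SpeciesProfiles,
                 ppt: PPTAnnotation | None = None,
                 bp: BPAnnotation | None = None) -> dict[str, float]:
    """The five information scores of one intron (bits; composition bits/nt)."""
    from .signals import find_ppt, scan_bp

    out: dict[str, float] = {}
    dw = junction_window(rec, "donor")
    aw = junction_window(rec, "acceptor")
    out["5ss"] = profiles.donor_pwm.score(dw) if dw else 0.0
    out["3ss"] = profiles.acceptor_pwm.score(aw) if aw else 0.0
    if bp is None:
        if ppt is None:
            ppt = find_ppt(rec)
        bp = scan_bp(rec, profiles.core_bp, ppt=ppt)
    out["BP"] = (profiles.bp_profile.score(bp.heptamer)
                 if bp.present and len(bp.heptamer) == 7 else 0.0)
    out["length"] = length_score(rec.length, profiles.length_model)
    out["composition"] = composition_score(rec.sequence,
                                           profiles.intron_markov,
                                           profiles.genome_markov)
    return out


def score_table(introns: Sequence[IntronRecord],
                profiles: SpeciesProfiles) -> pd.DataFrame:
    """Per-intron score table (columns: intron_id + the five features)."""
    annots = annotate_introns(introns, profiles.core_bp)
    rows = []
    for rec, (ppt, bp) in zip(introns, annots):
        row = {"intron_id": rec.intron_id}
        row.update({f"IS_{k}": v
                    for k, v in score_intron(rec, profiles, ppt, bp).items()})
        rows.append(row)
    return pd.DataFrame(rows)
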