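"""Inter-species feature divergences (modified symmetric Kullback-Leibler).

For a motif feature with species frequencies f, g and genomic backgrounds
F, G the divergence is

    D(A, B) = sum_j sum_k (f - g) * (log2(f/F) - log2(g/G)),

i.e. the difference in expected motif score under the cognate versus the
heterologous log-odds PWM, symmetrised.  The same form applies to 5-mer
composition (stationary intronic 5-mer probabilities against genomic
ones), and intron-length models are compared by the plain symmetric KL of
their discrete densities on the common length range.  These divergences
are not guaranteed non-negative; negative values are reported as-is and
clipped (with a warning) only when a distance matrix feeds UPGMA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lengths import LengthModel
from .markov import MarkovModel
from .pwm import PWMProfile

logger = logging.getLogger(__name__)

#: motif columns excluded from divergence: the invariant terminal
#: dinucleotide of the intron (donor +1,+2; acceptor -2,-1)
TERMINAL_COLUMNS = {"5ss": (3, 4), "3ss": (11, 12), "BP": ()}


def _smoothed_log_odds(f: np.ndarray, bg: np.ndarray, eps: float) -> np.ndarray:
    return np.log2((f + eps) / (bg + eps))


def motif_distance(pwm_a: PWMProfile, pwm_b: PWMProfile,
                   feature: str = "BP") -> float:
    """Symmetrised expected-score divergence between two motif profiles.

    Backgrounds are taken from each profile; for splice-site features the
    invariant terminal-dinucleotide columns are omitted.
    """
    if pwm_a.width != pwm_b.width:
        raise ValueError("profiles must have equal width")
    if feature not in TERMINAL_COLUMNS:
        raise ValueError(f"unknown motif feature {feature!r}")
    keep = [j for j in range(pwm_a.width)
            if j not in TERMINAL_COLUMNS[feature]]
    f = pwm_a.freqs[:, keep]
    g = pwm_b.freqs[:, keep]
    lo_a = _smoothed_log_odds(f, pwm_a.background[:, None], pwm_a.pseudo_count)
    lo_b = _smoothed_log_odds(g, pwm_b.background[:, None], pwm_b.pseudo_count)
    d = float(((f - g) * (lo_a - lo_b)).sum())
    if d < 0:
        logger.debug("negative motif divergence %.3g", d)
    return d


def composition_distance(markov_a: MarkovModel, genome_a: MarkovModel,
                         markov_b: MarkovModel, genome_b: MarkovModel,
                         k: int = 5, eps: float = 1e-6) -> float:
    """Divergence of intronic 5-mer composition between two species.

    f, g are stationary intronic 5-mer probabilities; F, G the genomic
    ones.
    """
    f = markov_a.kmer_probs(k)
    g = markov_b.kmer_probs(k)
    F = genome_a.kmer_probs(k)
    G = genome_b.kmer_probs(k)
    lo_a = np.log2((f + eps) / (F + eps))
    lo_b = np.log2((g + eps) / (G + eps))
    return float(((f - g) * (lo_a - lo_b)).sum())


def length_distance(model_a: LengthModel, model_b: LengthModel,
                    floor: float = 1e-12) -> float:
    """Symmetric KL of the two fitted discrete length densities.

    Summation runs over the common range [L_min, min(L_max_A, L_max_B));
    each density is renormalised on that range so the comparison is between
    genuine distributions.
    """
    lo = max(model_a.l_min, model_b.l_min)
    hi = min(model_a.l_max, model_b.l_max)
    if hi <= lo:
        raise ValueError("length models have empty common range")

    def density_on(model: LengthModel) -> np.ndarray:
        pmf = model.discrete_density()
        seg = pmf[lo - model.l_min: hi - model.l_min]
        total = seg.sum()
        if total <= 0:
            raise ValueError("no density mass on the common range")
        return np.maximum(seg / total, floor)

    f = density_on(model_a)
    g = density_on(model_b)
    return float((f * np.log2(f / g) + g * np.log2(g / f)).sum())


@dataclass
class FeatureDistanceMatrix:
    """Symmetric divergence matrix of one feature over a species panel."""

    feature: str
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("divergence matrix must be symmetric")

    def clipped(self) -> np.ndarray:
        """Non-negative copy for UPGMA input; warns when clipping occurs."""
        if (self.values < 0).any():
            logger.warning("%s matrix has %d negative entries; clipped to 0 "
                           "for tree building", self.feature,
                           int((self.values < 0).sum()))
        return np.maximum(self.values, 0.0)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(f"{lab[:10]:<10}" +
                         " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, feature: str = "") -> "FeatureDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(feature=feature or Path(path).stem,
                   labels=list(df.index), values=df.to_numpy())


def pairwise_matrix(feature: str, labels: Sequence[str],
                    dist: Callable[[int, int], float]) -> FeatureDistanceMatrix:
    """Build a symmetric matrix from a pairwise divergence callable."""
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(i, j)
    return FeatureDistanceMatrix(feature=feature, labels=list(labels), values=D)


def feature_distance_matrices(profiles: Sequence, ) -> dict[str, FeatureDistanceMatrix]:
    """All five feature matrices from a panel of SpeciesProfiles."""
    labels = [p.species for p in profiles]
    mats = {}
    mats["5ss"] = pairwise_matrix(
        "5ss", labels, lambda i, j: motif_distance(
            profiles[i].donor_pwm, profiles[j].donor_pwm, "5ss"))
    mats["3ss"] = pairwise_matrix(
        "3ss", labels, lambda i, j: motif_distance(
            profiles[i].acceptor_pwm, profiles[j].acceptor_pwm, "3ss"))
    mats["BP"] = pairwise_matrix(
        "BP", labels, lambda i, j: motif_distance(
            profiles[i].bp_profile, profiles[j].bp_profile, "BP"))
    mats["length"] = pairwise_matrix(
        "length", labels, lambda i, j: length_distance(
            profiles[i].length_model, profiles[j].length_model))
    kmers = [(p.intron_markov.kmer_probs(5), p.genome_markov.kmer_probs(5))
             for p in profiles]

    def comp(i: int, j: int) -> float:
        f, F = kmers[i]
        g, G = kmers[j]
        eps = 1e-6
        return float(((f - g) * (np.log2((f + eps) / (F + eps)) -
                                 np.log2((g + eps) / (G + eps)))).sum())

    mats["composition"] = pairwise_matrix("composition", labels, comp)
    return mats
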