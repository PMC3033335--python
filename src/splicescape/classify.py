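"""Downstream classification: U12-type intron calls, subtype-stratified
profiles, and clustering of contribution patterns.

AT-AC introns are typically spliced by the minor (U12) spliceosome.  An
intron is called U12-type when (i) its donor window scores more than
9 bits against a U12 reference 5'ss PWM, (ii) its best branch-point
heptamer scores more than 6 bits against a U12 reference BP PWM, and
(iii) it is shorter than 20 kb.  The reference PWMs are built from a
user-supplied set of verified U12 introns; no default matrix is shipped.

Species are also clustered by their recognition-contribution patterns:
PCA on the six raw contribution columns (five features + deficit), then
k-means (k = 6 by default) on the first two components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .divergence import motif_distance, pairwise_matrix
from .intronset import IntronRecord
from .lengths import fit_length_model
from .pwm import PWMProfile
from .signals import BP_WINDOW, TERMINAL_EXCLUDE, build_bp_profile, build_ss_pwm, junction_window

logger = logging.getLogger(__name__)

U12_5SS_BITS = 9.0
U12_BP_BITS = 6.0
U12_MAX_LENGTH = 20_000


@dataclass
class U12Call:
    intron_id: str
    fivess_score: float
    bp_score: float
    length: int
    meets_5ss: bool
    meets_bp: bool
    meets_length: bool

    @property
    def is_u12(self) -> bool:
        return self.meets_5ss and self.meets_bp and self.meets_length


def build_u12_reference_pwms(u12_introns: Sequence[IntronRecord],
                             background: np.ndarray | None = None,
                             ) -> tuple[PWMProfile, PWMProfile]:
    """(5'ss 4x9, BP 4x7) reference profiles from verified U12 introns.

    The BP heptamers are taken as the best-matching position per intron
    against a CCTTAAC-anchored seed count (a plain consensus alignment);
    with a curated input set this reduces to the obvious alignment.
    """
    fivess = build_ss_pwm(u12_introns, "donor", background=background)
    # seed consensus CCTTAAC: pick per intron the 7-mer with most matches
    seed = "CCTTAAC"
    heptamers = []
    for rec in u12_introns:
        seq = rec.sequence.upper()
        hi = len(seq) - TERMINAL_EXCLUDE
        lo = max(0, hi - BP_WINDOW)
        best, best_m = None, -1
        for p in range(lo, hi - 7 + 1):
            h = seq[p:p + 7]
            m = sum(a == b for a, b in zip(h, seed))
            if m >= best_m:
                best, best_m = h, m
        if best is not None:
            heptamers.append(best)
    if not heptamers:
        raise ValueError("no usable BP heptamers in the U12 reference set")
    bp = PWMProfile.from_sequences(heptamers, background=background,
                                   offsets=tuple(range(-2, 5)), name="U12-BP")
    return fivess, bp


def classify_u12(introns: Sequence[IntronRecord],
                 u12_5ss_pwm: PWMProfile,
                 u12_bp_pwm: PWMProfile) -> tuple[list[U12Call], pd.DataFrame]:
    """Per-intron U12 criteria flags plus the criteria-combination tally.

    The BP score is the best 7-mer score within 100 nt of the 3'ss (no
    core-matrix gate and no PPT requirement — the 6-bit criterion replaces
    both).  Criteria use strict inequalities.
    """
    if u12_5ss_pwm is None or u12_bp_pwm is None:
        raise ValueError("both U12 reference PWMs are required")
    calls: list[U12Call] = []
    for rec in introns:
        dw = junction_window(rec, "donor")
        s5 = u12_5ss_pwm.score(dw) if dw else float("-inf")
        seq = rec.sequence.upper()
        hi = len(seq) - TERMINAL_EXCLUDE
        lo = max(0, hi - BP_WINDOW)
        sbp = float("-inf")
        for p in range(lo, hi - 7 + 1):
            sbp = max(sbp, u12_bp_pwm.score(seq[p:p + 7]))
        calls.append(U12Call(
            intron_id=rec.intron_id, fivess_score=s5, bp_score=sbp,
            length=rec.length,
            meets_5ss=s5 > U12_5SS_BITS,
            meets_bp=sbp > U12_BP_BITS,
            meets_length=rec.length < U12_MAX_LENGTH))
    rows = []
    for f5 in (True, False):
        for fb in (True, False):
            for fl in (True, False):
                n = sum(c.meets_5ss == f5 and c.meets_bp == fb and
                        c.meets_length == fl for c in calls)
                rows.append({"meets_5ss": f5, "meets_bp": fb,
                             "meets_length": fl, "count": n})
    return calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subtype-stratified profiles


def subtype_stratified_profiles(introns_by_species: Mapping[str, Sequence[IntronRecord]],
                                backgrounds: Mapping[str, np.ndarray],
                                core_bp: PWMProfile,
                                min_instances: int = 100,
                                subtypes: Sequence[str] = ("GT-AG", "GC-AG", "AT-AC"),
                                ) -> dict[str, dict]:
    """Per-(species, subtype) feature profiles and divergence matrices.

    Only (species, subtype) strata with more than ``min_instances``
    introns are profiled.  Length models are not fit for AT-AC strata
    (their sparse length distributions do not support a two-component
    fit).  Returns {"profiles": {(species, subtype): {...}},
    "matrices": {feature: FeatureDistanceMatrix}} where splice-site
    matrices disregard the terminal dinucleotide columns.
    """
    strata: dict[tuple[str, str], dict] = {}
    for species, recs in introns_by_species.items():
        bg = backgrounds[species]
        for st in subtypes:
            sub = [r for r in recs if r.subtype == st]
            if len(sub) <= min_instances:
                logger.info("%s %s: %d introns <= %d; skipped",
                            species, st, len(sub), min_instances)
                continue
            entry: dict = {
                "donor_pwm": build_ss_pwm(sub, "donor", background=bg),
                "acceptor_pwm": build_ss_pwm(sub, "acceptor", background=bg),
            }
            try:
                entry["bp_profile"], _ = build_bp_profile(sub, core_bp,
                                                          background=bg,
                                                          min_accepted=20)
            except ValueError:
                logger.info("%s %s: no BP-positive introns", species, st)
            if st != "AT-AC":
                try:
                    entry["length_model"] = fit_length_model(
                        np.array([r.length for r in sub]))
                except (ValueError, RuntimeError):
                    logger.info("%s %s: length model not fit", species, st)
            strata[(species, st)] = entry

    labels = [f"{sp}:{st}" for sp, st in strata]
    keys = list(strata)
    matrices = {}
    for feat, slot in (("5ss", "donor_pwm"), ("3ss", "acceptor_pwm")):
        matrices[feat] = pairwise_matrix(
            feat, labels,
            lambda i, j, slot=slot, feat=feat: motif_distance(
                strata[keys[i]][slot], strata[keys[j]][slot], feat))
    return {"profiles": strata, "matrices": matrices}


# ---------------------------------------------------------------------------
# clustering of contribution patterns


@dataclass
class ClusterAssignment:
    species: str
    pc1: float
    pc2: float
    cluster: int


def cluster_contributions(table: pd.DataFrame, k: int = 6, seed: int = 0,
                          n_restarts: int = 20) -> list[ClusterAssignment]:
    """PCA + k-means on the six raw contribution columns.

    ``table`` must be indexed by species with columns
    5ss, 3ss, BP, length, composition, deficit (any order).  The first two
    principal components feed k-means; the best inertia over restarts is
    kept, and a fixed seed makes assignments reproducible.
    """
    cols = ["5ss", "3ss", "BP", "length", "composition", "deficit"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"contribution table lacks columns {sorted(missing)}")
    X = table[cols].to_numpy(dtype=float)
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of species ({n})")
    n_comp = min(2, n, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    Z = pca.fit_transform(X)
    if Z.shape[1] < 2:
        Z = np.column_stack([Z, np.zeros(len(Z))])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Z[:, :2])
    return [ClusterAssignment(species=str(sp), pc1=float(z[0]),
                              pc2=float(z[1]), cluster=int(c) + 1)
            for sp, z, c in zip(table.index, Z, labels)]
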