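"""U12-type calls, subtype-stratified profiling and contribution clustering."""

import numpy as np
import pandas as pd
import pytest

import splicescape as ss
from splicescape.classify import (build_u12_reference_pwms, classify_u12,
                                  cluster_contributions,
                                  subtype_stratified_profiles)
from splicescape.syndata import _pwm

from conftest import light_length_mixture


def sharp_col(base, conc=0.998):
    return {base: conc, **{x: (1 - conc) / 3 for x in "ACGT" if x != base}}


def u12_spec(name, n, seed):
    """AT-AC species with sharply planted U12-consensus donor (ATATCC) and
    BP (CCTTAAC); a single mismatch in either motif costs ~8 bits against
    the reference PWMs, so sharp planting is what makes the bit criteria
    attainable."""
    donor = _pwm([
        {"A": .30, "C": .30, "G": .25, "T": .15},   # -3 exonic
        {"A": .30, "C": .25, "G": .25, "T": .20},   # -2
        {"A": .25, "C": .30, "G": .25, "T": .20},   # -1
        {"A": 1.0}, {"T": 1.0},                      # +1 +2 (AT, resynced)
        sharp_col("A"), sharp_col("T"), sharp_col("C"), sharp_col("C"),
    ], (-3, -2, -1, 1, 2, 3, 4, 5, 6), "U12-donor")
    bp = _pwm([sharp_col(b) for b in "CCTTAAC"],
              tuple(range(-2, 5)), "U12-BP")
    return ss.default_species_spec(
        name, n_introns=n, seed=seed,
        subtype_fractions={"GT-AG": 0.0, "GC-AG": 0.0, "AT-AC": 1.0},
        donor_pwm=donor, bp_pwm=bp, length_mixture=light_length_mixture())


@pytest.fixture(scope="module")
def u12_reference_pwms():
    ref_species = ss.generate_species(u12_spec("u12ref", 300, 77))
    return build_u12_reference_pwms(ref_species.introns)


class TestU12:
    def test_reference_pwms_match_planted_consensus(self, u12_reference_pwms):
        fivess, bp = u12_reference_pwms
        assert fivess.consensus()[3:] == "ATATCC"
        assert bp.consensus() == "CCTTAAC"

    def test_length_criterion_boundary(self, u12_reference_pwms):
        fivess, bp = u12_reference_pwms
        seq = "AT" + "ATCC" + "G" * 24900 + "CCTTAAC" + "T" * 60 + "AC"
        long_intron = ss.IntronRecord(
            species="s", contig="c", start=0, end=len(seq), strand="+",
            sequence=seq, upstream_exon_flank="A" * 50,
            downstream_exon_flank="G" * 50)
        calls, _ = classify_u12([long_intron], fivess, bp)
        assert not calls[0].meets_length
        assert not calls[0].is_u12

    def test_score_criteria_are_strict_inequalities(self):
        from splicescape.classify import U12Call
        c = U12Call(intron_id="x", fivess_score=9.0, bp_score=6.0, length=100,
                    meets_5ss=9.0 > 9.0, meets_bp=6.0 > 6.0, meets_length=True)
        assert not c.meets_5ss and not c.meets_bp and not c.is_u12

    def test_planted_u12_sensitivity_and_specificity(self, u12_reference_pwms):
        fivess, bp = u12_reference_pwms
        u12 = ss.generate_species(u12_spec("u12", 400, 78))
        calls, tally = classify_u12(u12.introns, fivess, bp)
        sens = sum(c.is_u12 for c in calls) / len(calls)
        assert sens > 0.95
        # GT-AG controls from the default (major-spliceosome) generator
        control = ss.generate_species(ss.default_species_spec(
            "ctl", n_introns=400, seed=79,
            length_mixture=light_length_mixture()))
        gtag = [r for r in control.introns if r.subtype == "GT-AG"]
        ctl_calls, _ = classify_u12(gtag, fivess, bp)
        assert sum(c.is_u12 for c in ctl_calls) == 0
        assert tally["count"].sum() == len(calls)


class TestSubtypeStratified:
    def test_sparse_strata_skipped_and_atac_has_no_length_model(self):
        spec = ss.default_species_spec(
            "mix", n_introns=2500, seed=41,
            subtype_fractions={"GT-AG": 0.78, "GC-AG": 0.14, "AT-AC": 0.08},
            length_mixture=light_length_mixture())
        species = ss.generate_species(spec)
        bg = ss.genome_background(species.genome_sequences())
        out = subtype_stratified_profiles(
            {"mix": species.introns}, {"mix": bg}, ss.load_default_core_bp(),
            min_instances=100)
        profs = out["profiles"]
        assert ("mix", "GT-AG") in profs
        assert ("mix", "GC-AG") in profs
        assert ("mix", "AT-AC") in profs
        assert "length_model" not in profs[("mix", "AT-AC")]
        assert "5ss" in out["matrices"] and "3ss" in out["matrices"]
        # a stratum below the instance floor is not profiled
        out2 = subtype_stratified_profiles(
            {"mix": [r for r in species.introns][:400]}, {"mix": bg},
            ss.load_default_core_bp(), min_instances=100)
        assert ("mix", "AT-AC") not in out2["profiles"]


class TestClustering:
    def _archetype_table(self, noise, seed):
        rng = np.random.default_rng(seed)
        archetypes = np.array([
            [.30, .25, .02, .02, .02, .39],
            [.28, .22, .02, .02, .10, .36],
            [.20, .18, .05, .35, .05, .17],
            [.18, .16, .10, .12, .12, .32],
            [.10, .08, .02, .02, .02, .76],
            [.22, .20, .05, .10, .28, .15],
        ])
        rows, labels = [], []
        for a, arch in enumerate(archetypes):
            for r in range(5):
                rows.append(arch + noise * rng.standard_normal(6))
                labels.append(a)
        table = pd.DataFrame(
            rows, columns=["5ss", "3ss", "BP", "length", "composition",
                           "deficit"],
            index=[f"sp{a}_{r}" for a in range(6) for r in range(5)])
        return table, np.array(labels)

    def test_six_archetypes_recovered_at_low_noise(self):
        from sklearn.metrics import adjusted_rand_score
        table, truth = self._archetype_table(noise=0.005, seed=1)
        assignments = cluster_contributions(table, k=6, seed=0)
        pred = [a.cluster for a in assignments]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_k_equals_one_single_cluster(self):
        table, _ = self._archetype_table(noise=0.01, seed=2)
        assignments = cluster_contributions(table, k=1, seed=0)
        assert {a.cluster for a in assignments} == {1}

    def test_deterministic_under_fixed_seed(self):
        table, _ = self._archetype_table(noise=0.02, seed=3)
        a = [c.cluster for c in cluster_contributions(table, k=6, seed=5)]
        b = [c.cluster for c in cluster_contributions(table, k=6, seed=5)]
        assert a == b

    def test_invariant_to_column_order(self):
        table, _ = self._archetype_table(noise=0.005, seed=4)
        shuffled = table[["deficit", "BP", "5ss", "composition", "length",
                          "3ss"]]
        a = [c.cluster for c in cluster_contributions(table, k=6, seed=0)]
        b = [c.cluster for c in cluster_contributions(shuffled, k=6, seed=0)]
        assert a == b

    def test_k_larger_than_n_rejected(self):
        table, _ = self._archetype_table(noise=0.01, seed=5)
        with pytest.raises(ValueError):
            cluster_contributions(table.iloc[:4], k=6)
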