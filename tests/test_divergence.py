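"""Inter-species feature divergences: symmetry, self-distance, oracles."""

import numpy as np
import pytest

from splicescape.divergence import (FeatureDistanceMatrix,
                                    composition_distance, length_distance,
                                    motif_distance, pairwise_matrix)
from splicescape.lengths import FrechetComponent, LengthModel
from splicescape.markov import MarkovModel

from conftest import random_pwm


class TestMotifDistance:
    def test_self_distance_zero(self, rng):
        pwm = random_pwm(7, rng, background=np.array([0.2, 0.3, 0.3, 0.2]))
        assert motif_distance(pwm, pwm, "BP") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_swap(self, rng):
        a = random_pwm(7, rng)
        b = random_pwm(7, rng, background=np.array([0.3, 0.2, 0.2, 0.3]))
        assert motif_distance(a, b, "BP") == pytest.approx(
            motif_distance(b, a, "BP"), abs=1e-12)

    def test_term_by_term_summation_oracle(self, rng):
        a = random_pwm(9, rng)
        b = random_pwm(9, rng, background=np.array([0.3, 0.2, 0.2, 0.3]))
        keep = [0, 1, 2, 5, 6, 7, 8]  # all columns except donor +1, +2
        total = 0.0
        for j in keep:
            for k in range(4):
                f, g = a.freqs[k, j], b.freqs[k, j]
                lf = np.log2((f + a.pseudo_count) /
                             (a.background[k] + a.pseudo_count))
                lg = np.log2((g + b.pseudo_count) /
                             (b.background[k] + b.pseudo_count))
                total += f * (lf - lg) + g * (lg - lf)
        assert motif_distance(a, b, "5ss") == pytest.approx(total, abs=1e-10)

    def test_terminal_dinucleotide_columns_ignored(self, rng):
        a = random_pwm(9, rng)
        f2 = a.freqs.copy()
        f2[:, 3] = [0.0, 0.0, 1.0, 0.0]   # change only the +1/+2 columns
        f2[:, 4] = [0.0, 0.0, 0.0, 1.0]
        import dataclasses
        b = dataclasses.replace(a, freqs=f2)
        assert motif_distance(a, b, "5ss") == pytest.approx(0.0, abs=1e-12)
        assert motif_distance(a, b, "BP") != pytest.approx(0.0, abs=1e-6)

    def test_width_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            motif_distance(random_pwm(7, rng), random_pwm(9, rng), "BP")


class TestCompositionDistance:
    def test_identical_species_zero_and_symmetric(self):
        mi = MarkovModel.iid(np.array([0.3, 0.2, 0.2, 0.3]))
        mg = MarkovModel.iid(np.full(4, 0.25))
        assert composition_distance(mi, mg, mi, mg) == pytest.approx(0.0, abs=1e-9)
        mi2 = MarkovModel.iid(np.array([0.2, 0.3, 0.3, 0.2]))
        d1 = composition_distance(mi, mg, mi2, mg)
        d2 = composition_distance(mi2, mg, mi, mg)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 > 0

    def test_explicit_1024_term_sum_oracle(self):
        mi_a = MarkovModel.iid(np.array([0.4, 0.1, 0.2, 0.3]))
        mi_b = MarkovModel.iid(np.array([0.25, 0.25, 0.3, 0.2]))
        mg_a = MarkovModel.iid(np.array([0.3, 0.2, 0.25, 0.25]))
        mg_b = MarkovModel.iid(np.full(4, 0.25))
        eps = 1e-6
        total = 0.0
        import itertools
        for combo in itertools.product(range(4), repeat=5):
            f = np.prod([[0.4, 0.1, 0.2, 0.3][k] for k in combo])
            g = np.prod([[0.25, 0.25, 0.3, 0.2][k] for k in combo])
            F = np.prod([[0.3, 0.2, 0.25, 0.25][k] for k in combo])
            G = 0.25 ** 5
            lf = np.log2((f + eps) / (F + eps))
            lg = np.log2((g + eps) / (G + eps))
            total += f * (lf - lg) + g * (lg - lf)
        got = composition_distance(mi_a, mg_a, mi_b, mg_b)
        assert got == pytest.approx(total, abs=1e-6)


class TestLengthDistance:
    def _model(self, scale_long=800.0):
        return LengthModel(short=FrechetComponent(3.0, 40.0, 30.0),
                           long=FrechetComponent(2.0, scale_long, 60.0),
                           weight=0.6)

    def test_identical_models_zero(self):
        m = self._model()
        assert length_distance(m, m) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_positive(self):
        a, b = self._model(), self._model(scale_long=300.0)
        assert length_distance(a, b) == pytest.approx(length_distance(b, a))
        assert length_distance(a, b) > 0

    def test_direct_summation_oracle_over_common_range(self):
        a, b = self._model(), self._model(scale_long=300.0)
        lo = max(a.l_min, b.l_min)
        hi = min(a.l_max, b.l_max)
        fa = a.discrete_density()[lo - a.l_min: hi - a.l_min]
        fb = b.discrete_density()[lo - b.l_min: hi - b.l_min]
        fa = np.maximum(fa / fa.sum(), 1e-12)   # same underflow floor
        fb = np.maximum(fb / fb.sum(), 1e-12)
        oracle = float(sum(f * np.log2(f / g) + g * np.log2(g / f)
                           for f, g in zip(fa, fb)))
        assert length_distance(a, b) == pytest.approx(oracle, rel=1e-6)

    def test_empty_common_range_raises(self):
        a = self._model()
        b = LengthModel(short=FrechetComponent(3.0, 5.0, 30.0),
                        long=FrechetComponent(3.0, 6.0, 30.0),
                        weight=0.5, l_min=30, l_max=31)
        with pytest.raises(ValueError):
            length_distance(a, b)


class TestMatrix:
    def test_matrix_construction_and_clipping(self, caplog):
        labels = ["a", "b", "c"]
        mat = pairwise_matrix("5ss", labels,
                              lambda i, j: -0.1 if (i, j) == (0, 1) else 1.0)
        assert (mat.values == mat.values.T).all()
        clipped = mat.clipped()
        assert clipped.min() == 0.0
        assert mat.values.min() == -0.1  # original preserved

    def test_tsv_round_trip(self, tmp_path):
        mat = pairwise_matrix("BP", ["x", "y"], lambda i, j: 2.5)
        path = tmp_path / "bp.tsv"
        mat.to_tsv(path)
        back = FeatureDistanceMatrix.from_tsv(path, feature="BP")
        np.testing.assert_allclose(back.values, mat.values)
        assert back.labels == mat.labels
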