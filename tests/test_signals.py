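"""PPT and branch-point detection, and splice-site profile construction."""

import numpy as np
import pytest

import splicescape as ss
from splicescape.signals import (BP_SCORE_THRESHOLD, find_ppt, scan_bp,
                                 build_bp_profile, build_ss_pwm)

from conftest import random_dna


def ppt_oracle(seq: str, window: int = 50, terminal_exclude: int = 2):
    """Independent list-based replay of the PPT scan."""
    seq = seq.upper()
    hi = len(seq) - terminal_exclude
    lo = max(0, hi - window)
    py = set("CT")
    ends = [i + 1 for i in range(lo, hi - 1)
            if seq[i] in py and seq[i + 1] in py]
    if not ends:
        return None
    end = ends[-1]
    scores = []
    total = 0.0
    for i in range(end, lo - 1, -1):
        total += 1.0 if seq[i] in py else -1.5
        scores.append((i, total))
    best = -1e18
    start = end
    for i, sc in scores:
        if sc >= best:
            best, start = sc, i
        elif best - sc >= 2.0:
            break
    tract = seq[start:end + 1]
    ct = sum(b in py for b in tract) / len(tract)
    if ct < 0.5:
        return None
    return start, end, best, ct


class TestFindPPT:
    def test_all_pyrimidine_window(self):
        intron = "GT" + "A" * 20 + "T" * 50 + "AG"
        ann = find_ppt(intron)
        assert ann.present
        assert ann.length == 50
        assert ann.ppt_score == pytest.approx(50.0)
        assert ann.ct_fraction == pytest.approx(1.0)

    def test_all_purine_window_lacks_ppt(self):
        intron = "GT" + "A" * 70 + "AG"
        assert not find_ppt(intron).present

    def test_matches_replay_oracle_on_random_sequences(self, rng):
        for _ in range(400):
            intron = random_dna(int(rng.integers(35, 120)), rng,
                                p=[0.3, 0.2, 0.2, 0.3])
            ann = find_ppt(intron)
            oracle = ppt_oracle(intron)
            if oracle is None:
                assert not ann.present
            else:
                start, end, score, ct = oracle
                L = len(intron)
                assert ann.present
                assert (L + ann.start, L + ann.end) == (start, end)
                assert ann.ppt_score == pytest.approx(score)
                assert ann.ct_fraction == pytest.approx(ct)

    def test_present_implies_valid_ct_fraction(self, rng):
        for _ in range(200):
            ann = find_ppt(random_dna(60, rng))
            if ann.present:
                assert 0.5 <= ann.ct_fraction <= 1.0


class TestScanBP:
    def test_absent_when_nothing_clears_threshold(self, core_bp):
        # G-rich intron: every 5-mer scores far below 1.85 bits
        intron = "GT" + "G" * 40 + "TTTTTTTTTT" + "AG"
        ann = scan_bp(intron, core_bp)
        assert not ann.present

    def test_consensus_found_with_column_maxima_score(self, core_bp):
        consensus = core_bp.consensus()  # CTAAC for the packaged matrix
        intron = "GT" + "G" * 40 + consensus + "T" * 20 + "AG"
        ann = scan_bp(intron, core_bp)
        assert ann.present
        assert ann.core_score == pytest.approx(core_bp.consensus_score())
        assert ann.heptamer[2:] == consensus

    def test_tie_resolves_to_three_prime_most(self, core_bp):
        consensus = core_bp.consensus()
        intron = ("GT" + "G" * 10 + consensus + "G" * 10 + consensus +
                  "T" * 20 + "AG")
        ann = scan_bp(intron, core_bp)
        second = len("GT") + 10 + 5 + 10
        assert len(intron) + ann.position == second

    def test_no_ppt_means_no_bp_by_default(self, core_bp):
        intron = "GT" + "G" * 20 + core_bp.consensus() + "G" * 40 + "AG"
        assert not scan_bp(intron, core_bp).present
        assert scan_bp(intron, core_bp, require_ppt=False).present

    def test_maximum_equals_brute_force_over_window(self, rng, core_bp):
        for _ in range(300):
            intron = random_dna(int(rng.integers(40, 150)), rng,
                                p=[0.3, 0.2, 0.2, 0.3])
            ppt = find_ppt(intron)
            ann = scan_bp(intron, core_bp, ppt=ppt)
            if not ppt.present:
                assert not ann.present
                continue
            L = len(intron)
            hi = L - 2
            lo = max(0, hi - 100)
            limit = L + ppt.start
            best = None
            for p in range(max(lo, 2), min(limit, hi - 4)):
                s = core_bp.score(intron[p:p + 5])
                if best is None or s >= best[1]:
                    best = (p, s)
            if best is None or best[1] <= BP_SCORE_THRESHOLD:
                assert not ann.present
            else:
                assert ann.present
                assert L + ann.position == best[0]
                assert ann.core_score == pytest.approx(best[1])


class TestProfiles:
    def test_bp_profile_degenerate_when_all_heptamers_identical(self, core_bp):
        introns = []
        for i in range(30):
            seq = "GT" + "G" * 30 + "TACTAAC" + "T" * 15 + "TTTTTTTTTTTAG"
            introns.append(ss.IntronRecord(
                species="s", contig="c", start=i * 1000,
                end=i * 1000 + len(seq), strand="+", sequence=seq,
                upstream_exon_flank="A" * 50, downstream_exon_flank="G" * 50))
        profile, annots = build_bp_profile(introns, core_bp, min_accepted=10)
        assert all(a.present for a in annots)
        assert profile.consensus() == "TACTAAC"
        assert profile.freqs.max(axis=0).min() == pytest.approx(1.0)

    def test_ss_pwm_degenerate_and_uniform_limits(self, rng):
        recs = []
        for i in range(40):
            seq = "GTAAGT" + "C" * 50 + "TTTTTTTTTTTAG"
            recs.append(ss.IntronRecord(
                species="s", contig="c", start=i * 500, end=i * 500 + len(seq),
                strand="+", sequence=seq, upstream_exon_flank="A" * 47 + "CAG",
                downstream_exon_flank="G" * 50))
        donor = build_ss_pwm(recs, "donor")
        assert donor.consensus() == "CAGGTAAGT"
        assert donor.width == 9
        # uniform random junctions carry (almost) no information
        recs2 = []
        for i in range(400):
            seq = random_dna(60, rng)
            recs2.append(ss.IntronRecord(
                species="s", contig="c", start=i * 500, end=i * 500 + 60,
                strand="+", sequence=seq,
                upstream_exon_flank=random_dna(50, rng),
                downstream_exon_flank=random_dna(50, rng)))
        acceptor = build_ss_pwm(recs2, "acceptor")
        assert acceptor.width == 14
        assert acceptor.information_content() < 0.25

    def test_planted_profiles_recovered(self, small_species, small_profiles):
        spec = small_species.spec
        tv = np.abs(small_profiles.donor_pwm.freqs -
                    spec.donor_pwm.freqs).sum(axis=0) / 2
        assert tv.max() < 0.08  # n=400: generous law-of-large-numbers bound
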