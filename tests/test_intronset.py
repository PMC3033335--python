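"""Intron extraction, quality filtering, de-duplication and subtype tally."""

import numpy as np
import pytest
from Bio.Seq import Seq

import splicescape as ss
from splicescape.intronset import FLANK_LEN, IntronRecord, classify_subtype

from conftest import random_dna


def make_record(sequence, up=None, down=None, species="s", contig="c",
                start=0, strand="+"):
    return IntronRecord(
        species=species, contig=contig, start=start,
        end=start + len(sequence), strand=strand, sequence=sequence,
        upstream_exon_flank=up or "A" * FLANK_LEN,
        downstream_exon_flank=down or "G" * FLANK_LEN)


class TestExtraction:
    def test_two_exon_plus_strand_gene(self):
        intron = "GTAAGT" + "C" * 30 + "TTCAG"
        genome = {"c": "A" * 60 + intron + "G" * 60}
        recs = ss.extract_introns(genome, {"t": ("c", "+", [(0, 60), (60 + len(intron), 120 + len(intron))])})
        assert len(recs) == 1
        assert recs[0].sequence == intron
        assert recs[0].subtype == "GT-AG"
        assert recs[0].upstream_exon_flank == "A" * 50

    def test_minus_strand_reverse_complemented(self):
        intron = "GTAAGT" + "ACGTACGT" * 4 + "TTCAG"
        plus = "A" * 60 + intron + "G" * 60
        genome_minus = {"c": str(Seq(plus).reverse_complement())}
        L = len(plus)
        spans = [(0, 60), (L - 60, L)]  # mirror of the plus-strand exons
        recs = ss.extract_introns(genome_minus, {"t": ("c", "-", spans)})
        assert recs[0].sequence == intron
        assert recs[0].subtype == "GT-AG"

    def test_multi_exon_transcript_gap_lengths(self, rng):
        """A 5-exon transcript yields 4 introns whose lengths equal the
        annotated gaps (independent coordinate arithmetic)."""
        exon_len, gaps = 80, [40, 55, 33, 90]
        pos, spans = 0, []
        for g in [0] + gaps:
            pos += g
            spans.append((pos, pos + exon_len))
            pos += exon_len
        genome = {"c": random_dna(pos + 10, rng)}
        recs = ss.extract_introns(genome, {"t": ("c", "+", spans)})
        assert [r.length for r in recs] == gaps
        for (s1, e1), (s2, e2), rec in zip(spans, spans[1:], recs):
            assert (rec.start, rec.end) == (e1, s2)

    def test_coordinates_outside_contig_raise(self):
        with pytest.raises(ValueError):
            ss.extract_introns({"c": "ACGT" * 10},
                               {"t": ("c", "+", [(0, 10), (20, 100)])})

    def test_round_trip_of_generated_species(self, small_species, tmp_path):
        small_species.write(tmp_path)
        recs = ss.extract_introns(tmp_path / "small.fa",
                                  tmp_path / "small.gff3", species="small")
        recs.sort(key=lambda r: r.start)
        assert len(recs) == len(small_species.introns)
        for a, b in zip(recs, small_species.introns):
            assert (a.sequence, a.start, a.end, a.subtype) == \
                   (b.sequence, b.start, b.end, b.subtype)
            assert a.upstream_exon_flank == b.upstream_exon_flank


class TestQualityFilter:
    def test_twelve_intron_fixture_survivors(self):
        """Hand-built fixture: exact per-criterion rejection sets."""
        good = "GT" + "A" * 60 + "AG"
        records = [
            make_record(good, start=0),                       # pass
            make_record("GC" + "A" * 60 + "AG", start=100),   # pass (GC-AG)
            make_record("AT" + "A" * 60 + "AC", start=200),   # pass (AT-AC)
            make_record("CT" + "A" * 60 + "AG", start=300),   # (i) non-canonical
            make_record("GT" + "A" * 60 + "AC", start=400),   # (i) mispaired
            make_record("AT" + "A" * 60 + "AG", start=500),   # (i) mispaired
            make_record("GT" + "A" * 21 + "AG", start=600),   # (ii) 25 nt
            make_record("GT" + "A" * 26 + "AG", start=700),   # (ii) exactly 30
            make_record("GT" + "A" * 27 + "AG", start=800),   # pass (31 nt)
            make_record(good, start=900),                     # (iii) mismatches
            make_record(good, start=1000),                    # (iii) gap
            make_record(good, start=1100),                    # pass
        ]
        ctx = {records[9].intron_id: (2, 0, 0, 0),
               records[10].intron_id: (0, 0, 1, 1),
               records[11].intron_id: (1, 0, 1, 0)}  # boundary: still passes
        passed, report = ss.quality_filter(records, alignment_context=ctx)
        assert [r.start for r in passed] == [0, 100, 200, 800, 1100]
        assert report.rejected_noncanonical == 3
        assert report.rejected_short == 2
        assert report.rejected_alignment == 2

    def test_filter_is_total(self, small_species):
        passed, report = ss.quality_filter(small_species.introns)
        assert report.n_passed == len(small_species.introns)


class TestDeduplicate:
    def _pair_with_identity(self, ident: float, rng):
        """Two records whose four junction contexts share the given
        ungapped identity (verified position-by-position)."""
        base_up = random_dna(50, rng)
        base_seq = "GT" + random_dna(96, rng) + "AG"
        base_down = random_dna(50, rng)
        r1 = make_record(base_seq, up=base_up, down=base_down, start=0)
        n_mut = round((1 - ident) * 100)
        # mutate n_mut positions in each 100-nt context, avoiding the ends
        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
            return "".join(out)
        don_pos = rng.choice(np.arange(2, 98), size=n_mut, replace=False)
        acc_pos = rng.choice(np.arange(2, 98), size=n_mut, replace=False)
        up2 = mutate(base_up, [p for p in don_pos if p < 50])
        seq2 = mutate(base_seq, [p - 50 + 0 for p in don_pos if p >= 50])
        seq2 = mutate(seq2, [len(base_seq) - 50 + p for p in acc_pos if p < 50])
        down2 = mutate(base_down, [p - 50 for p in acc_pos if p >= 50])
        r2 = make_record(seq2, up=up2, down=down2, start=1000)
        d1, a1 = r1.junction_contexts()
        d2, a2 = r2.junction_contexts()
        got = sum(x == y for x, y in zip(d1, d2)) / 100
        assert got == pytest.approx(ident, abs=0.001)
        return r1, r2

    def test_identical_contexts_collapse(self, rng):
        seq = "GT" + random_dna(60, rng) + "AG"
        r1 = make_record(seq, start=0)
        r2 = make_record(seq, start=500)
        kept = ss.deduplicate([r1, r2])
        assert len(kept) == 1
        assert kept[0].start == 0  # lexicographically smallest coordinate

    def test_eighty_percent_identity_merges(self, rng):
        r1, r2 = self._pair_with_identity(0.80, rng)
        assert len(ss.deduplicate([r1, r2])) == 1

    def test_sixty_percent_identity_retained(self, rng):
        r1, r2 = self._pair_with_identity(0.60, rng)
        assert len(ss.deduplicate([r1, r2])) == 2

    def test_threshold_is_strict(self, rng):
        r1, r2 = self._pair_with_identity(0.75, rng)
        assert len(ss.deduplicate([r1, r2])) == 2

    def test_random_representative_reproducible(self, rng):
        seq = "GT" + random_dna(60, rng) + "AG"
        recs = [make_record(seq, start=i * 100) for i in range(4)]
        a = ss.deduplicate(recs, random_representative=True, seed=3)
        b = ss.deduplicate(recs, random_representative=True, seed=3)
        assert [r.start for r in a] == [r.start for r in b]


class TestSubtypeTally:
    def test_fraction_arithmetic(self):
        recs = ([make_record("GT" + "A" * 40 + "AG", start=i * 100)
                 for i in range(98)] +
                [make_record("GC" + "A" * 40 + "AG", start=i * 100 + 50)
                 for i in range(2)])
        tally = ss.subtype_tally(recs)
        frac = dict(zip(tally["subtype"], tally["fraction"]))
        assert frac["GT-AG"] == pytest.approx(0.98)
        assert frac["GC-AG"] == pytest.approx(0.02)

    def test_empty_input_empty_table(self):
        assert ss.subtype_tally([]).empty

    def test_planted_fractions_recovered_within_3_sigma(self):
        fracs = {"GT-AG": 0.9, "GC-AG": 0.08, "AT-AC": 0.02}
        spec = ss.default_species_spec("tally", n_introns=10000, seed=21,
                                       subtype_fractions=fracs)
        species = ss.generate_species(spec)
        tally = ss.subtype_tally(species.introns)
        counts = dict(zip(tally["subtype"], tally["count"]))
        n = 10000
        for st, p in fracs.items():
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(st, 0) - n * p) < 3 * sigma


def test_classify_subtype_consistency():
    assert classify_subtype("GTAAAG") == "GT-AG"
    assert classify_subtype("GCAAAG") == "GC-AG"
    assert classify_subtype("ATAAAC") == "AT-AC"
    assert classify_subtype("ATAAAG") == "other"
    assert classify_subtype("CTAAAC") == "other"
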