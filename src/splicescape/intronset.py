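"""Intron extraction, quality filtering, de-duplication and exchange IO.

Introns are extracted from a genome plus transcript exon structures
(GFF3 or BED12), classified by their terminal dinucleotides
(GT-AG / GC-AG / AT-AC / other), filtered by three quality criteria and
de-duplicated by junction-context identity.  The exchange format is a pair
of files: a FASTA of intron sequences (ids encode coordinates) and a
metadata TSV carrying flanks and annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

FLANK_LEN = 50
MIN_INTRON_LENGTH = 31  # introns must be longer than 30 nt

SUBTYPES = ("GT-AG", "GC-AG", "AT-AC")

_DONOR_TO_ACCEPTOR = {"GT": "AG", "GC": "AG", "AT": "AC"}


def classify_subtype(sequence: str) -> str:
    """Terminal-dinucleotide subtype of an intron sequence."""
    if len(sequence) < 4:
        return "other"
    donor = sequence[:2].upper()
    acceptor = sequence[-2:].upper()
    if _DONOR_TO_ACCEPTOR.get(donor) == acceptor:
        return f"{donor}-{acceptor}"
    return "other"


@dataclass
class IntronRecord:
    """One extracted intron with its exonic junction context.

    Coordinates are 0-based half-open on the genomic contig; ``sequence``
    and the flanks are in spliced-strand orientation (the sequence starts
    with the donor dinucleotide regardless of genomic strand).
    """

    species: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    upstream_exon_flank: str
    downstream_exon_flank: str
    subtype: str = ""
    interior_span: tuple[int, int] | None = None  # generator truth, optional

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError("span length disagrees with sequence length")
        if not self.subtype:
            self.subtype = classify_subtype(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def intron_id(self) -> str:
        return f"{self.species}|{self.contig}:{self.start}-{self.end}({self.strand})"

    def junction_contexts(self, half: int = FLANK_LEN) -> tuple[str, str]:
        """(donor, acceptor) contexts: half exonic + half intronic nt each."""
        don = self.upstream_exon_flank[-half:] + self.sequence[:half]
        acc = self.sequence[-half:] + self.downstream_exon_flank[:half]
        return don, acc


# ---------------------------------------------------------------------------
# extraction


def _read_genome(genome: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: str(v).upper() for k, v in genome.items()}
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome), "fasta")}


def read_exon_structures(path: str | Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    """Transcript id -> (contig, strand, sorted exon spans, 0-based half-open).

    Accepts GFF3 (exon features grouped by Parent) or BED12.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id or "transcript"])
        for parent in parents:
            contig, strand, spans = out.setdefault(parent, (exon.seqid, exon.strand, []))
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            spans.append((exon.start - 1, exon.end))
    return {
        tid: (contig, strand, sorted(spans))
        for tid, (contig, strand, spans) in out.items()
    }


def _read_bed12(path: Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    out: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            spans = [(chrom_start + s, chrom_start + s + sz)
                     for s, sz in zip(starts, sizes)]
            out[name] = (chrom, strand, sorted(spans))
    return out


def extract_introns(genome: str | Path | Mapping[str, str],
                    exon_structures: str | Path | Mapping[str, tuple[str, str, list[tuple[int, int]]]],
                    species: str = "species",
                    flank: int = FLANK_LEN) -> list[IntronRecord]:
    """One IntronRecord per internal exon gap of every multi-exon transcript.

    Minus-strand genes are reverse-complemented so records are always in
    spliced-strand orientation.  Exon flanks are taken from the adjacent
    exon ends, padded with N if the exon is shorter than ``flank``.
    Overlapping exons within a transcript skip that gap with a warning.
    """
    seqs = _read_genome(genome)
    if not isinstance(exon_structures, Mapping):
        exon_structures = read_exon_structures(exon_structures)

    records: list[IntronRecord] = []
    for tid, (contig, strand, spans) in sorted(exon_structures.items()):
        if contig not in seqs:
            raise ValueError(f"transcript {tid}: contig {contig!r} not in genome")
        contig_seq = seqs[contig]
        clen = len(contig_seq)
        spans = sorted(spans)
        if any(s < 0 or e > clen or s >= e for s, e in spans):
            raise ValueError(f"transcript {tid}: exon coordinates outside contig")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 >= s2:
                logger.warning("transcript %s: overlapping/adjacent exons at "
                               "%d-%d / %d-%d; gap skipped", tid, s1, e1, s2, e2)
                continue
            istart, iend = e1, s2
            intron = contig_seq[istart:iend]
            up = contig_seq[max(0, e1 - flank):e1].rjust(flank, "N")
            down = contig_seq[s2:s2 + flank].ljust(flank, "N")
            if strand == "-":
                intron = str(Seq(intron).reverse_complement())
                up, down = (str(Seq(down).reverse_complement()),
                            str(Seq(up).reverse_complement()))
            records.append(IntronRecord(
                species=species, contig=contig, start=istart, end=iend,
                strand=strand, sequence=intron,
                upstream_exon_flank=up, downstream_exon_flank=down))
    return records


# ---------------------------------------------------------------------------
# quality filter


@dataclass
class FilterReport:
    n_input: int = 0
    rejected_noncanonical: int = 0
    rejected_short: int = 0
    rejected_alignment: int = 0
    n_passed: int = 0


def quality_filter(records: Sequence[IntronRecord],
                   alignment_context: Mapping[str, tuple[int, int, int, int]] | None = None,
                   min_length: int = MIN_INTRON_LENGTH,
                   ) -> tuple[list[IntronRecord], FilterReport]:
    """Apply the three intron quality criteria.

    (i) terminal dinucleotides must be GT-AG, GC-AG or AT-AC;
    (ii) length must exceed 30 nt;
    (iii) the transcript-to-genome alignment must have at most one mismatch
    and no gap within the 10 exonic positions flanking each junction.

    ``alignment_context`` maps intron_id -> (mm_5', gaps_5', mm_3', gaps_3');
    absent entries (e.g. error-free synthetic data) pass criterion (iii).
    """
    report = FilterReport(n_input=len(records))
    passed: list[IntronRecord] = []
    for rec in records:
        if rec.subtype not in SUBTYPES:
            report.rejected_noncanonical += 1
            continue
        if rec.length < min_length:
            report.rejected_short += 1
            continue
        if alignment_context is not None:
            mm5, gap5, mm3, gap3 = alignment_context.get(rec.intron_id, (0, 0, 0, 0))
            if mm5 > 1 or mm3 > 1 or gap5 > 0 or gap3 > 0:
                report.rejected_alignment += 1
                continue
        passed.append(rec)
    report.n_passed = len(passed)
    return passed, report


# ---------------------------------------------------------------------------
# de-duplication


def _identity(a: str, b: str) -> float:
    """Ungapped percent identity of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("contexts must have equal length")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def _contexts_similar(r1: IntronRecord, r2: IntronRecord,
                      threshold: float) -> bool:
    d1, a1 = r1.junction_contexts()
    d2, a2 = r2.junction_contexts()
    return _identity(d1, d2) > threshold and _identity(a1, a2) > threshold


def deduplicate(records: Sequence[IntronRecord],
                identity_threshold: float = 0.75,
                random_representative: bool = False,
                seed: int = 0) -> list[IntronRecord]:
    """Collapse groups of introns with near-identical junction contexts.

    Two introns are redundant when both of their 100-nt junction contexts
    (50 exonic + 50 intronic nt at each junction) exceed the identity
    threshold; redundancy groups are the connected components of this
    relation.  The representative is the coordinate-lexicographically
    smallest record by default, or a seeded random choice.

    All-pairs comparison with early exit; intended for per-species sets of
    up to a few thousand records (synthetic pipelines with unique introns
    can skip this step).
    """
    n = len(records)
    if n <= 1:
        return list(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # byte-encode contexts once; compare via numpy for speed
    ctx = np.zeros((n, 4 * FLANK_LEN), dtype=np.uint8)
    for i, rec in enumerate(records):
        d, a = rec.junction_contexts()
        ctx[i] = np.frombuffer((d + a).encode("ascii"), dtype=np.uint8)
    half = 2 * FLANK_LEN
    min_matches = int(np.floor(identity_threshold * half)) + 1
    for i in range(n):
        ri = find(i)
        same_d = (ctx[i + 1:, :half] == ctx[i, :half]).sum(axis=1) >= min_matches
        same_a = (ctx[i + 1:, half:] == ctx[i, half:]).sum(axis=1) >= min_matches
        for j in np.nonzero(same_d & same_a)[0] + i + 1:
            rj = find(int(j))
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    rng = np.random.default_rng(seed)
    keep: list[IntronRecord] = []
    for members in groups.values():
        if random_representative:
            pick = int(rng.choice(members))
        else:
            pick = min(members, key=lambda i: (records[i].species,
                                               records[i].contig,
                                               records[i].start))
        keep.append(records[pick])
    keep.sort(key=lambda r: (r.species, r.contig, r.start))
    return keep


# ---------------------------------------------------------------------------
# subtype tally


def subtype_tally(records: Sequence[IntronRecord]) -> pd.DataFrame:
    """Per-species counts and fractions of each terminal-dinucleotide subtype."""
    rows = [(r.species, r.subtype) for r in records]
    if not rows:
        return pd.DataFrame(columns=["species", "subtype", "count", "fraction"])
    df = pd.DataFrame(rows, columns=["species", "subtype"])
    counts = (df.groupby(["species", "subtype"]).size()
              .rename("count").reset_index())
    counts["fraction"] = counts.groupby("species")["count"].transform(
        lambda c: c / c.sum())
    return counts


# ---------------------------------------------------------------------------
# exchange format


def write_introns(records: Sequence[IntronRecord], prefix: str | Path) -> None:
    """Write the FASTA + metadata-TSV exchange pair ``<prefix>.fa`` / ``.tsv``."""
    prefix = str(prefix)
    with open(prefix + ".fa", "w") as fa:
        for rec in records:
            fa.write(f">{rec.intron_id}\n{rec.sequence}\n")
    rows = []
    for rec in records:
        rows.append({
            "intron_id": rec.intron_id, "species": rec.species,
            "contig": rec.contig, "start": rec.start, "end": rec.end,
            "strand": rec.strand, "subtype": rec.subtype, "length": rec.length,
            "upstream_exon_flank": rec.upstream_exon_flank,
            "downstream_exon_flank": rec.downstream_exon_flank,
            "interior_start": rec.interior_span[0] if rec.interior_span else "",
            "interior_end": rec.interior_span[1] if rec.interior_span else "",
        })
    pd.DataFrame(rows).to_csv(prefix + ".tsv", sep="\t", index=False)


def read_introns(prefix: str | Path) -> list[IntronRecord]:
    prefix = str(prefix)
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(prefix + ".fa", "fasta")}
    meta = pd.read_csv(prefix + ".tsv", sep="\t",
                       keep_default_na=False, dtype=str)
    records = []
    for _, row in meta.iterrows():
        interior = None
        if row.get("interior_start", "") != "":
            interior = (int(row["interior_start"]), int(row["interior_end"]))
        records.append(IntronRecord(
            species=row["species"], contig=row["contig"],
            start=int(row["start"]), end=int(row["end"]), strand=row["strand"],
            sequence=seqs[row["intron_id"]],
            upstream_exon_flank=row["upstream_exon_flank"],
            downstream_exon_flank=row["downstream_exon_flank"],
            subtype=row["subtype"], interior_span=interior))
    return records
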