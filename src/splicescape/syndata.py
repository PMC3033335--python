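"""Synthetic species with planted splicing-signal parameters.

Every downstream stage of the pipeline is validated against species whose
truth is fully known: donor/acceptor/branch-point motifs are drawn from
planted PWMs, the polypyrimidine tract from a planted length/C+T model,
intron lengths from a planted two-component Frechet mixture, intron
interiors from a planted fourth-order Markov model, and exons/intergenic
sequence from a genomic Markov model.  Introns are embedded in two-exon
genes separated by intergenic spacers so the candidate windows of the
recognition stage never cross genes.

Intron architecture (5' to 3'):

    donor 6-mer | interior (Markov) | BP heptamer | PPT | acceptor 13-mer

with the first/last two intron bases forced to the sampled subtype's
dinucleotides; the planted donor/acceptor PWM columns at those positions
equal the subtype-mixture frequencies, so empirical profiles converge to
the planted ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .intronset import FLANK_LEN, IntronRecord
from .lengths import FrechetComponent, LengthModel
from .markov import MarkovModel
from .pwm import ALPHABET, PWMProfile

MIN_INTRON = 31
FIXED_PARTS = 6 + 7 + 13     # donor + BP heptamer + acceptor motif nt
MIN_PPT = 5
EXON_LEN = 100
SPACER_LEN = 250

SUBTYPE_DINUCS = {"GT-AG": ("GT", "AG"), "GC-AG": ("GC", "AG"),
                  "AT-AC": ("AT", "AC")}
SUBTYPE_ORDER = ("GT-AG", "GC-AG", "AT-AC")


@dataclass
class SpeciesSpec:
    """Planted-truth parameters of one synthetic species."""

    name: str
    n_introns: int
    subtype_fractions: dict[str, float]
    donor_pwm: PWMProfile          # 4 x 9, positions -3..+6
    acceptor_pwm: PWMProfile       # 4 x 14, positions -13..+1
    bp_pwm: PWMProfile             # 4 x 7 heptamer
    ppt_length_mean: float
    ppt_ct_fraction: float
    length_mixture: LengthModel
    intron_markov: MarkovModel
    genome_markov: MarkovModel
    genome_gc: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_introns < 0:
            raise ValueError("n_introns must be non-negative")
        total = sum(self.subtype_fractions.get(s, 0.0) for s in SUBTYPE_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1")
        if any(v < 0 for v in self.subtype_fractions.values()):
            raise ValueError("subtype fractions must be non-negative")
        if not (0.5 < self.ppt_ct_fraction <= 1.0):
            raise ValueError("ppt_ct_fraction must lie in (0.5, 1]")
        if self.donor_pwm.width != 9 or self.acceptor_pwm.width != 14 \
                or self.bp_pwm.width != 7:
            raise ValueError("planted PWM widths must be 9/14/7")


def _pwm(cols: list[dict[str, float]], offsets: Sequence[int],
         name: str) -> PWMProfile:
    freqs = np.array([[c.get(b, 0.0) for c in cols] for b in ALPHABET])
    freqs = freqs / freqs.sum(axis=0, keepdims=True)
    return PWMProfile(freqs=freqs, offsets=tuple(offsets), name=name)


def _terminal_columns(fracs: dict[str, float]) -> tuple[np.ndarray, ...]:
    """Donor +1,+2 and acceptor -2,-1 column frequencies implied by the
    subtype mixture (GT/GC/AT donors; AG/AG/AC acceptors)."""
    gt, gc, at = (fracs.get(s, 0.0) for s in SUBTYPE_ORDER)
    d1 = np.array([at, 0.0, gt + gc, 0.0])            # G or A
    d2 = np.array([0.0, gc, 0.0, gt + at])            # T or C
    a1 = np.array([gt + gc + at, 0.0, 0.0, 0.0])      # always A
    a2 = np.array([0.0, at, gt + gc, 0.0])            # G or C
    return d1, d2, a1, a2


def sync_terminal_columns(spec: SpeciesSpec) -> SpeciesSpec:
    """Make the planted PWM terminal columns consistent with the subtype mix."""
    d1, d2, a1, a2 = _terminal_columns(spec.subtype_fractions)
    donor = spec.donor_pwm.freqs.copy()
    donor[:, 3], donor[:, 4] = d1, d2
    acceptor = spec.acceptor_pwm.freqs.copy()
    acceptor[:, 11], acceptor[:, 12] = a1, a2
    return replace(spec,
                   donor_pwm=replace(spec.donor_pwm, freqs=donor),
                   acceptor_pwm=replace(spec.acceptor_pwm, freqs=acceptor))


def default_species_spec(name: str = "synthetic", n_introns: int = 1000,
                         seed: int = 0, **overrides) -> SpeciesSpec:
    """A realistic single-celled-eukaryote-like default parameter set.

    Donor/acceptor frequencies follow the canonical eukaryotic splice-site
    consensus; the branch point is sharp (fungus-like TACTAAC) so the core
    scan accepts nearly all planted heptamers; intron interiors are
    modestly A/T-rich against a balanced genome; the length mixture has a
    tight short component near 80 nt and a heavy long tail.
    """
    fracs = overrides.pop("subtype_fractions",
                          {"GT-AG": 0.986, "GC-AG": 0.013, "AT-AC": 0.001})
    donor = _pwm([
        {"A": .33, "C": .36, "G": .19, "T": .12},   # -3
        {"A": .60, "C": .13, "G": .14, "T": .13},   # -2
        {"A": .09, "C": .05, "G": .79, "T": .07},   # -1
        {"G": 1.0},                                  # +1 (resynced)
        {"T": 1.0},                                  # +2 (resynced)
        {"A": .60, "C": .04, "G": .33, "T": .03},   # +3
        {"A": .70, "C": .08, "G": .12, "T": .10},   # +4
        {"A": .07, "C": .06, "G": .80, "T": .07},   # +5
        {"A": .16, "C": .16, "G": .20, "T": .48},   # +6
    ], (-3, -2, -1, 1, 2, 3, 4, 5, 6), "donor")
    py = {"A": .13, "C": .31, "G": .10, "T": .46}   # pyrimidine-rich interior
    acceptor = _pwm([
        py, py, py, py, py, py, py, py, py,          # -13..-5
        {"A": .24, "C": .30, "G": .21, "T": .25},   # -4
        {"A": .06, "C": .64, "G": .04, "T": .26},   # -3
        {"A": 1.0},                                  # -2 (resynced)
        {"G": 1.0},                                  # -1 (resynced)
        {"A": .24, "C": .14, "G": .49, "T": .13},   # +1
    ], tuple(range(-13, 0)) + (1,), "acceptor")
    # near-invariant TACTAAC heptamer, as in budding yeast; the planted
    # signal must dominate its window for profile recovery to be meaningful
    bp = _pwm([
        {"A": .02, "C": .015, "G": .015, "T": .95},    # -2
        {"A": .95, "C": .02, "G": .015, "T": .015},    # -1
        {"A": .002, "C": .996, "G": .001, "T": .001},  # core C
        {"A": .002, "C": .001, "G": .001, "T": .996},  # core T
        {"A": .996, "C": .002, "G": .001, "T": .001},  # core A
        {"A": .998, "C": .001, "G": .0005, "T": .0005},  # branch A
        {"A": .002, "C": .996, "G": .001, "T": .001},  # core C
    ], tuple(range(-2, 5)), "BP")
    length_mixture = overrides.pop("length_mixture", LengthModel(
        short=FrechetComponent(shape=3.0, scale=40.0, location=30.0),
        long=FrechetComponent(shape=2.0, scale=800.0, location=60.0),
        weight=0.6))
    gc = overrides.pop("genome_gc", 0.5)
    spec = SpeciesSpec(
        name=name, n_introns=n_introns, subtype_fractions=fracs,
        donor_pwm=overrides.pop("donor_pwm", donor),
        acceptor_pwm=overrides.pop("acceptor_pwm", acceptor),
        bp_pwm=overrides.pop("bp_pwm", bp),
        ppt_length_mean=overrides.pop("ppt_length_mean", 15.0),
        ppt_ct_fraction=overrides.pop("ppt_ct_fraction", 0.85),
        length_mixture=length_mixture,
        intron_markov=overrides.pop("intron_markov", MarkovModel.iid(
            np.array([0.30, 0.20, 0.20, 0.30]))),
        genome_markov=overrides.pop("genome_markov", MarkovModel.gc_biased(gc)),
        genome_gc=gc, seed=seed)
    if overrides:
        raise TypeError(f"unknown spec overrides: {sorted(overrides)}")
    return sync_terminal_columns(spec)


# ---------------------------------------------------------------------------
# generation


@dataclass
class SyntheticSpecies:
    """Generated genome + annotation + intron set of one synthetic species."""

    spec: SpeciesSpec
    genome: dict[str, str]
    introns: list[IntronRecord]
    gff3_records: list[tuple] = field(default_factory=list)

    def genome_sequences(self) -> list[str]:
        return list(self.genome.values())

    def intergenic_sequences(self) -> list[str]:
        """Spacer sequences between genes — pure genomic-model material.

        Useful for planted-truth recovery of the genomic composition
        model; a genome-wide fit also sees introns and exonic motifs.
        """
        genes = sorted((int(rec[3]) - 1, int(rec[4]))
                       for rec in self.gff3_records if rec[2] == "gene")
        out = []
        for contig_seq in self.genome.values():
            prev = 0
            for gs, ge in genes:
                if gs > prev:
                    out.append(contig_seq[prev:gs])
                prev = ge
            if prev < len(contig_seq):
                out.append(contig_seq[prev:])
        return out

    def write(self, outdir: str | Path) -> None:
        """FASTA + GFF3 + planted-truth sidecars; byte-stable per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        name = self.spec.name
        with open(outdir / f"{name}.fa", "w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        with open(outdir / f"{name}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in self.gff3_records:
                fh.write("\t".join(str(x) for x in rec) + "\n")
        self.spec.donor_pwm.to_tsv(outdir / f"{name}.donor_pwm.tsv")
        self.spec.acceptor_pwm.to_tsv(outdir / f"{name}.acceptor_pwm.tsv")
        self.spec.bp_pwm.to_tsv(outdir / f"{name}.bp_pwm.tsv")
        truth = {
            "name": name, "n_introns": self.spec.n_introns,
            "subtype_fractions": self.spec.subtype_fractions,
            "ppt_length_mean": self.spec.ppt_length_mean,
            "ppt_ct_fraction": self.spec.ppt_ct_fraction,
            "genome_gc": self.spec.genome_gc, "seed": self.spec.seed,
            "length_mixture": {
                "weight_short": self.spec.length_mixture.weight,
                "short": vars(self.spec.length_mixture.short),
                "long": vars(self.spec.length_mixture.long)},
        }
        with open(outdir / f"{name}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _sample_pwm_rows(pwm: PWMProfile, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    cols = []
    for j in range(pwm.width):
        p = pwm.freqs[:, j]
        cols.append(rng.choice(4, size=n, p=p / p.sum()))
    return np.stack(cols, axis=1)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(k)] for k in codes)


def generate_species(spec: SpeciesSpec) -> SyntheticSpecies:
    """Sample one species; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_introns
    contig = "chr1"
    if n == 0:
        genome_seq = spec.genome_markov.sample(2 * SPACER_LEN, rng)
        return SyntheticSpecies(spec=spec, genome={contig: genome_seq},
                                introns=[], gff3_records=[])

    fracs = np.array([spec.subtype_fractions.get(s, 0.0)
                      for s in SUBTYPE_ORDER])
    subtype_idx = rng.choice(len(SUBTYPE_ORDER), size=n, p=fracs / fracs.sum())
    lengths = spec.length_mixture.sample(n, rng, min_length=MIN_INTRON)

    ppt_draw = np.rint(rng.normal(spec.ppt_length_mean,
                                  spec.ppt_length_mean / 4.0, size=n))
    ppt_lens = np.clip(ppt_draw, MIN_PPT,
                       lengths - FIXED_PARTS).astype(np.int64)
    interior_lens = (lengths - FIXED_PARTS - ppt_lens).astype(np.int64)

    donors = _sample_pwm_rows(spec.donor_pwm, n, rng)
    acceptors = _sample_pwm_rows(spec.acceptor_pwm, n, rng)
    bps = _sample_pwm_rows(spec.bp_pwm, n, rng)

    # force terminal dinucleotides to the sampled subtype
    d_codes = {s: [ALPHABET.index(b) for b in SUBTYPE_DINUCS[s][0]]
               for s in SUBTYPE_ORDER}
    a_codes = {s: [ALPHABET.index(b) for b in SUBTYPE_DINUCS[s][1]]
               for s in SUBTYPE_ORDER}
    for i, si in enumerate(subtype_idx):
        st = SUBTYPE_ORDER[si]
        donors[i, 3], donors[i, 4] = d_codes[st]
        acceptors[i, 11], acceptors[i, 12] = a_codes[st]

    # PPT bases: pyrimidine with prob ct_fraction, C/T and A/G equiprobable
    total_ppt = int(ppt_lens.sum())
    is_py = rng.random(total_ppt) < spec.ppt_ct_fraction
    half = rng.random(total_ppt) < 0.5
    ppt_pool = np.where(is_py, np.where(half, 1, 3), np.where(half, 0, 2))

    interiors = spec.intron_markov.sample_many(
        [int(x) for x in interior_lens], rng)
    # genomic material: leading spacer, then per gene exonA-core, exonB-core,
    # spacer — a single batched draw for determinism and speed
    gen_lengths = [SPACER_LEN]
    for _ in range(n):
        gen_lengths += [EXON_LEN - 3, EXON_LEN - 1, SPACER_LEN]
    genomic = spec.genome_markov.sample_many(gen_lengths, rng)

    parts: list[str] = [genomic[0]]
    pos = SPACER_LEN
    introns: list[IntronRecord] = []
    gff3: list[tuple] = []
    ppt_off = 0
    for i in range(n):
        st = SUBTYPE_ORDER[subtype_idx[i]]
        exon_a = genomic[1 + 3 * i] + _codes_to_str(donors[i, :3])
        exon_b = _codes_to_str(acceptors[i, 13:]) + genomic[2 + 3 * i]
        ppt_seq = _codes_to_str(ppt_pool[ppt_off:ppt_off + ppt_lens[i]])
        ppt_off += int(ppt_lens[i])
        intron_seq = (_codes_to_str(donors[i, 3:]) + interiors[i] +
                      _codes_to_str(bps[i]) + ppt_seq +
                      _codes_to_str(acceptors[i, :13]))
        assert len(intron_seq) == lengths[i]

        gene_start = pos
        istart = gene_start + EXON_LEN
        iend = istart + int(lengths[i])
        gene_end = iend + EXON_LEN
        parts += [exon_a, intron_seq, exon_b, genomic[3 + 3 * i]]
        pos = gene_end + SPACER_LEN

        introns.append(IntronRecord(
            species=spec.name, contig=contig, start=istart, end=iend,
            strand="+", sequence=intron_seq,
            upstream_exon_flank=exon_a[-FLANK_LEN:],
            downstream_exon_flank=exon_b[:FLANK_LEN],
            subtype=st,
            interior_span=(6, 6 + int(interior_lens[i]))))

        gid, tid = f"gene{i:06d}", f"t{i:06d}"
        # GFF3 is 1-based inclusive
        gff3.append((contig, "splicescape_sim", "gene", gene_start + 1,
                     gene_end, ".", "+", ".", f"ID={gid}"))
        gff3.append((contig, "splicescape_sim", "mRNA", gene_start + 1,
                     gene_end, ".", "+", ".", f"ID={tid};Parent={gid}"))
        gff3.append((contig, "splicescape_sim", "exon", gene_start + 1,
                     istart, ".", "+", ".", f"ID={tid}.e1;Parent={tid}"))
        gff3.append((contig, "splicescape_sim", "exon", iend + 1,
                     gene_end, ".", "+", ".", f"ID={tid}.e2;Parent={tid}"))

    genome = {contig: "".join(parts)}
    return SyntheticSpecies(spec=spec, genome=genome, introns=introns,
                            gff3_records=gff3)


# ---------------------------------------------------------------------------
# hierarchical clade generation


def _perturb_simplex(p: np.ndarray, mag: float,
                     rng: np.random.Generator) -> np.ndarray:
    q = p * np.exp(mag * rng.standard_normal(p.shape))
    s = q.sum(axis=0) if q.ndim > 1 else q.sum()
    return q / s


def perturb_spec(spec: SpeciesSpec, mag: float,
                 rng: np.random.Generator) -> SpeciesSpec:
    """One drift step: multiplicative log-normal noise on every planted
    distribution, scaled by ``mag`` (0 = identity)."""
    if mag == 0.0:
        return spec
    new_fracs_arr = _perturb_simplex(
        np.array([spec.subtype_fractions.get(s, 0.0) for s in SUBTYPE_ORDER]),
        mag, rng)
    fracs = dict(zip(SUBTYPE_ORDER, (float(x) for x in new_fracs_arr)))

    def pert_pwm(pwm: PWMProfile) -> PWMProfile:
        return replace(pwm, freqs=_perturb_simplex(pwm.freqs, mag, rng))

    mix = spec.length_mixture
    scale_noise = np.exp(0.2 * mag * rng.standard_normal(4))
    new_mix = LengthModel(
        short=FrechetComponent(shape=mix.short.shape * scale_noise[0],
                               scale=mix.short.scale * scale_noise[1],
                               location=mix.short.location),
        long=FrechetComponent(shape=mix.long.shape * scale_noise[2],
                              scale=mix.long.scale * scale_noise[3],
                              location=mix.long.location),
        weight=float(np.clip(mix.weight * np.exp(0.2 * mag *
                                                 rng.standard_normal()),
                             0.02, 0.98)))
    cond = _perturb_simplex(spec.intron_markov.cond.T, 0.5 * mag, rng).T
    ct = spec.ppt_ct_fraction
    q = np.clip(2 * (ct - 0.5), 1e-6, 1 - 1e-6)
    logit = np.log(q / (1 - q)) + mag * rng.standard_normal()
    new_ct = 0.5 + 0.5 / (1 + np.exp(-logit))
    out = replace(spec,
                  subtype_fractions=fracs,
                  donor_pwm=pert_pwm(spec.donor_pwm),
                  acceptor_pwm=pert_pwm(spec.acceptor_pwm),
                  bp_pwm=pert_pwm(spec.bp_pwm),
                  ppt_length_mean=float(spec.ppt_length_mean *
                                        np.exp(0.2 * mag * rng.standard_normal())),
                  ppt_ct_fraction=float(min(new_ct, 1.0)),
                  length_mixture=new_mix,
                  intron_markov=MarkovModel(cond=cond))
    return sync_terminal_columns(out)


def generate_clade(base_spec: SpeciesSpec, guide: dict,
                   seed: int = 0) -> list[SpeciesSpec]:
    """Hierarchically drifted species specs along a guide topology.

    ``guide`` nodes are dicts: internal nodes carry ``{"drift": m,
    "children": [...]}`` and leaves ``{"drift": m, "name": label}``; the
    drift magnitude of an edge perturbs every planted distribution of the
    parent's spec before recursing.  Species sharing a recent ancestor
    therefore have smaller expected profile divergence than distant pairs.
    """
    rng = np.random.default_rng(seed)
    leaves: list[SpeciesSpec] = []

    def walk(node: dict, spec: SpeciesSpec) -> None:
        if not isinstance(node, dict) or ("children" not in node and
                                          "name" not in node):
            raise ValueError("malformed guide topology node")
        drifted = perturb_spec(spec, float(node.get("drift", 0.0)), rng)
        if "name" in node:
            leaves.append(replace(
                drifted, name=str(node["name"]),
                seed=int((seed + 1009 * (len(leaves) + 1)) % (2 ** 31))))
        else:
            for child in node["children"]:
                walk(child, drifted)

    walk(guide, base_spec)
    return leaves


def two_clade_guide(n_per_clade: int = 4, inter_drift: float = 0.6,
                    intra_drift: float = 0.05,
                    prefixes: tuple[str, str] = ("A", "B")) -> dict:
    """Guide topology for two clades of closely related species."""
    def clade(prefix: str) -> dict:
        return {"drift": inter_drift,
                "children": [{"drift": intra_drift, "name": f"{prefix}{k}"}
                             for k in range(1, n_per_clade + 1)]}
    return {"drift": 0.0, "children": [clade(prefixes[0]), clade(prefixes[1])]}
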