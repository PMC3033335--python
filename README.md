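# splicescape

Comparative analysis of the sequence features by which spliceosomal introns
are recognised: splice-site motifs, branch point (BP), polypyrimidine tract
(PPT), intron length, and oligomer composition.

`splicescape` is aimed at researchers studying the evolution of RNA splicing
signals across eukaryotes and at developers of gene-finding tools who need
per-species splicing-feature models.  Given a genome plus transcript exon
structures per species (or its built-in synthetic-species generator), it

1. extracts, quality-filters and de-duplicates introns and classifies them
   by terminal dinucleotides (GT-AG / GC-AG / AT-AC);
2. detects the PPT and BP in each intron and builds species-level motif
   profiles (donor 4×9, acceptor 4×14, BP 4×7 position weight matrices);
3. computes five per-intron information scores (bits);
4. measures inter-species divergence per feature and builds UPGMA feature
   trees, with a permutation test of their discordance from reference trees;
5. decomposes short-intron recognition accuracy into per-feature information
   contributions and an information deficit;
6. calls U12-type (minor-spliceosome) introns and clusters species by their
   contribution patterns (PCA + k-means).

## The scores and statistics

**Motif scores.** A motif with per-position base frequencies `f(k, j)` is
scored against the genomic background `F(k)` as a log-odds PWM,

    pwm(k, j) = log2((f(k,j) + ε) / (F(k) + ε)),      ε = 1e-4,

and a sequence window scores `IS = Σ_j pwm(s_j, j)`.  The information
content of a profile is its relative entropy `Σ_j Σ_k f log2(f/F)`.

**PPT.** Within 50 nt upstream of the 3'ss, a backward scan from the last
pyrimidine dinucleotide accumulates +1.0 per pyrimidine and −1.5 per purine,
stops when the score drops ≥ 2 below its running maximum, and places the
tract start at the maximal score.  A tract under 50% C+T means "no PPT".

**BP.** Core 5-mers starting upstream of the PPT start (within 100 nt of
the 3'ss) are scored with a 4×5 core matrix; the best position is accepted
when it exceeds 1.85 bits, and the accepted 5-mer plus its upstream 2-mer
(a heptamer) feeds the species 4×7 BP profile.

**Length.** Intron lengths follow a two-component Fréchet mixture
`f(l) = π F(l; α₁, σ₁, m₁) + (1−π) F(l; α₂, σ₂, m₂)` fitted by maximum
likelihood (EM); the length score is `log2(f(l)/c)` against the uniform
competitor `c = 1/(L_max − L_min)` with `L_min = 30` and `L_max` the 99%
quantile of the long component.

**Composition.** Intronic vs genomic homogeneous fourth-order Markov models
(≈ 5-mer statistics) give `IS_comp = log2(P_I(s)/P_G(s)) / l` in bits/nt.

**Divergence and trees.** Feature divergence between species A and B is a
symmetrised Kullback–Leibler-style difference in expected cognate vs
heterologous motif score, `Σ (f−g)(log2(f/F) − log2(g/G))` (terminal
dinucleotide columns excluded for splice sites); length models are compared
by symmetric KL of their discrete densities on the common range.  UPGMA
trees per feature are compared with reference topologies by the RMSD of
nodal matrices (counts of internal nodes between leaf pairs) against a
leaf-label permutation null.

**Recognition decomposition.** For each short intron, all canonical
candidate splice pairs within ±100 nt are scored with a feature subset
(always containing both splice sites); the accuracy `Ac` is the fraction of
introns whose true pair wins.  `TAc = −log2(1−Ac)` makes gains additive in
bits; the contribution of BP/length/composition is the clipped TAc gain
over splice sites alone, and the information deficit is
`−log2(0.02) − max TAc`, the gap to 98% accuracy.

## Worked example

Simulate a species with planted signals, extract its introns back from the
FASTA + GFF3, and score them:

```bash
splicescape simulate --name demo --n-introns 120 --seed 4 --outdir sim
splicescape extract --genome sim/demo.fa --annot sim/demo.gff3 \
    --species demo --out extracted
splicescape score --introns extracted --genome sim/demo.fa --out scores.tsv
splicescape contributions --introns extracted --genome sim/demo.fa \
    --out contrib.tsv
```

which prints

```
wrote 120 introns to sim
120 extracted, 120 passed (noncanonical 0, short 0, alignment 0)
scored 120 introns -> scores.tsv
decomposed recognition over 54 short introns -> contrib.tsv
```

`scores.tsv` holds the five information scores per intron:

```
intron_id             IS_5ss   IS_3ss   IS_BP    IS_length  IS_composition
demo|chr1:350-415(+)  8.79     5.68     8.55     6.55       0.024
demo|chr1:865-989(+)  12.34    7.89     6.46     3.27       0.015
```

The first intron's donor window matches the species donor profile at
8.79 bits over genomic background; its detected BP heptamer scores
8.55 bits; its 65-nt length is 6.55 bits more likely under the fitted
mixture than under a uniform length model.  `contrib.tsv` begins

```
quantity  key              value
Ac        5ss+3ss          0.8148
Ac        5ss+3ss+BP       0.8148
Ac        5ss+3ss+length   0.8704
```

i.e. with splice-site scores alone 81.5% of the 54 short introns are
located exactly among all candidate splice pairs, and adding the length
score raises this to 87.0% — a positive length contribution of
`−log2(1−0.870) + log2(1−0.815) ≈ 0.51` bits.

The same operations are available as library calls (`generate_species`,
`extract_introns`, `build_species_profiles`, `score_table`,
`contribution_decomposition`, ...); see the module docstrings.

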