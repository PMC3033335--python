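# Methods

This note records the models implemented in `splicescape`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Signal detection

**PPT scan.** The polypyrimidine tract is searched in the 50 nt upstream
of the 3' splice site, *excluding* the terminal AG/AC dinucleotide (that
dinucleotide belongs to the 3'ss motif; the window is therefore positions
−3…−52 from the intron end).  The scan anchors at the 3'-most pyrimidine
dinucleotide in the window, walks 5'-ward accumulating +1.0 per C/T and
−1.5 per A/G, and stops once the score falls 2.0 or more below its running
maximum.  The tract start is the 5'-most position attaining the maximum
(ties resolve to the longest tract).  A tract with C+T fraction below 0.5,
or a window with no pyrimidine dinucleotide, yields "no PPT".  Window
length, terminal exclusion, stop drop and the C+T floor are parameters of
`find_ppt`.

**BP scan.** A functional branch point is assumed to precede a functional
PPT, so by default no PPT means no BP call (`require_ppt=False` scans the
whole window).  Candidate core 5-mers are those whose *start* position
lies upstream of the detected PPT start and within 100 nt of the 3'ss;
the 5-mer itself may overlap the tract.  This matters: the trailing
pyrimidines of a real BP heptamer (e.g. the final C of TACTAAC) are
routinely absorbed into the detected PPT, and requiring the whole 5-mer
to clear the tract would make such branch points undetectable.  The
maximal-scoring 5-mer is accepted if it exceeds 1.85 bits under the 4×5
core matrix; ties resolve to the 3'-most position, mirroring the
biological placement of the BP near the PPT.  The packaged core matrix is
a synthetic CTAAC-consensus default (data, not code); substitute an
organism-specific matrix via `--core-bp`/`PWMProfile.from_tsv`.

**Splice-site profiles.** Donor windows cover positions −3…+6 around the
exon|intron junction (4×9), acceptor windows −13…+1 around intron|exon
(4×14), aligned gap-lessly on the junction.  The background is the
strand-symmetrised genome-wide mononucleotide composition.  Introns with
insufficient flank or fewer intronic nucleotides than the motif window are
skipped with a logged count.

## Scores

Log-odds PWM entries use a pseudo-count ε = 1e-4 inside both numerator and
denominator.  Information content is computed with raw frequencies
(`0·log 0 = 0`; a zero background entry is guarded with ε), so the exact
identities IC(f=F) = 0 and IC(one-hot, uniform) = 2 bits/column hold to
machine precision.

**Length model.** Fréchet components are parameterised (shape α, scale σ,
location m) with density zero at or below m.  Fitting is EM: quantile
splits (50/70/85%) initialise the two components, each weighted
component step maximises the likelihood numerically (Nelder–Mead on
log-transformed α, σ and a bounded logit for m < min(data)), and the best
converged restart wins.  The discrete density assigns CDF mass of
[l, l+1) to integer l, renormalised on [L_min, L_max) with L_min = 30 and
L_max the 99% quantile of the fitted long component.  Degenerate input
(all lengths equal) is rejected.  Out-of-range lengths receive the most
penalised in-range score with a flag, keeping candidate comparison total.
The location of a heavy long component is weakly identified (essentially
no draws fall near it); identifiable functionals — shapes, scales, weight
and L_max — are what recovery tests should assert.

**Short-intron threshold.** The per-species fitted short components are
discretised on a common grid, averaged with equal species weights, and the
95% quantile of the average is reported.  Pipelines default to a fixed
250 nt unless the data-driven threshold is requested.

**Composition.** Both intronic and genomic models are homogeneous
fourth-order Markov chains; the first four positions of a sequence are
scored with ramp-up tables of orders 0–3 derived from the stationary law
of the chain.  The per-intron score divides by the full intron length,
terminal dinucleotides included.  Stationary 5-mer probabilities (for the
composition divergence) come from the stationary distribution over 4-mer
contexts (power iteration) extended by one conditional step.

## Divergences and trees

Motif divergence is computed as `Σ (f−g)·(pwm_A − pwm_B)` over retained
columns with each species' ε-smoothed cognate log-odds; this form makes
the self-divergence exactly zero while matching the expected-score
difference reading of the definition.  Terminal dinucleotide columns
(donor +1/+2, acceptor −2/−1) are excluded for splice sites.  The measure
is not guaranteed non-negative; negative values are reported as-is and
clipped to zero (with a warning) only when a matrix feeds UPGMA.  Length
divergence renormalises both discrete densities on the common range
[L_min, min(L_max_A, L_max_B)) — without renormalisation the sum is not a
divergence of distributions — and floors densities at 1e-12 against
underflow of the Fréchet tail.

UPGMA is implemented directly (average linkage, heights = d/2) so that
tie-breaking is deterministic: the minimal pair with the lexicographically
smallest label pair merges first.  scipy's average-linkage heights serve
as an independent cross-check in the tests.  Nodal matrices count internal
nodes on each leaf-pair path (a multifurcation counts once).  Tree
discordance is the mean nodal RMSD against the reference trees; the null
permutes leaf labels on the fixed feature-tree topology.  Alongside the
normal-tail p-value, an exact permutation rank p-value is reported, since
100 permutations cannot support tail probabilities far below 1/100.

## Recognition decomposition

Candidate pairs obey GY–AG / AT–AC pairing with implied length in
[31, threshold]; the evaluation region extends up to 100 nt into each
exon flank (shorter flanks truncate it).  Candidate BP/PPT scores are
recomputed on the candidate's own implied intron; candidate splice-site
windows running off the region are N-padded (missing columns score 0).
Prediction takes the highest-scoring pair; ties resolve to the 5'-most
donor, then the 5'-most acceptor.  TAc uses base 2, so deficits are in
bits; TAc saturates at the necessary amount (−log2 0.02 ≈ 5.644 bits)
when Ac = 1.

All feature subsets contain both splice sites, so individual 5'ss and
3'ss contributions are not separable from the subset scheme; the joint
TAc(5+3) is split between them in proportion to their profile information
contents.  This split is a reporting convention, not part of the
measurement.  The absolute deficit is `necessary − max TAc` (floored at
0).  Because subsets can act synergistically, attributed contributions
plus that deficit need not equal the necessary amount exactly; the
*share* vector therefore sets the deficit share to one minus the
attributed shares (renormalising in the saturated case), so shares always
sum to 1.

## Synthetic species generator

Each intron is assembled as: donor 6-mer | Markov interior | BP heptamer |
PPT | acceptor 13-mer, with terminal dinucleotides forced to the sampled
subtype and the planted donor/acceptor PWM columns at those positions set
to the subtype-mixture frequencies (so empirical profiles converge to the
planted matrices).  Lengths are mixture draws resampled below 31 nt; the
PPT length is a clipped normal draw (mean 15 nt, sd mean/4, floor 5 nt)
with each base pyrimidine with probability `ppt_ct_fraction` (C/T and A/G
equiprobable within their class).  Introns sit in two-exon genes (100 nt
exons) separated by 250 nt intergenic spacers, so recognition windows
never cross genes; genes are emitted on the plus strand of a single
contig (strand handling is exercised by the extractor's own tests).
Output (FASTA, GFF3, truth sidecars) is byte-identical for identical spec
and seed.

Default parameters describe a compact-genome eukaryote: subtype fractions
0.986/0.013/0.001, canonical donor/acceptor consensus frequencies, a
near-invariant TACTAAC branch point (as in budding yeast), PPT mean 15 nt
at 85% C+T, length mixture π = 0.6, α = (3, 2), σ = (40, 800),
m = (30, 60), modestly A/T-rich intron interiors against a balanced
genome.  The near-invariant BP default is deliberate: profile recovery
tests are only meaningful when the planted signal dominates its scan
window.  With a weak (mammalian-style) planted BP — available via
overrides — a substantial fraction of scans land on decoy 5-mers, and the
estimated profile then describes *detected* signals rather than the
planted matrix; that behaviour is faithful to the detection method and is
the main caveat when interpreting BP profiles of weak-BP species.

Hierarchical clades perturb every planted distribution with multiplicative
log-normal noise along guide-topology edges (PWM columns and Markov rows
renormalised; mixture scales/shapes and PPT parameters drifted on a 0.2×
scale; the genomic model held fixed across the clade), then re-sync the
terminal PWM columns with the drifted subtype fractions.

What the generator does not emulate: alternative splicing, alignment or
sequencing error, transcript-coverage noise, position-dependent interior
composition, splicing enhancers/silencers, or realistic gene structure
beyond two exons.  Passing recovery tests therefore demonstrate
correctness of the estimators under the planted model, not performance on
real genomes with their messier signal-to-noise structure.

## Problem sizes used in validation

Recovery tests use one 20,000-intron species (total-variation 0.02/column
for PWMs, 10% relative error for identifiable Fréchet parameters,
0.05 bits mean absolute for 5-mer log-odds, with the genomic model fit on
intergenic spacers — a genome-wide fit would measure the realised genome
mixture, introns included, rather than the planted genomic model).
Clade/tree tests use 2×4-species clades at 250 introns per species over
20 seeded runs; recognition tests use 2,000 short introns per species;
U12 and clustering tests use 300–400 introns and 30 species-profiles
respectively.  The oracle-equivalence suite replays each scanning
primitive against an independent brute-force implementation on 10,000
random instances.
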