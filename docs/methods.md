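# Methods

This package reconstructs, as testable code, the inference chain used to
detect *Theobroma cacao* (and its relative *Herrania*) ancient DNA in
ceramic-residue sequencing libraries and to assign that DNA to reference
genetic groups, together with the methylxanthine (theobromine /
theophylline / caffeine) chemical evidence it is crossed with. Because
the real residue libraries are external data, every stage is exercised
against a synthetic generator whose statistical structure mirrors the
real analysis conditions and whose ground truth is retained.

## Synthetic data generator (`paleocacao.simulate`)

**Reference panel.** Group allele frequencies follow a Balding–Nichols
hierarchy: the ancestral alternate frequency at each locus is
Uniform(0.05, 0.95) and each group's frequency is Beta-distributed around
it with FST equal to the `divergence` parameter (default 0.15, a typical
between-group differentiation for structured crop populations).
Accession genotypes are Binomial(2, p<sub>k,l</sub>). The default
11-group panel reproduces the reference collection's composition — 76
accessions split 8/8/8/8/7/4/7/7/4/8/7 across Criollo, Caqueta, Curaray,
Nacional, Purus, Contamana, Marañon, Iquitos, Amelonado, Nanay and
Guiana. Admixed individuals draw each of two allele copies per locus
from group k with probability q<sub>k</sub>, then Bernoulli(p<sub>k,l</sub>).

**Fragmentation.** Fragment lengths are log-normal truncated to
[30 bp, contig length]. The log-scale sigma (`length_shape`, default
0.35) is a free parameter — only the mean is observable from the study
conditions — and the log-normal location is calibrated numerically
(bisection on the closed-form truncated mean) so the *truncated* law has
arithmetic mean exactly `length_mean` (default 81.65 bp). Break points
are placed so the odds that the genomic base immediately 5' of a
fragment start is a purine are multiplied by `depurination_bias`
(default 2), giving the closed-form purine fraction
bπ/(bπ+1−π) at offset −1. Only the start break carries the bias; the
read-orientation 5' enrichment over a mixed-strand library is therefore
the average of the biased and unbiased ends, ~(bπ/(bπ+1−π)/π + 1)/2.

**Deamination.** Double-strand library chemistry: a C at 5' distance i
(read orientation) becomes T with probability delta0·lambda^i, and
symmetrically G→A from the 3' end. `delta0` defaults to 0.05, inside the
4–5.5% terminal band the real libraries show; `lambda` (default 0.5) is
a free parameter — real decay is only shown qualitatively — chosen so the
signal is confined to the first ~8 bases, as in typical single-strand
overhang profiles. Geometric decay gives the testable ratio property
rate(0)/rate(1) = 1/lambda.

**Libraries.** Paired 2×150 reads; fragments shorter than 150 bp read
through into a fixed 33-mer adapter and are padded with G (the no-signal
call of two-channel chemistry) at `#` quality. Base qualities are a
constant Q37 so the trimming stages are exactly predictable.
Contaminant read pairs are drawn from non-target genomes at
`contamination_fraction` with the same fragmentation and damage model
(environmental DNA in a residue is itself old). A per-read truth table
(taxon, coordinates, strand, damage count) accompanies every library.

**Methylxanthines.** Item amounts are a two-component log-normal
mixture: an ambient-contamination background with median
`background_scale` (default 60 pg/sample, support essentially below
200 pg) and a true-positive component with median `positive_scale`
(default 7000 pg, support above 700 pg), with a shared latent factor
giving cross-analyte correlation 0.7. Defaults keep the components
separated the way the real value distributions are; overlapping scales
warn rather than fail.

**What the generator does not emulate:** sequencing miscalls beyond
deamination, indel damage, capture-enrichment bias, variable quality
strings, PCR duplicates with errors, and taxonomically structured
metagenomic backgrounds (contaminants are independent genomes). Passing
tests therefore demonstrate correctness of the inference chain under the
stated statistical model, not robustness to every artefact of real
residue data.

## Read processing (`paleocacao.readproc`)

Trim → merge → deduplicate → entropy-filter, with exact accounting
(unit: sequences; each stage's input count equals the previous output).
Trimming removes adapter read-through by exact/overlap match and then
strips bases below Q20 from both ends inward (a deliberately transparent
end-trimming rule rather than a running-sum heuristic); reads under
30 nt are discarded. Merging reverse-complements the second mate and
accepts the overlap (≥10 nt) with the lowest mismatch density ≤0.25,
ties to the longer overlap, resolving disagreements to the
higher-quality call. Deduplication collapses exact sequence duplicates
only — one mismatch is a different sequence. The entropy filter removes
reads containing any 50-base window whose 5-mer Shannon entropy,
normalized by log(min(4^5, 46)), falls below 0.7; a homopolymer scores
0, a dinucleotide repeat log2/log46 ≈ 0.18, random sequence ≈ 1.
Unmerged pairs are retained as two single-end sequences (config switch
`keep_unmerged`), maximizing usable molecules.

## Taxonomic assignment (`paleocacao.taxassign`)

Alignment is explicit Smith–Waterman with affine gaps
(match +1, mismatch −1, open −2, extend −1; N matches nothing). The DP
is row-vectorized in numpy; the within-row reference-gap state is
resolved by a prefix-max accumulate, which is exact whenever
gap_open ≤ gap_extend ≤ 0 (asserted). All tied optimal start and end
positions are reported (starts from the same recurrence on the reversed
pair), which is what the unique-mapping rule consumes.

The focal prefilter keeps a read when its best local score on either
strand reaches 0.9 × read length — loose enough to pass ~5% terminal
deamination on 80-mers, tight enough that random 80-mers essentially
never pass against multi-kilobase references. Best-hit classification
takes the maximal score over all database records and both strands; an
exact score tie between different taxa makes the read ambiguous and it
is assigned to nothing (the conservative reading of a "first hit").
An item is positive for a taxon when at least five *distinct* sequences
(exact identity, counted after deduplication) have their first hit
there; four distinct sequences are negative.

## Damage authentication (`paleocacao.damage`)

Mis-incorporation rates are counted per reference base over the first
25 positions from each end (reverse-strand fragments re-oriented first);
positions with no reference C (or G) are reported as missing rather
than zero. End composition covers offsets −2..+1 around both termini in
read orientation, with contig-edge flanks skipped and denominators
adjusted. The amplifiable fraction is the survival function of the
length distribution at each amplicon length (66/197/290/543 bp by
default), and the predicted Ct shift assumes perfect per-cycle doubling
— a declared simplification of the qPCR picture.

The composite verdict formalizes the usual visual inspection: authentic
iff (terminal C→T rate) / (median rate at positions 10–24) ≥ 3, purine
enrichment at 5' offset −1 ≥ 1.1, and mean length ≤ 120 bp; every
threshold is overridable, evidence is always reported, and an optional
fragment-bootstrap CI that straddles the ratio threshold marks the
verdict inconclusive. The decay parameters are recovered by a log-linear
fit of the first ten 5' rates weighted by sqrt(observed event counts),
so near-empty tail positions cannot dominate.

## SNP extraction (`paleocacao.snpcall`)

Fragments must map to exactly one best-scoring location on the focal
genome (both strands pooled). Covered panel loci yield one observation
each, with end distances measured on the read as sequenced. The
terminal-damage filter removes an observation only when it is within
five bases of an end *and* matches the damage pattern there (observed T
at a C/T locus near the 5' end; observed A at a G/A locus near the 3'
end, allele pairs taken in read orientation); all other terminal
observations are kept. Observations matching neither panel allele are
discarded and their fraction reported — on damaged simulations this
lands in the low single-digit percent range. The two filters act on
disjoint criteria, so their composition order is immaterial (property-
tested). Per-locus evidence collapses to dosage 0 / 0.5 / 1 (all-ref,
mixed, all-alt) — the simplest representation that exposes
heterozygosity to the admixture model while acknowledging that a
handful of fragments cannot estimate allele balance. Items with fewer
than 20 covered loci are ineligible for ancestry analyses.

## Ancestry inference (`paleocacao.popgen`)

**Supervised admixture.** With labelled reference groups, membership
proportions are the maximum-likelihood mixture weights of the model
P(allele) = Σ<sub>k</sub> q<sub>k</sub> p<sub>k,l</sub> per allele copy.
EM iterates responsibilities and simplex-renormalized means; the
log-likelihood is concave in q, non-decreasing per iteration (asserted
at every step), and the optimum is initialization-independent. Group
frequencies are clipped to [ε, 1−ε] with ε = 1/(2n<sub>k</sub>+1) so a
private allele in a four-accession group cannot contribute −∞. This
replaces unsupervised MCMC clustering: the target quantity (per-item
membership proportions against known groups) is identical, while the
estimator is deterministic and fast, and no K-sweep is needed. A pair
of groups the item draws ancestry from is flagged ambiguous when
swapping their estimated proportions costs less than 2 log-likelihood
units — the analogue of two reference groups a sparse item cannot
distinguish; both attributions are then reported.

**Distances and trees.** Nei's (1978) small-sample-unbiased distance
D = −ln(J<sub>xy</sub>/√(J<sub>x</sub>J<sub>y</sub>)) uses unbiased
within-population identities (2n·hom−1)/(2n−1); sampling-induced small
negatives clamp to 0. An archaeological item enters as a
pseudo-population of size 1. Individual-level structure uses the
allele-sharing dissimilarity (mean |dosage difference| over loci typed
in both), neighbor joining (scikit-bio's Saitou–Nei implementation,
negative branch lengths clamped to zero), and locus-bootstrap support:
loci resampled with replacement per replicate, support = % of replicates
containing each internal bipartition, replicate RNG streams derived
from a single seed.

## Methylxanthine calls (`paleocacao.chem`)

Positivity is strict: value > 700 pg/sample (a value of exactly 700 is
negative), applied per analyte; sub-threshold values are reported as 0
in output tables. The background break is located on log10-sorted
values below the 95th percentile as the largest gap between consecutive
values; the reported quantities are the gap's geometric midpoint and
its edges — the lower edge is the top of the ambient-contamination
cluster (~200 pg on study-shaped data). A largest gap under 0.3 log10
units (~2×) is treated as no break. Concordance between chemistry and
aDNA presence is a per-analyte 2×2 over the items analyzed by both
methods, with percentages in both directions rounded half-up to integer
(one-decimal values alongside).

## Problem sizes and numerical choices

Stochastic checks run at the sizes the analyses are specified at:
20,000 fragments for damage-model recovery (terminal rate ±0.01, mean
length within 2 SE), 50 simulated items over an 11-group panel
(divergence 0.15, 100–500 loci) for ancestry recovery (mean absolute
error ≤ 0.08 per component), and 20 independent pure-contaminant
libraries for negative-control behaviour. Unit tests use smaller
fixtures (20 kb focal genome, 300 random reads against 30 kb for the
prefilter rejection rate, 22 accessions × 150 replicates for bootstrap
clade support) — these sizes are the package's own test-design choice;
the properties they check are size-stable. EM convergence is
Δlog-likelihood < 1e-8 (max 1000 iterations; the few runs that reach the
cap are within ~1e-3 of the optimum in q). Alignment scores are exact
integers in float arithmetic; determinism everywhere comes from
explicit numpy Generator seeding, with child streams drawn from a
single master seed.

## Known limitations

Single-source recovery at 500 loci / FST 0.15 concentrates ~0.85–1.0 of
the mass on the true group depending on the genotype draw: the residual
spread is a property of the MLE with related groups, not an estimator
defect, and the tests assert it distributionally. Best-hit
classification over whole-genome records has no E-value model — it is a
score comparison, appropriate for the small curated taxon sets it is
designed for, not for open-ended databases. The unique-mapping rule
enumerates exact score ties only; near-ties (score within 1) are kept.
The qPCR Ct model ignores amplification efficiency below 1. The damage
model is substitution-only; indels and strand-specific (single-strand
library) asymmetries are out of scope.
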