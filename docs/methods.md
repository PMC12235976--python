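# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
places where the design was genuinely open.

## Sequence model and coordinates

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted only at I/O. Minus-strand genes are loaded in
transcription orientation (exons ordered 5′→3′ along the mRNA, sequences
reverse-complemented), so every downstream step — exon-pair selection,
alignment, primer design — reasons on the transcribed strand. Genotype
matrices follow the GenAlEx co-dominant CSV layout; allele tokens are the
amplicon length in bp, with `length.variant` suffixes distinguishing
equal-length sequence variants and `0` for missing. This stays readable by
length-based tools while preserving sequence-level alleles.

## SSR scanning

Only perfect (uninterrupted) tandem repeats count. A run is the maximal
period-p stretch of a read (an `N` or a mismatch to the base p positions
earlier breaks it); its repeat number is ⌊stretch/p⌋ and its span starts at
the stretch's left edge, which makes the scanner's output phase-unambiguous
and lets a brute-force per-position enumeration serve as an exact oracle.
Units that are themselves periodic (ACAC as a 4-mer) are reported at their
smallest period only; homopolymers are not mined. Defaults are the study
thresholds: ≥10 repeats for 2-mers, ≥8 for 3-mers, ≥4 for 4/5-mers, both
flanks strictly longer than 20 bp. Motifs are canonicalized by the
lexicographically minimal rotation on the read strand only — no
reverse-complement merging, because primer design operates on the read as
sequenced. Downstream primer design consumes only 4/5-mer candidates
(shorter units slip too readily during PCR); the scanner still reports all
classes for summary counts, where a read counts once per unit-length class.

## EPIC mining

Exon pairs qualify when both exons exceed 20 bp and the intervening intron
is under 400 bp, both strict, as worded in the protocol; a feasibility check
also requires that some primer placement can give a 425–470 bp product
(shortest product = intron + 2×18 bp of primer, longest = both exons plus
intron). Placement on the target genome replaces an interactive BLAST step
with a deterministic procedure: exact 15-mer seeds from the 5′ exon (both
strands), nearby seed diagonals collapsed, then local affine-gap alignment
(match +1, mismatch −2, gap open −5, extend −2; Biopython's
`PairwiseAligner` does the extension) in a ±50 bp window. The region is
extended rightwards by 1.5× the donor intron plus the 3′ exon, and the 3′
exon is re-aligned inside the extension. A mapping is rejected when either
exon aligns below 70 % identity over 80 % of its length, and when the two
best 5′-exon placements score identically the locus is dropped as a
duplication suspect (logged as "ambiguous placement"). Conservation for
primer placement means 100 % identity: conserved windows are maximal runs of
identical, gap-free alignment columns of at least 18 bp (the minimum primer
length), restricted to exon footprints. Splice isoforms are not reconciled
(first annotated transcript per gene); within a gene all qualifying pairs
are emitted and ranking is left to the caller.

## Primer design

Melting temperatures are nearest-neighbor values under the unified
SantaLucia parameter set at 50 mM monovalent salt and 250 nM oligo with the
entropy salt correction, computed through Biopython; a hand-summed ΔH/ΔS
oracle in the test suite pins the implementation. The thermodynamic model
behind the original interactive design tool is not specified anywhere, so
the individual-primer acceptance band is set to 55 ± 3 °C alongside the
stated pairwise |ΔTm| < 5 °C. "One to two G/C pairs at both ends" is read
as the common GC-clamp: the count of G/C bases among the two terminal
positions at each primer end must be 1 or 2. Pairs are ranked by summed
|Tm − 55|, then |product − 450| bp, then the 5′-most forward position — an
explicit tie-break standing in for interactive choice. The read-based
duplication screen counts shotgun reads containing a full-length primer
match (either strand, ≤1 substitution) and discards primers with more than
one supporting read; as worded this passes zero-support primers, so a
`min_support` option exists but defaults to off. The genome screen requires
exactly one exact hit per primer, inward-facing at a product-compatible
distance; zero hits flags contamination, multiple hits duplication. Adapter
tails are the two fixed partial Illumina sequences prepended 5′ of the
locus-specific primers; re-tailing raises.

## Allele calling

Read pairs merge over the best ungapped 3′ overlap of at least 20 bp with a
mismatch fraction ≤ 0.1; disagreements resolve to the higher-quality base.
The overlap is located by exact 20-mer seeds from the reverse-complemented
mate (three seed windows), with an exhaustive scan as fallback, so the
"best overlap" semantics hold even when seeds fail. Demultiplexing assigns
a merged read to the unique panel locus whose forward primer matches the 5′
end and whose reverse-complemented reverse primer matches the 3′ end, each
within 2 substitutions; reads matching primers of different loci are binned
as chimeric. Per-sample index demultiplexing is assumed done upstream by
the sequencing facility.

The calling thresholds are disclosed, configurable stand-ins for an
external pipeline whose internals are not published: sequences within edit
distance 1 of a ≥10× more abundant sequence fold into it (sequencing
error); with a known repeat unit, sequences exactly one unit shorter than a
more abundant sequence and below 0.5× its count fold into it as stutter
(the edit distance must also equal the unit length, so an unrelated
equal-length allele is never folded); remaining sequences need ≥10 reads to
be candidates; the runner-up becomes the second allele when its count is at
least 0.25× the top count, and a third candidate above that ratio flags the
call as ambiguous. Variant ids are assigned per locus after all samples are
called: a length with a single sequence variant keeps id 0, lengths with
several variants number them by descending total called depth, then
lexicographic sequence — stable across reruns.

The study filter cascade runs in a fixed order — samples with > 30 %
missing markers, then markers missing in > 30 % of the *remaining* samples,
then markers monomorphic across the whole dataset, then populations under
five individuals — with missingness denominators recomputed from the
current matrix at each stage. The ordering is observable: a marker whose
missingness is concentrated in bad samples survives sample-first filtering
but not marker-first, and a test pins this. "Missing" means no genotype
call emitted, the only operational reading available. The cascade is
idempotent.

## Population genetics

He is plain gene diversity 1 − Σp² and Ne = 1/Σp² (no small-sample
correction), matching the summary statistics convention of the GenAlEx
lineage of tools; means ± SE across loci use sd/√L with L the loci typed in
that population. HWE is the chi-square goodness-of-fit over all k(k+1)/2
genotype classes with df = k(k−1)/2, no pooling of rare classes and no
multiple-testing correction; deviation counts use α = 0.05. The chi-square
is asymptotic — with rare alleles at small n its type-I error drifts, which
is why the calibration check runs at n = 200 with balanced alleles.

Pairwise F_ST ships in two estimators because the upstream tooling is
ambiguous about which one the published tables used. The default Nei-style
estimator takes per locus Hs as the unweighted mean of the two populations'
He and Ht as the He of the mean allele-frequency vector, and forms the
ratio of sums across loci, clamped at ≥ 0. Weir–Cockerham θ (1984 variance
components, summed over alleles and loci) is the alternative; θ is the one
whose expectation equals the Balding–Nichols F, so the drift-tracking
checks use it (the two-deme Nei form has expectation ≈ F/2 by
construction). Loci with under two typed individuals in either population
are skipped by θ.

Null alleles are estimated per (population, locus) by EM on allele
frequencies augmented with a null allele under Hardy–Weinberg: visible
heterozygotes are observed directly, an observed i/i homozygote splits in
the E-step into true i/i versus i/null in proportion p_i : 2r, and blank
individuals are null homozygotes. By default blanks enter the likelihood
(`include_blanks=True`); the alternative conditions the likelihood on a
visible genotype (dividing class probabilities by 1 − r²), mirroring the
two conventions of the standard null-allele tool. Initialisation is
observed allele frequencies scaled by (1 − r₀) with r₀ = 0.1; convergence
is a parameter change below 1e-8 within 1000 iterations, and the
log-likelihood is asserted non-decreasing every step. Markers are flagged
per population when r̂ > 0.2 strictly, and globally only when every
population with an estimate exceeds the threshold.

## Clustering

DAPC one-hot expands the matrix into individual × allele counts (0/1/2),
mean-imputes missing cells per column (the default behaviour of the
standard DAPC implementation), centers, and takes principal axes from an
SVD — 4 by default, reduced with a warning when the design has lower rank.
Linear discriminant analysis with pooled within-group covariance runs on
the retained scores (scikit-learn), with at most min(groups − 1, n_pca)
discriminant axes; membership probabilities are the Gaussian class
posteriors. Axis signs are fixed by forcing the largest-magnitude loading
positive, so runs are reproducible. When the pooled within-group scatter is
exactly zero (fully separated synthetic clusters) the Gaussian model is
singular and the fit falls back to nearest-centroid assignment with hard
memberships. Downsampling draws a seeded uniform sample of five individuals
from every group *larger* than five (groups at or below the target stay
whole, matching the protocol wording). Evanno's
ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) consumes a
generic K → log-likelihood table from any admixture program; it needs at
least three consecutive K and two runs per K, reports ΔK as undefined where
the run-to-run sd is zero, and exposes the argmax without further
automatic model choice. The admixture MCMC itself is an external tool and
is deliberately not reimplemented.

## Synthetic data

`simulate_genotypes` draws per-locus ancestral frequencies from a symmetric
Dirichlet(1), per-population frequencies from the Balding–Nichols
distribution (Dirichlet with concentration p(1 − F)/F; F = 0 short-circuits
to the ancestral vector), and diploid genotypes under within-population
HWE. Null alleles act per transmitted copy at `null_rate`: null/null cells
become missing, null/visible cells appear as visible homozygotes; extra
missingness is independent at `missing_rate`. The Balding–Nichols choice
over an explicit coalescent is deliberate: its single parameter maps
directly to expected F_ST, which is the property the checks need. The
default scale mirrors the emulated study design — five populations of 6,
5, 9, 5, 16 individuals and 30 loci.

Allele sequences are built as flank + unit×k + flank with k varying between
alleles, so length and sequence variation are both exercised; about 30 % of
loci replace one allele with a same-length SNP variant to exercise
sequence-only discrimination. `simulate_amplicons` wraps allele cores in
panel primers, draws depth from a negative binomial (mean 100×, dispersion
10 by default, or constant when dispersion is None — the study itself
averaged ~1000×, but 100× sits far above every calling threshold and keeps
fixture runs in seconds), splits reads binomially between alleles, applies
per-base substitution errors, and emits stutter reads one unit shorter at
`stutter_rate`. `simulate_genome_pair` plants two-exon genes (a configured
subset satisfying the EPIC criteria, the rest violating exactly one
criterion each), mutates exons/introns/spacers at separate divergences, and
plants SSR motifs with periodicity deliberately broken at both boundaries
so planted coordinates are exact. All generators are bit-reproducible under
a fixed seed, and truth records carry every latent quantity needed to score
the pipeline.

What the generators do **not** emulate: indel sequencing errors, PCR
chimeras, cross-sample contamination, primer-binding-site mutations as the
*mechanism* of null alleles (nulls are injected at the genotype level),
linkage, demographic history (bottlenecks, admixture), or splice isoforms.
Passing tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to every artefact of real libraries.

## Problem sizes and tolerances in the checks

The end-to-end recovery check runs 41 samples × 10 loci at constant 50×
depth with zero error — small enough to finish in seconds, large enough
that every filter and labelling path is exercised. EM recovery uses 100
replicates of n = 500 at r ∈ {0, 0.1, 0.3} (±0.03 on the mean); the HWE
calibration 10,000 replicates at n = 200 (±0.01 around α); drift tracking
six replicates of two demes × 100 individuals × 100 loci per F (±0.02);
the scanner oracle 1,000 random 300 nt reads; genome mining a ~12 kb toy
pair against an exhaustive local-alignment oracle. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch under a
caller-supplied seed.

## Known limitations

- The caller's thresholds are sensible defaults, not fitted values; real
  datasets may need tuning (all are exposed and logged).
- Nei-vs-θ estimator choice changes pairwise F_ST by several hundredths on
  small samples; both are reported rather than adjudicated.
- The EPIC miner assumes the homologous intron is within 1.5× the donor
  intron length; strongly expanded target introns will fail the 3′-exon
  search window.
- Multiplex pool assignment and cross-dimer thermodynamics are out of
  scope; primer pooling should go through a dedicated external tool.
- The chi-square HWE test is unreliable for many rare alleles at small n;
  an exact test is not provided.
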