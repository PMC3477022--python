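# Methods

This note documents the models, parameters and numerical conventions behind
`stagewave`: what each computation assumes, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## The measurement model

The unit of observation is a read count `n_ij` for contig *i* in cDNA
library *j*, one library per fruit age (0, 4, 8, 12, 16 days post
pollination by default; multiple libraries per age are supported and
aggregate within age). Counts are treated as a multinomial draw per
library: sequencing throughput is fixed per library, and a contig's
probability of capturing a read is proportional to its transcript
abundance. Expression comparisons therefore use **transcripts per
thousand**, `TPT_ij = 1000 n_ij / N_j` with `N_j` the library total —
computed over the *full* matrix, before any filtering, so the denominator
is the total number of reads generated for the library and each column sums
to 1000 exactly.

**Minimum-read filter.** Downstream analyses are restricted to contigs with
at least 30 reads summed across libraries (inclusive threshold,
configurable). The justification is empirical and reproduced by
`saturation_profile`: below ~30 reads/contig, assembled length and the
rate of homolog identification are still rising with coverage, so
proportion estimates are dominated by sampling noise and annotation is
unreliable. The filter uses the total across libraries, not per-library
counts, since the proportion statistic is defined on the total.

## Stage grouping

`pca_libraries` performs PCA with the five libraries as observations and
filtered contig TPT values as variables, from the **covariance** matrix
(not correlation — after TPT normalization the variables share a scale, and
covariance preserves the dominance of highly expressed contigs). It is
computed by SVD of the centred 5 × p matrix; variance fractions are
eigenvalues over their sum, and each component's sign is fixed by making
its largest-magnitude library coordinate positive. A between-library
variance of zero (e.g. identical libraries) yields zero fractions and a
warning rather than an error.

`group_ages` merges age-adjacent libraries in the PC1–PC2 plane by
centroid-linkage agglomeration until the requested number of groups
remains. The contiguity constraint reflects that developmental stages are
intervals of the age axis; unconstrained k-means over five points would be
seed-fragile and can return non-contiguous groups that have no
developmental reading. With three groups the default simulation yields
{0,4}, {8}, {12,16} — cell division / pre-exponential growth, peak
expansion, and late/post-exponential growth.

The Venn partition counts contigs by the set of groups in which they are
detected; "detected" means ≥ 1 read in the group (`detect_min`), the
weakest defensible notion of presence given no stated threshold.

**Open choice, resolved:** the PCA input is depth-normalized TPT rather
than raw reads. Raw counts confound library depth with biology whenever
depths differ; with equal depths the two are identical, so nothing is lost
in the balanced design.

## Proportion-of-expression statistic and module selection

For contig *i* and group *g*, `p_ig = Σ_{j∈g} TPT_ij / Σ_j TPT_ij`. Under
constant expression every library carries 1/5 of a transcript's normalized
reads, so the null vector is (#libraries in group)/5 per group — (0.40,
0.20, 0.40) for the three-group scheme. Portions are computed from TPT for
the same depth-confounding reason as the PCA (a raw-read mode exists in the
arithmetic but is not the default); contigs with zero total expression in
the analysis set are excluded with a warning.

`tail_sets` selects, per group, the `ceil(q·N)` contigs with the largest
`p_ig` (default q = 0.025). Ties are broken deterministically: larger
portion, then more total reads, then lexicographically smaller contig id.
Disjointness of the three tails is a *finding*, reported not enforced; an
`assign_argmax` helper resolves overlaps to the max-portion group when a
partition is needed.

`top_represented` uses raw read pools: a contig's share of group *g* is its
reads there over the group's total reads, and the module lists are contigs
with share > 0.1%, with exclusive sublists per group and the list common to
all groups (housekeeping-dominated, by construction of the generator).

## Homology tiers and unknown function

`classify_tier` is a total cascade over best-hit-per-query BLAST records:
Arabidopsis hit passing the E-value threshold → `arabidopsis`; else a
passing green-plant hit outside the cucurbit genera → `other_plant`; else
passing hits only within cucurbit genera → `cucurbit_only`; else `no_hit`.
The threshold defaults to 1e-5 (no canonical value exists; the weakest hit
in the packaged cucurbit-only table, 1.0e-25, passes with a wide margin).
Cucurbit genera default to {Cucumis, Cucurbita, Citrullus, Momordica},
matched against the subject taxon's genus; the set is configurable. A
passing nr hit without a subject taxon is an error, since the cascade
cannot proceed without it.

A contig is **unknown-function** iff it is `no_hit`, or its best
description is the "No hits found" sentinel or contains "unknown" or
"hypothetical" (case-insensitive). Including "hypothetical" is deliberate:
uncharacterized cross-species hits carry no functional information, and the
rule as stated reproduces all three printed counts of the packaged
age-group tables (14/27, 5/21, 1/21). Named-but-uncharacterized genes
(e.g. "MEE59") are *not* flagged; the rule is lexical, and making it
stricter breaks the 8-dpp block count.

## K-means and GO enrichment

`kmeans_profiles` clusters per-age portion vectors (5 values summing to 1)
so that expression *shape* rather than magnitude drives membership.
Lloyd's algorithm with Euclidean distance is implemented directly:
convergence when the maximum centroid shift drops below 1e-8 or after 300
iterations, best of 25 restarts by inertia, empty clusters re-seeded from
the farthest point. The per-iteration inertia trace of the winning restart
is returned; inertia is non-increasing along it, which the tests assert.
k defaults to 10, roughly the number of age and age-pair shape classes a
five-point profile supports (each single age, each adjacent pair, flat).

`go_enrichment` works on flat, multi-label GO classes (no DAG
propagation). For category *c*: normalized frequency = (fraction of the
set annotated to *c*) / (genome fraction of *c*); bootstrap SD is the SD of
that statistic over `n_boot = 100` resamples of the set with replacement;
the p-value is hypergeometric (upper tail for enrichment, lower for
depletion, two-sided reported as min(2·tail, 1)), with the category's
genome count recovered as `round(fraction × genome_size)`. The exact
p-value convention of legacy web tools is undocumented, so the
hypergeometric choice is recorded in the output columns (`p_upper`,
`p_lower` alongside `p_value`). Raw p-values are reported; no
multiple-testing correction is applied, matching the practice of shading
categories at P < 0.05.

## Validation utilities

`est_relative_expression` computes fold changes of TPT at each age against
the 0-dpp baseline (14 genes × 4 ages = 56 comparisons in the worked
example). A zero baseline gets a pseudo-count of 0.5 reads in every
library before normalization, for the fold computation only, and is
flagged per gene. `concordance` is Pearson's r on log2 folds (log
stabilizes multiplicative error; a linear-scale option exists), reporting
R² = r²; zero-variance inputs return NaN with a `degenerate` flag.

`chlorophyll_total` evaluates the linear spectrophotometric form
`c647·A647 + c665·A665`, scaled by extract volume over sample mass. The
shipped coefficient set (`"dmf"`: 17.67, 7.12 µg/ml) is the published
N,N-dimethylformamide method; the original report does not print its
coefficients, so the set is named configuration that appears in output
metadata, and any coefficient pair can be supplied.

## The synthetic-data generator

`generate_counts` emulates the *statistical* structure of the five-library
study, not its sequences: no reads, no assembly, no error model.

* **Programs.** Each contig belongs to one of six latent stage programs
  (probabilities `program_mix`): division (age weights 1, 1, 0.05, 0.01,
  0.01), photosynthesis (0.5, 1, 0.3, 0.05, 0.05), expansion (0.02, 0.1,
  1, 0.3, 0.1), surface/phloem (0.01, 0.05, 1, 0.8, 0.6), stress (0.02,
  0.05, 0.2, 1, 1) and flat housekeeping. A contig's true age-proportion
  vector is its program's normalized weights; these are the recovery
  targets.
* **Abundance and allocation.** Base abundances are lognormal (σ = 1.5),
  giving the heavy-tailed reads/contig distribution real EST sets show and
  a well-defined >0.1%-of-pool top tier. Within each library, reads are
  allocated multinomially over contigs with probabilities ∝ base × age
  weight, conditional on the configured depth — column sums are exact.
  (A Poisson mode exists for unconditional sampling; it is not the
  default.) Default depths are 226,000 per library (~1.13M reads total,
  the emulated study's scale); the per-library split is not published, so
  equal depths are assumed and configurable. The test suite and analysis
  scripts run the generator at 5,000 contigs × 5 × 50,000 reads, a size
  chosen to keep every property of interest measurable while the full
  suite runs in seconds.
* **Program mix.** Defaults are (0.015, 0.15, 0.22, 0.15, 0.18, 0.285).
  The division program is the only one whose true single-group proportion
  exceeds 0.9 (0.966 at 0+4), and its share is set at 1.5% so that the
  strongly stage-specific class is a *rare planted signal*, smaller than
  the 2.5% tail that is supposed to recover it — at the desk scale above,
  ~20–30 filtered division contigs against a tail capacity of ~42. A
  materially larger share makes ≥80% recovery arithmetically impossible
  (the tail cannot hold the class), which is a statement about tail
  selection, not about the data; the mix was sized once at design time on
  that argument.
* **Lengths.** Expected length is `100 + 1300·(1 − exp(−reads/8))` bp plus
  Gaussian noise (SD 120, floor 40 bp): rising steadily to ~30 reads and
  saturating at 1400 bp, with overall mean length near the high hundreds
  at a median of ~7–15 reads/contig. Zero noise reproduces the curve
  exactly.
* **Annotation tiers.** True tiers are drawn per program (division/
  photosynthesis/housekeeping mostly Arabidopsis-tier; expansion and
  surface/phloem with elevated cucurbit-only mass, mirroring where
  cucurbit-specific transcripts concentrate). Observed tiers pass through
  a detection censor: a contig's homolog is found with probability
  `1 − exp(−reads/6)`, so the observed Arabidopsis rate climbs with
  coverage and saturates at the program mix's asymptote — this is what the
  saturation profile measures. Consequence: χ²-style checks of tier
  frequencies against `tier_probs` must use the *true* tiers in
  `SyntheticTruth`; observed frequencies are biased low at low coverage by
  design.
* **qPCR.** Pseudo-measurements are TPT ratios to the 0-dpp baseline times
  lognormal noise, `2^N(0, σ)` with σ = 0.25 by default on the log2 scale.
  Zero-noise draws equal the TPT ratios exactly, so pipeline concordance is
  R² = 1 by construction — a plumbing identity, not a scientific result.
* **GO map.** `generate_go_map` assigns SuperViewer-style flat classes to
  informative Arabidopsis-tier contigs with program-dependent tilts
  (division → cell organization / DNA-RNA metabolism, stress → stress
  responses and transcription factors, etc.) over a fixed genome-frequency
  table, so stage modules show the qualitatively expected enrichments.

**What passing tests show, and what they do not.** The generator draws
counts from exactly the multinomial family the statistics assume, with
independent contigs, no overdispersion between biological replicates, no
assembly artifacts (chimeras, split contigs), and tier labels independent
of expression given the program. Recovery results (stage groups found in
≥90% of seeds, ≥80% of planted stage-specific contigs in the right tail,
disjoint tails, two components carrying >80% of library variance)
therefore certify the *pipeline's* correctness and statistical behaviour
under the intended model — they do not certify that real EST data satisfy
that model, and real-data quantities (overall variance explained, qPCR R²
of 0.85–0.91) are properties of the deposited libraries that desk-scale
simulation can only parallel qualitatively.

## Determinism

A single integer seed governs each generator call; sub-streams (counts,
lengths, tiers, qPCR, GO) are derived via `SeedSequence([seed, k])`. The
pipeline derives per-stage seeds by stable hashing of the stage name
(CRC32, reduced mod 2³¹), so a rerun of the same configuration is
byte-identical, which the tests verify file by file.

## Known limitations

* Five points is the floor for a library-level PCA; variance fractions are
  noisy by nature and the contiguity-constrained grouping is what makes
  the stage assignment stable.
* The unknown-function rule is lexical; descriptions that are
  uninformative without saying "unknown"/"hypothetical" are not flagged.
* GO enrichment assumes the genome background fractions are exact, and the
  bootstrap SD reflects set-resampling variability only.
* The generator plants one strongly stage-specific class (division); the
  8-dpp and 12+16-dpp programs are realistic but below the 90%
  single-group threshold, so tail recovery is exercised primarily on the
  0+4 group.
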