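# Methods

This note records the models implemented in `geosig`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Channel schemas and classification

Mutations are classified into the field's standard channel schemas.

**SBS-96.** Single-base substitutions in trinucleotide context,
canonicalized to a pyrimidine reference: a purine-reference substitution is
reverse-complemented together with both flanking bases. Channel order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), context-minor (5' base,
then 3' base, each A/C/G/T). **SBS-288** crosses each SBS-96 channel with
the transcriptional strand of the pyrimidine (T transcribed, U
untranscribed, N unknown). Unknown strand gets its own bucket rather than
being folded into T or U, so strand-bias summaries are never silently
diluted; collapsing to SBS-96 drops the N bucket by default (a
`drop_unknown=False` switch conserves totals instead). The two-base-flank
(1536-channel) refinement is not implemented: every downstream analysis
here operates on 96 channels.

**DBS-78.** Doublet substitutions where both positions change. The ten
canonical reference doublets are AC, AT, CC, CG, CT, GC, TA, TC, TG, TT;
non-canonical references are reverse-complemented, and for the four
palindromic references the alt orientation is the lexicographically smaller
of alt and its reverse complement. This generates exactly 78 channels; the
test suite verifies by enumeration that the 144 stranded doublets cover
them with reverse-complement pairs merged.

**ID-83.** Indels are consumed VCF-style (left-aligned, anchor base
included) and the anchor is stripped before classification. 1-bp events are
binned by the pyrimidine-canonicalized base and the homopolymer run at the
site; deletion categories count copies of the deleted base *including* the
deleted copy (1..6+), insertion categories count copies already present
(0..5+). Longer events are binned by tandem copies of the indel'd unit with
the same including/excluding convention. Deletions of ≥2 bp with no full
extra copy of the unit but partial-unit homology — the longest of the
5'-suffix and 3'-prefix matches, capped at 5 — go to the microhomology
channels. These conventions reproduce the standard 83-channel dialect and
are verified against an in-repo exhaustive oracle over unit lengths 1–6,
run lengths 0–7 and homology 0–5; they are the package's fixed definition
of the schema rather than an attempt to byte-match any external tool.

Classification consumes flanking context carried on the record itself
(≥1 nt for substitutions, ≥10 nt per side for indels), which keeps every
test and simulation free of genome downloads; a FASTA-backed context
provider serves real VCFs. Records that cannot be classified (ambiguous
context bases, complex indels, wrong variant type for the schema) are
skipped and logged, and catalogue column sums equal the classified count
per sample by construction.

## De novo extraction

`SignatureExtraction` implements consensus NMF:

1. **Replicates.** Each replicate Poisson-resamples the catalogue entrywise
   (mean = observed count) and renormalizes hypermutators: columns whose
   total exceeds `factor_cap` (default 10) × the median column total are
   rescaled down to that cap, with per-sample scale factors recorded. The
   cap rule is a deliberate, testable stand-in for more elaborate mixture
   modelling of hypermutators; its purpose is only to bound any single
   sample's leverage on the factorization.
2. **Factorization.** Multiplicative updates under generalized KL
   divergence; the objective is non-increasing at every update pair (a
   property the tests assert on random Poisson matrices). Initialization is
   NNDSVD with zero entries replaced by the smallest positive value of the
   matrix, making each replicate deterministic given its resampled input.
   Defaults: `tol = 1e-8` (relative objective change), `max_iter = 10,000`,
   pseudocount `1e-12` on all-zero channel rows. W columns are normalized
   to sum 1 post hoc with the scale absorbed into H.
3. **Consensus.** For each k, replicate signatures are pooled and
   partitioned into k clusters with the constraint of one signature per
   replicate per cluster, enforced exactly by solving a k×k assignment
   problem per replicate inside a k-means-style loop under cosine distance
   (default 100 restarts). Per-signature stability is the mean silhouette
   width of its cluster (cosine metric); for k = 1 it is the mean cosine to
   the centroid. The consensus signature is the normalized centroid.
4. **Selection.** `selected_k` is the largest k whose mean stability is
   ≥ `s_min` (0.8) and whose every per-signature stability is ≥ `s_sig`
   (0.2), with degenerate solutions (empty clusters) never eligible; if no
   k qualifies, the most stable k is reported. Reconstruction error (mean
   per-sample relative L2 of an NNLS refit) is reported per k for
   diagnosis.

Replicates default to 100 for desk use; the conventional production setting
of 500 is a constructor argument away. The scan range defaults to k = 1..20.

A note on identifiability that the tests make explicit: when every sample
carries every signature at interior proportions, the KL optimum is a ridge —
profiles can mix by up to the minimum exposure ratio without changing the
fit. Recovery to cosine ≥ 0.95 therefore presumes cohorts in which each
signature is absent (or nearly so) in some samples, which is exactly the
prevalence structure multi-country cohorts exhibit.

## Reference decomposition

`decompose` expresses a de novo profile over a reference catalogue by
greedy forward selection (add the reference with the largest reconstruction
cosine gain while the gain exceeds `add_thresh` = 0.01), backward pruning
(drop any reference whose removal costs < `remove_thresh` = 0.01), and a
final NNLS refit on the retained set. A final cosine below
`novelty_cosine` = 0.8 flags the signature as novel. Thresholds are
configurable; forced co-inclusion rules for biologically paired reference
signatures are out of scope. The reference catalogue is user-supplied
(COSMIC-dialect CSV); tests use synthetic reference sets.

## Attribution

`SignatureAttribution` fits each sample independently:

- **Point estimate.** NNLS against the panel, then backward elimination:
  repeatedly refit without each retained signature and remove the one whose
  absence costs the least L2 similarity, while that cost is at most the
  per-schema penalty (SBS 0.008, DBS 0.014, ID 0.03 — the values suggested
  by simulation studies of false-positive attribution); ties break toward
  the earliest panel position, and at least one signature is always kept.
  L2 similarity is defined on raw counts as 1 − ‖v − v̂‖₂/‖v‖₂. If NNLS
  overshoots (Σe > total), exposures are rescaled to the total so
  stacked-proportion displays and the per-sample unassigned fraction
  (total − Σe ≥ 0) are well formed.
- **Uncertainty.** A parametric bootstrap (default `n_boot` = 200,
  α = 0.05): each replicate Poisson-resamples the spectrum channelwise and
  reruns the *full* selection, not just the refit, so a signature pruned in
  a replicate contributes zero and a lower CI limit of zero is a meaningful
  absence signal. CIs are empirical percentile intervals of replicate
  exposures; presence = both limits positive. Percentile (not
  bias-corrected) intervals are used and documented as such.

Calibration measured by the acceptance suite at the study's conditions
(burden 5,000, planted exposure 2,000, 200 bootstrap replicates): CI
coverage within 88–99%, and the lower limit is zero for non-generating
signatures in ≥95% of samples.

## Statistical layer

- **Dichotomization.** Presence/absence by the CI rule; signatures present
  in ≥75% of cases are instead split at the cohort median of attributed
  counts (near-ubiquitous signatures carry no information in presence
  space).
- **Risk-factor regressions.** Logistic regression of the binary outcome on
  the factor with sex, age at diagnosis, country and tobacco status as
  covariates (categoricals factorized). Raw p values are reported with the
  Bonferroni family size recorded alongside rather than applied. Perfect
  separation falls back to an L2-penalized fit, flagged, with no Wald p.
- **ASR regressions.** OLS of a burden or attribution on country-level ASR
  plus sex and age; single-country cohorts are rejected since ASR is then
  constant.
- **Country burden comparison.** Kruskal–Wallis across countries per
  mutation type — a rank test, chosen because somatic burdens are
  heavy-tailed; countries with fewer than 2 samples are excluded.
- **Multiple testing.** Benjamini–Hochberg step-up q values; the exact
  Wilcoxon signed-rank null is used for small tie-free samples and the
  tie-corrected normal approximation otherwise, with all-zero difference
  vectors returning p = 1 (vacuous test). Driver-spectrum enrichment uses
  the two-sided Fisher exact test on the (target class vs other) ×
  (exposed vs unexposed) table; exposure labels come from the CI presence
  rule of an aristolochic-acid-like signature.
- **Clonal timing.** Samples pass, in order: purity ≥ 0.40; clusters with
  CCF > 1.5 or with chromosome X as top mutation contributor dropped as
  artifacts; ≥ 256 clonal and ≥ 256 subclonal mutations; no subclone with
  CCF > 0.80; at least one clone and one subclone remaining. Every
  threshold is independently toggleable and exclusions are logged per rule.
  Clone and subclone spectra are attributed separately, normalized by the
  cluster's mutation total, and compared per signature by the paired
  two-sided Wilcoxon test with BH correction across signatures.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes. Per
sample: the active signature set is Bernoulli per country prevalence
(optionally with odds-ratio effects of current smoking), per-signature
burdens are log-normal, and channel counts are **multinomial conditional on
the planted burden** — not independent Poisson — so ground-truth exposures
are conserved exactly and recovery error is attributable to the pipeline
(a Poisson path exists in the resampling operations where the model calls
for it). Each channel count is materialized as mutation records whose
embedded contexts classify back to exactly that channel; this inverse
classification is exhaustively verified over all 96 + 288 + 78 + 83
channels.

The default scenario mirrors the structure of the motivating 11-country
kidney-cancer cohort: the countries and their ASRs (1.8–14.5 per 100,000)
and cohort sizes (5–259, ~960 total at full scale); a T>A-dominated
signature at 70%/23%/60% prevalence in three countries and 2% elsewhere,
with high log-normal burdens; a T>C-dominated signature at 72% prevalence
in one country and 2% elsewhere; and a flat ubiquitous signature whose mean
burden is 1,500 + 150 × ASR, putting median totals in the few-thousands
range typical of these genomes. A `scale` argument shrinks per-country
sizes proportionally; tests and the acceptance script run at scales
0.06–0.5, sizes chosen as sensible desk-scale cohorts.

Clone/subclone simulation gives every sample a clone near CCF 1 and a
subclone in (0.25, 0.70], with clonal/subclonal signature mixes differing
by configurable deltas, and injects filter-violating features (low purity,
CCF > 1.5 clusters, chrX-dominant clusters, undersized or poorly separated
subclones) in configurable fractions, flagging each so the timing filters
can be checked against an exact oracle.

What the generator does **not** emulate: sequence-level realism (no reads,
alignment artifacts or germline contamination), genomic position semantics
(coordinates are bookkeeping), copy-number or structural variation,
signature profile uncertainty (planted profiles are exact), or
between-sample correlation beyond country membership. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to the full messiness of real
calls — variant-calling QC is explicitly upstream of this package.

## Numerical conventions and degenerate inputs

Zero spectra are rejected by attribution and similarity functions
(undefined), zero-count samples are skipped with a log entry by cohort
attribution, and zero channel rows receive a 1e-12 pseudocount inside NMF
only. Cosine similarity on a zero vector raises. All randomness flows
through `numpy.random.Generator` objects seeded from explicit arguments;
cohort-level operations spawn per-sample child seeds so results are
invariant to sample order. Assignment ties in consensus clustering and
pruning break deterministically (panel/centroid index order).

## Known limitations

- The hypermutator cap and the stability-based k selection rule are
  pragmatic, documented replacements for unpublished internals of the
  original toolchain; both are configurable and their defaults are chosen
  for testability, not byte-compatibility.
- Decomposition implements no curated connected-signature constraints.
- The exact Wilcoxon null assumes untied ranks; tied data use the corrected
  normal approximation even at small n.
- Attribution treats samples independently; no cohort-level regularization.
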