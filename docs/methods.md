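# Methods

This note documents the models, defaults and design choices behind
`sigdepth`. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute.

## Problem setting

A disease gene signature — the up/down differentially expressed gene
(DEG) lists of a two-group RNA-seq contrast — is only as reliable as
the sequencing run behind it. Connectivity mapping compounds the
problem: the signature is matched against a library of
perturbagen-induced expression profiles, and a distorted signature can
lose therapeutic candidates or invent spurious ones. `sigdepth`
measures that sensitivity by re-running the whole
signature-to-connections pipeline on progressively thinned counts and
summarising the stability of the significant connections.

## Depth reduction: binomial thinning

Reduced cDNA library depth is simulated at the gene-count level: entry
*n* becomes Binomial(*n*, *f*). If read-to-gene assignment is
depth-invariant, this is distributionally identical to subsampling the
mapped reads themselves, so the alignment stack never enters the
analysis — the one deliberate modelling shortcut, taken to keep the
tool desk-scale. Two consequences the tests verify: thinning composes
(thin at f₁ then f₂ ≡ thin at f₁f₂ in distribution) and the NB
dispersion parameter is preserved (mean fμ, variance fμ + α f²μ²).

Each (fraction, iteration) grid cell is a *fresh* thinning of the full
matrix; fractions are not nested within one another. Whether the
original study nested its subsamples is not documented; independent
cells treat every fraction as its own simulated experiment, which is
the design the per-fraction frequency and FDR statistics assume. The
default grid {0.01, 0.1, 0.25, 0.5, 0.7, 0.8, 0.9, 0.99, 1.0} with
K = 25 iterations is configurable.

## Differential expression

The DE stage is a deliberately transparent NB-Wald approximation of
the standard bulk RNA-seq recipe, validated by calibration and power
tests rather than by equivalence to any external engine, and pluggable
behind the `DEResult` interface.

* **Normalization.** Relative log expression (median-of-ratios) size
  factors over genes positive in every sample, rescaled to geometric
  mean 1. A matrix with no all-positive gene cannot be normalized;
  `rle_size_factors` raises, and the grid runner records such a cell
  (possible only at extreme thinning) as an empty signature.
* **Dispersion.** Raw per-gene method-of-moments
  α̂ = (pooled within-group variance − pooled mean)/pooled mean²
  (floor 10⁻⁸) is provided as `estimate_dispersions`, but at 6 + 6
  replicates it is far too noisy to plug into a Wald test: ~half the
  null genes truncate at the floor, which anti-conservatively shrinks
  their standard errors. The default pipeline therefore fits the trend
  α(μ) = a₀ + a₁/μ by non-negative least squares on the *unfloored*
  estimates (fitting only positive estimates would select noise and
  bias the trend up) and uses the trend value unless a gene's own
  estimate exceeds 3× the trend, in which case the larger per-gene
  value is kept. This is the same moderation idea used by shrinkage
  dispersion estimators in the field, reduced to a two-parameter trend.
* **Test.** lfc = log₂((μ̂_B + c₀)/(μ̂_A + c₀)) with pseudocount
  c₀ = 0.5 and delta-method variance
  se² = [(1/n_A)(1/(μ̂_A+c₀) + α) + (1/n_B)(1/(μ̂_B+c₀) + α)]/ln²2;
  two-sided normal p; genes with both group means zero get p = 1,
  lfc = 0. BH step-up adjustment. No independent filtering, no
  fold-change shrinkage, no outlier replacement — kept out to keep the
  stage auditable; these are known divergences from full-featured DE
  engines.
* **Signature filter.** padj ≤ 0.05, |lfc| ≥ 1 (log₂), at most 100
  genes per direction (smallest p first, ties to larger |lfc| then gene
  id). The thresholds behind published signature sizes are generally
  supplement material; these defaults are the package's own, are
  configurable, and are recorded in the run manifest.

## Connectivity scoring

Unit gene weights (±1), the simplest member of the sscMap score
family: raw = Σ_up z − Σ_down z, normalized by the maximum attainable
|raw| for a signature of that size (sum of the k largest |z| in the
profile), giving a score in [−1, 1] that is invariant to rescaling a
profile and antisymmetric under swapping up and down. Rank weighting is
an extension point, not implemented.

Significance: M (default 10,000) random signatures with the observed
up/down sizes drawn uniformly from the universe; two-sided p on |score|
with the add-one estimator, so p ≥ 1/(M+1). The same M null signatures
are reused for every profile of a query (common random numbers), which
stabilises cross-perturbagen comparisons and the downstream frequency
analysis. When C(|U|, k)·2ᵏ ≤ 10⁶ the null is enumerated exhaustively —
all (up-set, down-set) pairs with the observed sizes, i.e. the exact
distribution the Monte-Carlo draws estimate — and p-values are exact
proportions.

Perturbagen-level aggregation is the mean of the compound's profile
scores, tested against the mean of the same null draws, BH across
perturbagens, significant iff q ≤ 0.05. The threshold rule used by any
particular connectivity engine is generally not published; this choice
is recorded in the manifest and per-profile reporting is available
(`aggregation_level="profile"`). Direction: rev iff score < 0, prog iff
score > 0; an exactly-zero score has no direction and is never
significant.

## Enrichment (length-bias aware)

Long transcripts collect more reads and are easier to call DE, so
category enrichment of DEG sets corrects for length: a monotone
probability-weighting function (PWF) P(DE | length) feeds a Wallenius
noncentral hypergeometric test whose odds is the mean weight inside the
category over the mean weight outside; at odds 1 it reduces exactly to
the one-sided Fisher/hypergeometric test (verified to 10⁻⁶).

The PWF is a Gaussian local-linear smooth of the DE flags on length
rank (bandwidth 0.1·n) projected onto the monotone cone by isotonic
regression, then clipped to (0, 1) and renormalized to the observed DE
fraction. The smoothing step is essential: raw isotonic regression of
0/1 flags interpolates noise at the extremes (on pure-null data its
boundary blocks reach 0 or 1), whereas the local-linear pre-fit is
boundary-unbiased for sloped trends and leaves monotonicity to the
projection. No claim of equivalence to spline-based PWFs is made. The
Wallenius tail is evaluated by `scipy.stats.nchypergeom_wallenius`.
Only over-representation (upper tail) is tested.

## Stability statistics

With S_f the significant set at a thinned cell and S₁ the reference
(f = 1) set, computed separately for rev and prog:

* **relative FDR** = |S_f \ S₁| / |S_f| (0 when S_f is empty): the
  share of connections the full data never supported, treated as false
  positives *relative to the full data* — not an oracle FDR.
* **frequency** = detections / K per (perturbagen, direction);
  connections never significant are absent. At f = 1 (one
  deterministic run) every detected connection has frequency 1.
* **consensus set** at a fraction = connections with frequency ≥ 0.5
  (configurable). How per-fraction sets should be consolidated across
  iterations before Venn analysis is an open choice; a majority vote is
  the default here.
* **Venn partition** over a fraction subset (default the intersection
  of {0.01, 0.1, 0.5, 1.0} with the grid): all 2^m − 1 regions,
  pairwise disjoint and exhaustive; derived views gained(f) = S_f \ S₁,
  lost(f) = S₁ \ S_f, consistent = ∩ over all fractions.
* **top-k stability** (default k = 50): per-fraction ranking of
  strongest reversers by mean aggregate score across the fraction's
  iterations (ties to smaller mean q, then id), with pairwise overlap
  and Jaccard.
* **CIs** are percentile intervals (2.5/97.5, linear interpolation)
  across iterations — degenerate at f = 1. Whether published CI bands
  of this kind are iteration percentiles or parametric is typically
  unstated; percentile-across-iterations is this package's choice.

Determinism: one master seed expands into per-cell child seeds through
`child_seed(master, *labels)` (CRC32 of the label path as a
`SeedSequence` spawn key), so any grid cell is independently
reproducible, summaries serialize to byte-identical JSON across reruns,
and cells persisted under `--out` are skipped on resume.

## Synthetic study design

The generator replaces a patient cohort and a large profile compendium
with planted truth, at a scale where a full grid cell runs in well
under a second:

| parameter | default | why |
|---|---|---|
| genes | 2,000 | desk-scale universe; grid cells < 1 s |
| samples | 6 + 6 | a small two-arm cohort; the hard regime for dispersion estimation |
| π_DE | 0.1 | 200 planted DE genes, |log₂FC| = 2, random sign |
| dispersion trend (a₀, a₁) | (0.05, 5) | α ≈ 0.06–0.2 over the expression range, typical bulk RNA-seq |
| depth_mean | 150,000 reads/sample | see below |
| depth_cv | 0.3 | moderate library-size variation |
| library | 40 perturbagens × 3 cell lines | 8 reversers, 8 progressors, 24 nulls |
| planted effect κ | 3 | reverser/progressor profiles score ∓3·sign(β_g) + N(0,1) on planted genes |
| neuronal cell lines | 1 of 3 | exercises tag-based subsetting |

**Why depth 150,000.** The fixed planted effect (|log₂FC| = 2) makes
per-gene power a steep function of counts, unlike real cohorts whose
effect sizes shade continuously into the detection limit. For the
thinning grid to exercise the phenomenon under study — signatures
degrading with depth — the detection transition must fall *inside* the
grid: at 150,000 expected reads per sample (~75 per gene) the full data
sit comfortably above it (all planted reversers recovered), while
f = 0.01 (~0.75 reads per gene) sits below it (signatures shrink
drastically, sometimes to empty, and relative FDR becomes nonzero).
A depth chosen by naively scaling a production-scale run to the 2,000
gene universe leaves the entire grid saturated and the study
uninformative.

**What the generator does not emulate:** continuous effect-size
distributions, batch effects, isoform/length structure in the counts
(lengths enter only through the annotation generator), correlated
noise across library profiles of the same compound class, and the
heavy-tailed score distributions of real profile compendia. Passing
tests therefore demonstrate that the pipeline's statistics behave
correctly where truth is known — monotone depth trends, calibrated
nulls, exact reference-run identities — not that any particular real
cohort is robust at a given depth.

Profile noise ε is i.i.d. standard normal per profile; the noise
structure of real reference libraries is not characterized publicly,
so this model is the package's own and is flagged as such.

## Numerical choices and degenerate inputs

* BH uses the step-up cumulative-minimum form; inputs outside (0, 1]
  are rejected.
* Wald p-values are clipped to [tiny, 1]; genes with both group means
  zero are conventionally null (p = 1, lfc = 0).
* A signature that filters to empty is flagged, not an error;
  connectivity refuses it, and the grid records the cell with zero
  connections. An empty *reference* run aborts the grid — there is
  nothing to compare against.
* Zero connection score ⇒ no direction, never significant.
* `summarize_ci` of a single value returns the degenerate interval.
* Wallenius categories with no gene in the universe are skipped with a
  warning; with zero DE genes every p is 1.
* Score normalization guards max_raw = 0 (all-zero profile ⇒ score 0).

## Known limitations

* The DE stage is an approximation: no GLM designs beyond two groups,
  no covariates, no outlier handling. It is pluggable — any engine
  producing a `DEResult` can replace it.
* Relative FDR measures agreement with the full-data run, not truth;
  with planted truth available the synthetic tests also check genuine
  misclassification (progressors never called rev).
* Binary GCTX, FASTQ/SAM/BAM and ontology parsing are out of scope;
  supported formats are TSV, GMT/GRP and the GCT 1.3 text dialect.
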