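# Methods

This note records the models, algorithms and design choices behind
`proteoflow`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and provenance

All stages operate on a `QuantMatrix`: a features × samples matrix bound to
a sample/condition/replicate design, on a declared scale (`raw`, `log2` or
`glog2`). Missing values are `NaN` throughout; the MaxQuant wide dialect's
`0` and the string tokens `NA`/`NaN`/`Filtered` are mapped to missing at
ingest, and absent (feature, sample) pairs in long DIA reports become
missing on reshaping. Every mutating stage appends exactly one history
record (operation, parameters, features in/out); the pipeline serialises
this history into `run_log.json`, from which the human-readable report is
regenerated verbatim. Per-stage random seeds are forked from the single
global seed by hashing the stage name, so inserting a stage never perturbs
the random streams of later stages.

## Filtering

Reverse-database hits and potential contaminants are dropped when a flag
column holds `"+"`. Missing-occupancy filtering defaults to the
per-condition rule with threshold 0 — a feature is kept iff it is fully
observed in at least one condition — which favours features whose absence
is itself condition-dependent (candidate on/off regulation) over features
missing haphazardly everywhere. An overall-observed-fraction mode is
available.

## Variance-stabilizing normalization

The calibration model is a per-sample affine transform followed by a
generalised log:

    h_i(x) = glog2((x − a_i) / b_i),   glog2(y) = log2(y + √(y² + 1)).

Under the standard two-component error model (multiplicative noise
dominating at high intensity, additive noise at low intensity) this
transform renders the variance of a feature approximately independent of
its mean; for x ≫ b the transform converges to log2, so differences of
transformed values are log2 ratios.

Fitting maximises the profiled Gaussian likelihood (feature means and the
common variance profiled out; the transform's Jacobian included) over
(a_i, log b_i) with analytic gradients via L-BFGS. The coordinate-wise
updates of this likelihood have no closed form, so a quasi-Newton fit is
used; it is wrapped in a least-trimmed-squares loop that refits on the 90%
of features with the smallest mean squared residual until the trimmed set
stabilises, protecting the calibration against genuinely differential
features. Degenerate inputs with an exact fit (e.g. duplicated samples,
where the profiled likelihood is unbounded) are detected by a vanishing
residual and returned as-is. Inputs are pre-scaled by their global median
so the optimizer works on O(1) numbers; the parameters are rescaled back.
The benchmark in the test suite shows the low/high-intensity decile ratio
of row SDs collapsing from >3 (raw log scale) to <1.5 after the transform.
A simple per-sample median centering on the log2 scale is provided as a
light-weight alternative; VSN is the default.

## Imputation

Missingness in label-free data mixes left-censoring at the detection limit
(MNAR) and stochastic loss (MAR). Methods, all column-wise because
detection limits are run-specific:

| method         | assumption | semantics                                                        |
|----------------|-----------|-------------------------------------------------------------------|
| `left-shifted` | MNAR      | Normal(mean_s − shift·sd_s, (width·sd_s)²); defaults 1.8 / 0.3    |
| `min-det`      | MNAR      | per-sample quantile of observed values (default q = 0.01)         |
| `min-prob`     | MNAR      | Normal centred at that quantile, SD = width·sd_s                  |
| `knn`          | MAR       | mean of k nearest features with complete overlap on observed cols |
| `zero`         | —         | literal zero                                                      |

The shift/width defaults are the downshifted-Gaussian convention
popularised by Perseus. knn distance is squared Euclidean over shared
columns divided by the number of shared columns, ties broken by feature
order; a row with no eligible neighbour falls back to its own mean, which
is recorded in the history. All draws come from one seeded generator and
cells are filled in row-major order, so output is a pure function of
(matrix, spec, seed). Observed cells are never touched.

## Peptide-to-protein aggregation

The peptide pipeline imputes at the peptide level first and then
summarises each protein group, bypassing upstream software's summaries.

* **Median polish** sweeps row and column medians alternately until the
  largest change in (overall + column effects) is below `tol` (default
  1e-6, max 50 sweeps); the protein's abundance in sample s is overall +
  column effect. Even-count medians are midpoints of the central order
  statistics, making results platform-deterministic.
* **Robust regression** fits y_ps = μ_s + π_p by IRLS with Huber weights
  (k = 1.345) and MAD-rescaled residual scale. Peptide effects are
  identified by the sum-to-zero constraint, so μ_s is the group-average
  abundance and all three methods are comparable. An exact fit (residual
  scale below 1e-12) short-circuits to the OLS solution; as k → ∞ the
  method reduces to OLS exactly. Non-convergence at `max_iter` returns the
  best iterate with a warning.
* **Total sum** adds raw intensities per column (missing contributes 0)
  and reports log2 of the sum. It is defined on the raw scale only —
  summing log-scale values is meaningless — so in the pipeline this
  strategy aggregates before normalization/imputation, and a sample whose
  peptides are all missing stays missing rather than becoming log2(0).

Benchmark design: the aggregation-recovery experiment uses 60 proteins × 8
peptides × (3+3) samples with σ = 0.3 replicate noise and 5% gross outlier
cells (+5–10 log2 units), with the censoring mechanism disabled so the
comparison isolates summarization. Median polish and robust regression
recover centred per-sample profiles with RMSE < 0.15 while the naive sum
exceeds 2. Two caveats are deliberate: (i) with very few peptides per
protein (≤4) no summarizer resists two gross outliers landing in the same
sample, so the claim is about reasonably covered proteins; (ii) RMSE is a
quadratic loss and occasionally jumps (to ~0.2) on seeds where ≥4 of 8
peptides are contaminated in one column — a breakdown-point fact, not an
implementation artefact.

## Moderated t-tests

Per feature, a cell-means OLS fit gives contrast estimate β_g (log2 FC),
residual variance s²_g on d_g = n_g − (#conditions with data) degrees of
freedom, and u_g = √(1/n_A + 1/n_B). Variances are shrunk under the
conjugate hierarchy s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g, 1/σ²_g ~
χ²_{d0}/(d0·s0²). The hyperparameters are estimated by the method of
moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): d0 solves the trigamma
equation trigamma(d0/2) = Var(e) − mean trigamma(d_g/2) via the guarded
Newton iteration for the trigamma inverse, and s0² = exp(mean e + ψ(d0/2)
− log(d0/2)). When the observed spread of e does not exceed its sampling
component, d0 = ∞ and s0² is the plain mean of the variances (matching the
reference implementation's behaviour in this branch). Zero variances are
floored at 1e-12 before taking logs. The posterior variance
s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g) yields t̃ = β/(u·s̃) on d0 + d_g
degrees of freedom; d0 = ∞ uses a normal reference. The whole chain is
cross-checked in the test suite against the Bioconductor reference via
Rscript on a simulated matrix, and d0 = 0 reproduces the ordinary t-test
exactly.

BH adjustment is applied per contrast by default (pooling across contrasts
is available); significance is gated by padj ≤ α AND |log2FC| ≥ lfc with
defaults 0.05 / 1.0, both exposed in config. The defaults are conventions,
not statements about any particular dataset.

The module is shaped as a Model/Results pair (`DifferentialModel.fit() →
DifferentialResults` with `summary()`), which keeps estimates,
uncertainties and significance calls together and gives downstream modules
one object to consume.

## PTM pipeline

Modified-peptide tables are re-keyed on rendered site identifiers
`PROTEIN_RposMmult` (first protein of a group, single-letter residue,
1-based position, multiplicity). Rows with missing site fields are dropped
and counted; duplicate keys receive deterministic `.k` suffixes. Rows of
different multiplicity are kept distinct — collapsing them would discard
stoichiometry information. When a localization-probability column is
present, sites below 0.75 (the class-I convention) are removed; the filter
is skipped, and logged as skipped, when the column is absent or empty. All
later stages are identifier-agnostic: the test suite asserts bitwise
equality with the protein pipeline on the same numeric matrix. Ratio
adjustment against total-proteome abundance is out of scope.

## Enrichment

ORA uses the hypergeometric upper tail P(X ≥ k) with the universe
defaulting to the features actually tested — the correct background, since
annotation-wide universes inflate enrichment. Sets are intersected with
the universe and size-filtered (defaults 5–500) before testing. GSEA is
the preranked variant: hits increment the running sum by |score|^p
(default p = 1) normalised to one, misses decrement 1/(N−K); ES is the
extreme of the running sum. The null permutes gene labels (uniform
same-size subsets), which is the appropriate null when only a ranked list
is available; NES divides ES by the mean |ES| of same-sign permutations
and perm_p uses the (b+1)/(B+1) estimator over same-sign permutations. The
default ranking metric from the differential results is the moderated t,
sign-preserving. Annotation collections are consumed as local GMT files
only.

## Pattern clustering and networks

Profiles (per-condition means of significant features) are row z-scored —
constant rows dropped — so Euclidean distance equals correlation distance
up to scale; this choice is recorded here because either metric could be
defended. Fuzzy c-means uses the standard alternating updates with
fuzzifier m = 2 by default, random data rows as initial centers from the
seeded generator, and a zero-distance guard assigning full membership to a
coinciding center. The objective Σ u^m d² is recorded per iteration and is
non-increasing by construction of the alternating minimisation; m → 1
approaches hard k-means.

Interaction networks are read from local STRING-style `protein1 protein2
combined_score` files; numeric species prefixes are stripped, matching is
case-insensitive, edges below the score threshold (default 400, the
"medium confidence" convention) are dropped, duplicate orientations merge
keeping the maximum score and self-loops are discarded. Subnetwork
extraction is a plain induced subgraph that retains isolated queried
nodes; no network statistics or API calls.

## Synthetic data

The peptide generator emulates a two-condition LFQ experiment: protein
log2 abundances ~ N(25, 2²) (the MS1 intensity scale), peptide ionisation
offsets ~ N(0, 1), replicate noise ~ N(0, σ²) with σ = 0.3 by default, a
configurable fraction (default 10%) of proteins shifted by ±effect in
condition B, soft logistic left-censoring (observation probability
logistic((x − (μ_s − shift·σ_s))/0.5), default shift 1.8), 2% uniform
dropout, and 5% gross outlier cells at +U(5, 10). The soft threshold (not
hard truncation) keeps imputation comparisons smooth. What it does *not*
emulate: correlated peptide noise within proteins, shared peptides between
groups, batch effects, intensity-dependent replicate variance, or any
spectrum-level process — so passing benchmarks demonstrate correctness of
the estimators under the stated model, not performance on any real
instrument's quirks.

Problem sizes in the acceptance checks were chosen for stable Monte-Carlo
estimates at desk scale: the null calibration uses 2000 features × (3+3);
FDR control uses 20 replicate datasets of 1000 features with 10% true
effects at Δ = 1; prior recovery uses 5000 simulated variances; the
fold-change recovery experiment averages over 60 regulated proteins (300
total, 20% regulated, 8 peptides each, n = 4/group) because with fewer
regulated proteins the Monte-Carlo spread of the mean exceeds the ±0.1
accuracy being verified.

## Known limitations

* No moderated F-tests, intensity-trend (mean-dependent) variance priors,
  duplicate-correlation models, or multiple-imputation uncertainty
  propagation.
* VSN assumes a common variance after transform; strongly heteroscedastic
  designs (e.g. mixed instrument runs) violate it.
* The `sum` aggregation order (aggregate before normalization) and the
  normalize-then-aggregate default for the other two strategies are
  documented choices; both orders are reachable through the library API.
* Network identifiers are matched textually; no cross-namespace ID mapping.
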