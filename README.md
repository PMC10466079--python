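# proteoflow

Differential analysis toolkit for label-free quantitative proteomics.

Mass-spectrometry quantification tables — MaxQuant-style wide protein-group
or peptide tables, or long DIA reports (DIA-NN, Spectronaut) — arrive with
QC artefacts (reverse hits, contaminants), intensity-dependent variance,
and 10–50% missing values that mix left-censoring at the detection limit
with random dropout. `proteoflow` takes such tables through a complete,
reproducible chain: QC/occupancy filtering → variance-stabilizing
normalization → MNAR/MAR imputation → optional peptide-to-protein
aggregation → empirical-Bayes moderated t-tests → function mining
(over-representation, preranked GSEA, fuzzy c-means pattern clustering,
STRING-style interaction subnetworks), with a machine-readable run log of
every stage. It is written for proteomics analysts who want a scriptable,
deterministic alternative to spreadsheet-and-GUI workflows, and for method
developers who need a tested reference of the standard chain.

## The statistics at the core

**Normalization.** Per-sample affine calibration with a generalised log,
h_i(x) = glog2((x − a_i)/b_i), glog2(y) = log2(y + √(y²+1)), fitted by
maximum likelihood with least-trimmed-squares robustness. For large x,
differences of h are log2 ratios; near the detection limit the arsinh
shape stabilises the variance.

**Testing.** Per feature g, OLS on condition means gives the log2 fold
change β_g, residual variance s²_g on d_g df, and u_g = √(1/n_A + 1/n_B).
Variances are shrunk under the conjugate inverse-χ² prior with
hyperparameters (d₀, s₀²) estimated by moments on log s²_g (a trigamma
equation solved by Newton iteration):

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t̃_g  = β_g / (u_g · s̃_g)   ~   t(d₀ + d_g)   under H₀,

followed by Benjamini–Hochberg adjustment per contrast and significance
gating on padj ≤ α and |log2FC| ≥ lfc. Borrowing variance strength across
features is what makes n = 3/group designs testable.

**Aggregation.** Three peptide→protein summarizers: Tukey median polish
(overall + sample effects from iterated median sweeps), Huber-IRLS robust
regression with sum-to-zero peptide effects, and raw-scale total sum.

See `docs/methods.md` for the full model descriptions, parameter defaults
and known limitations.

## Worked example

```python
import proteoflow as pf

# simulate a two-condition LFQ peptide experiment with known truth:
# 150 proteins x 4 peptides, 3 vs 3 replicates, 10% regulated at |log2FC| = 2
qt, design, truth = pf.simulate_peptide_dataset(
    n_proteins=150, peptides_per_protein=4, n_reps_per_group=3,
    effect_size=2.0, sigma=0.3, seed=42,
)

qt = pf.filter_flags(qt, ["Reverse", "Potential contaminant"])
qm = pf.bind_design(qt, design)
qm = pf.filter_missing(qm, thr=0)            # fully observed in >=1 condition
qm, vsn = pf.normalize_vsn(qm)               # glog2 scale
qm = pf.impute(qm, pf.ImputeSpec(method="left-shifted", seed=1))
qm = pf.aggregate_peptides(
    qm, pf.AggregationSpec(method="median-polish", grouping_key="protein_group")
)
results = pf.DifferentialModel(qm, ["B_vs_A"]).fit(alpha=0.05, lfc=1.0)
print(results.summary())
```

```
Moderated t-test results
================================================
features: 150
prior df d0: 1.783   prior variance s0^2: 0.06564
thresholds: padj <= 0.05, |log2FC| >= 1.0
------------------------------------------------
B_vs_A: 13 significant / 150 tested  (median log2FC -0.067)
```

13 of the 15 truly regulated proteins are recovered; the bulk of the
matrix sits at median log2FC ≈ 0. The estimated prior (d₀ ≈ 1.8,
s₀² ≈ 0.066) says each feature's variance is moderated by roughly two
pseudo-replicates of prior information. The top of the contrast table:

```
feature_id    log2fc      t_mod     padj  significant
  PROT0097  5.551661  23.821538 0.000081         True
  PROT0020 -3.829274 -20.898846 0.000086         True
  PROT0041  2.246886  14.959592 0.000260         True
```

PROT0097's estimate (5.6 against a simulated effect of 2) is the familiar
LFQ signature of an on/off protein: it is censored below the detection
limit in condition A, so the left-shifted imputation places it deep in the
low tail and the fold change is amplified. The calls are correct; the
magnitudes of such features should be read as "large", not as precise
ratios.

The same chain is available from the shell:

```sh
proteoflow simulate --n-proteins 150 --seed 42 --outdir sim/
proteoflow run --pipeline peptide-aggregate \
    --input sim/quant_table.tsv --design sim/design.tsv \
    --contrasts B_vs_A --seed 42 --outdir results_run/
```

which writes the normalized matrix, per-contrast TSVs, `run_log.json`
(inputs digests, every stage's parameters and feature counts, seed) and a
text report regenerable from the log alone. `proteoflow enrich`,
`cluster` and `network` expose the downstream analyses; PTM site tables
run via `--pipeline ptm`.

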