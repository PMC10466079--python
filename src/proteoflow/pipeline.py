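"""End-to-end pipeline orchestration with a machine-readable run log.

Three differential-analysis pipelines share one stage chain:

* ``protein``            — protein-group tables: filter → VSN → impute →
  moderated t-test.
* ``ptm``                — modified-peptide tables re-keyed on modification
  sites, then the same chain.
* ``peptide-aggregate``  — peptide tables: filter → VSN → peptide-level
  impute → aggregate to proteins (median polish / robust / sum) → test.
  Early imputation at the peptide level is the point of this pipeline:
  missingness is resolved before summarization.  For the ``sum`` strategy
  aggregation happens on the raw scale first (sums are only meaningful
  pre-log).

Every run writes a JSON run log holding input digests, every stage's
parameters and feature counts, the seed, the package version and the
output file list; the human-readable report is generated from that log
alone, so it can be reproduced from the log after the fact.  Per-stage
random seeds are forked from the global seed by stable stage-name hashing,
so inserting a stage does not perturb later stages' streams.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .aggregate import AggregationSpec, aggregate_peptides
from .containers import QuantTable, bind_design
from .diffstats import DifferentialModel
from .enrich import gsea, ora_hypergeometric, read_gmt
from .impute import ImputeSpec, impute
from .ingest import parse_design, read_wide_table, reshape_long
from .network import induced_subnetwork, load_network
from .patterns import fuzzy_cmeans, standardize_profiles
from .preprocess import filter_flags, filter_missing, log2_transform, normalize_median, normalize_vsn
from .ptm import build_site_ids

__all__ = ["run_pipeline", "write_report", "fork_seed", "PIPELINES"]

PIPELINES = ("protein", "ptm", "peptide-aggregate")


def fork_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (global seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_table(cfg: dict[str, Any]) -> QuantTable:
    fmt = cfg.get("input_format", "wide")
    path = cfg["input"]
    if fmt == "wide":
        return read_wide_table(
            path,
            intensity_prefix=cfg.get("intensity_prefix", "LFQ intensity "),
            id_column=cfg.get("id_column", "Protein IDs"),
            name_column=cfg.get("name_column") or None,
            flag_columns=_split(cfg.get("flag_columns", "")),
        )
    if fmt == "long":
        rows = pd.read_csv(path, sep="\t")
        return reshape_long(
            rows,
            feature_key=cfg.get("feature_key", "feature"),
            sample_key=cfg.get("sample_key", "sample"),
            value_key=cfg.get("value_key", "intensity"),
            duplicate_policy=cfg.get("duplicate_policy", "error"),
        )
    raise ValueError(f"unknown input_format {fmt!r}")


def _split(value: str) -> list[str]:
    return [v.strip() for v in str(value).split(";") if v.strip()]


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute one pipeline per the config mapping; return the run log.

    Required keys: ``pipeline`` (protein | ptm | peptide-aggregate),
    ``input``, ``design``, ``contrasts`` (";"-separated ``A_vs_B``).
    Optional keys mirror the stage parameters (see the CLI ``run --help``).
    Writes the normalized matrix, one TSV per contrast, a combined wide
    TSV, optional enrichment/cluster/network outputs, ``run_log.json`` and
    ``report.txt`` into ``outdir``.
    """
    pipeline = config.get("pipeline")
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; choose from {PIPELINES}")
    contrasts = _split(config.get("contrasts", ""))
    if not contrasts:
        raise ValueError("config must name at least one contrast (e.g. B_vs_A)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    inputs: dict[str, str] = {}
    for key in ("input", "design", "gmt", "network"):
        if config.get(key):
            inputs[str(config[key])] = _sha256(config[key])

    qt = _load_table(config)
    design = parse_design(config["design"])

    if pipeline == "ptm":
        qt = build_site_ids(
            qt,
            protein_col=config.get("protein_col", "Protein"),
            position_col=config.get("position_col", "Position"),
            aa_col=config.get("aa_col", "Amino acid"),
            multiplicity_col=config.get("multiplicity_col") or None,
        )

    qt = filter_flags(qt, _split(config.get("flag_columns", "")))
    qm = bind_design(qt, design)
    qm = filter_missing(
        qm,
        thr=int(config.get("missing_thr", 0)),
        mode=config.get("missing_mode", "per-condition"),
        fraction=float(config.get("missing_fraction", 0.0)),
    )

    agg_method = config.get("aggregate_method", "median-polish")
    raw_qm = qm  # kept for 'sum' aggregation, which needs the raw scale

    norm = config.get("normalize", "vsn")
    if pipeline == "peptide-aggregate" and agg_method == "sum":
        spec = AggregationSpec(method="sum", grouping_key=config.get("grouping_key", "protein_group"))
        qm = aggregate_peptides(raw_qm, spec)  # raw in, log2 out
        qm = impute(qm, _impute_spec(config, seed))
    else:
        if norm == "vsn":
            qm, _ = normalize_vsn(qm, lts_keep=float(config.get("vsn_lts_keep", 0.9)))
        elif norm == "median":
            qm = normalize_median(log2_transform(qm))
        elif norm == "log2":
            qm = log2_transform(qm)
        else:
            raise ValueError(f"unknown normalize option {norm!r}")
        qm = impute(qm, _impute_spec(config, seed))
        if pipeline == "peptide-aggregate":
            spec = AggregationSpec(
                method=agg_method,
                grouping_key=config.get("grouping_key", "protein_group"),
                huber_k=float(config.get("huber_k", 1.345)),
            )
            qm = aggregate_peptides(qm, spec)

    model = DifferentialModel(qm, contrasts)
    res = model.fit(
        alpha=float(config.get("alpha", 0.05)),
        lfc=float(config.get("lfc", 1.0)),
        adjust=config.get("adjust", "per-contrast"),
    )

    outputs: list[str] = []
    matrix_path = outdir / "normalized_matrix.tsv"
    qm.X.to_csv(matrix_path, sep="\t", float_format="%.6g")
    outputs.append(matrix_path.name)

    for name in res.contrast_names:
        tab = res.contrast_table(name)
        path = outdir / f"contrast_{name}.tsv"
        tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs.append(path.name)
    combined = res.table.pivot(index="feature_id", columns="contrast_name",
                               values=["log2fc", "padj", "significant"])
    combined.columns = [f"{a}.{b}" for a, b in combined.columns]
    combined_path = outdir / "contrasts_combined.tsv"
    combined.to_csv(combined_path, sep="\t", float_format="%.6g")
    outputs.append(combined_path.name)

    results_summary: dict[str, Any] = {
        "contrasts": {
            name: {
                "n_tested": int(res.contrast_table(name)["p"].notna().sum()),
                "n_significant": int(res.contrast_table(name)["significant"].sum()),
            }
            for name in res.contrast_names
        },
        "prior": {"d0": float(res.prior.d0), "s0_2": float(res.prior.s0_2)},
    }

    if config.get("gmt"):
        gsc = read_gmt(config["gmt"])
        universe = list(qm.X.index)
        sig = res.significant_features(res.contrast_names[0])
        enr_top: list[dict[str, Any]] = []
        if sig:
            ora = ora_hypergeometric(
                sig, universe, gsc,
                min_size=int(config.get("min_set_size", 5)),
                max_size=int(config.get("max_set_size", 500)),
            )
            ora_path = outdir / "ora_results.tsv"
            ora.to_csv(ora_path, sep="\t", index=False, float_format="%.6g")
            outputs.append(ora_path.name)
            enr_top = ora.head(5)[["set_name", "p", "padj"]].to_dict("records")
        if config.get("run_gsea", "false") in ("true", "1", True):
            ranked = res.ranked_genes(res.contrast_names[0])
            gs = gsea(ranked, gsc,
                      n_perm=int(config.get("gsea_nperm", 1000)),
                      seed=fork_seed(seed, "gsea"))
            gsea_path = outdir / "gsea_results.tsv"
            gs.to_csv(gsea_path, sep="\t", index=False, float_format="%.6g")
            outputs.append(gsea_path.name)
        results_summary["enrichment_top"] = enr_top

    if config.get("cluster_k"):
        sig = res.significant_features()
        if len(sig) > int(config["cluster_k"]):
            profiles = standardize_profiles(qm.condition_means().loc[sig])
            cres = fuzzy_cmeans(
                profiles,
                k=int(config["cluster_k"]),
                m=float(config.get("fuzzifier", 2.0)),
                seed=fork_seed(seed, "cmeans"),
            )
            ctab = pd.DataFrame(
                {
                    "feature_id": cres.membership.index,
                    "cluster": cres.hard_labels().to_numpy(),
                    "max_membership": cres.max_membership().to_numpy(),
                }
            )
            cpath = outdir / "clusters.tsv"
            ctab.to_csv(cpath, sep="\t", index=False, float_format="%.6g")
            outputs.append(cpath.name)
            results_summary["clusters"] = {
                "k": int(config["cluster_k"]),
                "n_clustered": int(len(ctab)),
            }

    if config.get("network"):
        g = load_network(config["network"], score_threshold=int(config.get("score_threshold", 400)))
        sub = induced_subnetwork(g, res.significant_features())
        edges = pd.DataFrame(
            [(a, b, d["combined_score"]) for a, b, d in sub.edges(data=True)],
            columns=["protein1", "protein2", "combined_score"],
        )
        npath = outdir / "subnetwork_edges.tsv"
        edges.to_csv(npath, sep="\t", index=False)
        outputs.append(npath.name)
        results_summary["network"] = {
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
        }

    runlog = {
        "package": "proteoflow",
        "version": __version__,
        "pipeline": pipeline,
        "seed": seed,
        "inputs": inputs,
        "parameters": {k: str(v) for k, v in sorted(config.items())},
        "stages": qm.history,
        "results": results_summary,
        "outputs": outputs,
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(runlog, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report_path = outdir / "report.txt"
    report_path.write_text(write_report(runlog), encoding="utf-8")
    return runlog


def write_report(runlog: dict[str, Any]) -> str:
    """Render the human-readable summary from the run log alone."""
    lines = [
        f"proteoflow {runlog['version']} — pipeline: {runlog['pipeline']}",
        f"seed: {runlog['seed']}",
        "",
        "Stages:",
    ]
    for stage in runlog["stages"]:
        lines.append(
            f"  {stage['operation']}: {stage['features_in']} -> {stage['features_out']} features"
        )
    lines.append("")
    lines.append("Contrasts:")
    for name, info in runlog["results"]["contrasts"].items():
        lines.append(
            f"  {name}: {info['n_significant']} significant of {info['n_tested']} tested"
        )
    prior = runlog["results"].get("prior")
    if prior:
        d0 = prior["d0"]
        d0_str = "inf" if d0 == float("inf") else f"{d0:.3g}"
        lines.append(f"Variance prior: d0={d0_str}, s0^2={prior['s0_2']:.3g}")
    for title, key in (("Top enriched sets:", "enrichment_top"),):
        if runlog["results"].get(key):
            lines.append(title)
            for rec in runlog["results"][key]:
                lines.append(f"  {rec['set_name']}: p={rec['p']:.3g} padj={rec['padj']:.3g}")
    if "clusters" in runlog["results"]:
        c = runlog["results"]["clusters"]
        lines.append(f"Clusters: k={c['k']} over {c['n_clustered']} significant features")
    if "network" in runlog["results"]:
        nw = runlog["results"]["network"]
        lines.append(f"Subnetwork: {nw['n_nodes']} nodes, {nw['n_edges']} edges")
    lines.append("")
    lines.append("Outputs: " + ", ".join(runlog["outputs"]))
    return "\n".join(lines) + "\n"


def _impute_spec(config: dict[str, Any], seed: int) -> ImputeSpec:
    return ImputeSpec(
        method=config.get("impute_method", "left-shifted"),
        shift=float(config.get("impute_shift", 1.8)),
        width=float(config.get("impute_width", 0.3)),
        quantile=float(config.get("impute_q", 0.01)),
        k=int(config.get("impute_k", 10)),
        seed=fork_seed(seed, "impute"),
    )
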