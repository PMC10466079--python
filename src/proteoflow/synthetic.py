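"""Synthetic datasets with known ground truth.

Every input the pipeline consumes can be generated here, so tests and
benchmarks run without downloads.  The peptide-level generator emulates a
two-condition label-free experiment: protein log2 abundances around 25
(typical MS1 intensity scale), peptide-specific ionisation offsets,
replicate noise, a left-censored (MNAR) detection mechanism plus uniform
(MAR) dropout, and occasional gross outlier cells.  The MNAR mechanism is
a *soft* logistic threshold rather than hard truncation, so comparisons
between imputation strategies have a smooth target.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QuantTable

__all__ = [
    "SimTruth",
    "simulate_peptide_dataset",
    "simulate_null_dataset",
    "simulate_profiles",
]


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    true_log2fc: pd.Series               # per protein, condition B minus A
    regulated: pd.Series                 # boolean per protein
    peptide_map: pd.Series               # peptide feature_id -> protein
    cluster_labels: pd.Series | None = None
    mnar_shift: float = 0.0
    mar_rate: float = 0.0


def _two_group_design(n_reps: int) -> pd.DataFrame:
    rows = [
        {"sample": f"{cond}_{r}", "condition": cond, "replicate": r}
        for cond in ("A", "B")
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows)


def simulate_peptide_dataset(
    n_proteins: int = 100,
    peptides_per_protein: int = 3,
    n_reps_per_group: int = 3,
    effect_size: float = 1.0,
    sigma: float = 0.3,
    mnar_shift: float = 1.8,
    mar_rate: float = 0.02,
    outlier_rate: float = 0.05,
    regulated_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[QuantTable, pd.DataFrame, SimTruth]:
    """Simulate a raw-scale peptide quantification table with truth.

    Protein log2 abundances ~ Normal(25, 2^2); peptide offsets ~
    Normal(0, 1); replicate noise ~ Normal(0, sigma^2).  A
    ``regulated_fraction`` of proteins receives +/- ``effect_size`` in
    condition B.  A cell at log2 value x in sample s is *observed* with
    probability logistic((x - (mu_s - mnar_shift * sd_s)) / 0.5), then
    additionally dropped uniformly at ``mar_rate``; outlier cells gain
    +Uniform(5, 10).  Raw intensity is 2^x.
    """
    for name, val in [("n_proteins", n_proteins), ("peptides_per_protein", peptides_per_protein),
                      ("n_reps_per_group", n_reps_per_group)]:
        if val < 1:
            raise ValueError(f"{name} must be positive")
    for name, val in [("mar_rate", mar_rate), ("outlier_rate", outlier_rate),
                      ("regulated_fraction", regulated_fraction)]:
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if sigma < 0 or effect_size < 0:
        raise ValueError("sigma and effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    design = _two_group_design(n_reps_per_group)
    samples = list(design["sample"])
    n_samples = len(samples)
    n_pep = n_proteins * peptides_per_protein

    proteins = [f"PROT{i+1:04d}" for i in range(n_proteins)]
    prot_mean = rng.normal(25.0, 2.0, n_proteins)
    n_reg = int(round(regulated_fraction * n_proteins))
    reg_idx = rng.choice(n_proteins, size=n_reg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    log2fc = np.zeros(n_proteins)
    log2fc[reg_idx] = signs * effect_size

    pep_offset = rng.normal(0.0, 1.0, n_pep)
    prot_of_pep = np.repeat(np.arange(n_proteins), peptides_per_protein)
    is_b = np.array([c == "B" for c in design["condition"]])

    X = (
        prot_mean[prot_of_pep][:, None]
        + pep_offset[:, None]
        + (log2fc[prot_of_pep][:, None] * is_b[None, :])
        + rng.normal(0.0, sigma, (n_pep, n_samples))
    )
    outliers = rng.random((n_pep, n_samples)) < outlier_rate
    X = X + outliers * rng.uniform(5.0, 10.0, (n_pep, n_samples))

    # missingness: soft left-censoring per sample, then uniform dropout
    mu_s = X.mean(axis=0)
    sd_s = X.std(axis=0, ddof=1)
    thresh = mu_s - mnar_shift * sd_s
    p_obs = 1.0 / (1.0 + np.exp(-(X - thresh[None, :]) / 0.5))
    observed = rng.random((n_pep, n_samples)) < p_obs
    observed &= rng.random((n_pep, n_samples)) >= mar_rate

    raw = np.where(observed, np.exp2(X), np.nan)
    pep_ids = [
        f"{proteins[prot_of_pep[i]]}_pep{i % peptides_per_protein + 1}"
        for i in range(n_pep)
    ]
    intens = pd.DataFrame(raw, index=pd.Index(pep_ids, name="feature_id"), columns=samples)
    meta = pd.DataFrame(
        {
            "name": pep_ids,
            "raw_ids": pep_ids,
            "protein_group": [proteins[j] for j in prot_of_pep],
            "Reverse": "",
            "Potential contaminant": "",
        },
        index=intens.index,
    )
    truth = SimTruth(
        true_log2fc=pd.Series(log2fc, index=proteins, name="true_log2fc"),
        regulated=pd.Series(log2fc != 0.0, index=proteins, name="regulated"),
        peptide_map=pd.Series([proteins[j] for j in prot_of_pep], index=pep_ids),
        mnar_shift=mnar_shift,
        mar_rate=mar_rate,
    )
    return QuantTable(intens, meta), design, truth


def simulate_null_dataset(
    n_features: int = 2000,
    n_reps_per_group: int = 3,
    sigma: float = 0.3,
    mean: float = 25.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete log2 matrix with equal condition means (global null).

    Returns ``(X, design)`` for a 2-condition design; every feature has
    true mean ``mean`` in both conditions and noise SD ``sigma``.
    """
    rng = np.random.default_rng(seed)
    design = _two_group_design(n_reps_per_group)
    X = mean + rng.normal(0.0, sigma, (n_features, len(design)))
    ids = [f"F{i+1:05d}" for i in range(n_features)]
    return (
        pd.DataFrame(X, index=pd.Index(ids, name="feature_id"), columns=list(design["sample"])),
        design,
    )


def simulate_profiles(
    n_per_cluster: int = 50,
    k: int = 3,
    n_conditions: int = 6,
    separation: float = 10.0,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """k template profiles at pairwise distance >= separation, plus noise.

    Returns ``(matrix, labels)`` with ``k * n_per_cluster`` rows.  Templates
    are drawn by rejection sampling (scale grows if placement fails), so
    the pairwise-distance guarantee holds for any k and dimension.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    templates: list[np.ndarray] = []
    scale = float(separation)
    tries = 0
    while len(templates) < k:
        cand = rng.normal(0.0, scale, n_conditions)
        if all(np.linalg.norm(cand - t) >= separation for t in templates):
            templates.append(cand)
        tries += 1
        if tries % 200 == 0:
            scale *= 1.5
    T = np.vstack(templates)
    labels = np.repeat(np.arange(k), n_per_cluster)
    X = T[labels] + rng.normal(0.0, noise, (k * n_per_cluster, n_conditions))
    return X, labels
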