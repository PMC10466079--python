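import numpy as np
import pandas as pd
import pytest

from proteoflow.containers import QuantMatrix, QuantTable


def two_group_design(n_reps: int = 3) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": f"{c}_{r}", "condition": c, "replicate": r}
            for c in ("A", "B")
            for r in range(1, n_reps + 1)
        ]
    )


def make_qm(
    X: np.ndarray,
    n_reps: int = 3,
    scale: str = "log2",
    feature_ids: list[str] | None = None,
    meta_extra: dict | None = None,
) -> QuantMatrix:
    """QuantMatrix over a 2-condition design from a plain array."""
    design = two_group_design(n_reps)
    assert X.shape[1] == 2 * n_reps
    ids = feature_ids or [f"f{i}" for i in range(X.shape[0])]
    Xdf = pd.DataFrame(np.asarray(X, float), index=pd.Index(ids, name="feature_id"),
                       columns=list(design["sample"]))
    meta = pd.DataFrame({"name": ids, "raw_ids": ids}, index=Xdf.index)
    for key, vals in (meta_extra or {}).items():
        meta[key] = vals
    return QuantMatrix(Xdf, design, meta, scale=scale)


def make_qt(X: np.ndarray, samples: list[str], meta_extra: dict | None = None) -> QuantTable:
    ids = [f"f{i}" for i in range(X.shape[0])]
    intens = pd.DataFrame(np.asarray(X, float), index=pd.Index(ids, name="feature_id"),
                          columns=samples)
    meta = pd.DataFrame({"name": ids, "raw_ids": ids}, index=intens.index)
    for key, vals in (meta_extra or {}).items():
        meta[key] = vals
    return QuantTable(intens, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
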