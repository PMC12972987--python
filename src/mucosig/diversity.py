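"""Alpha diversity on rarefied feature tables and its group-comparison models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import compare_groups

__all__ = ["alpha_metrics", "compare_alpha_ileum", "compare_alpha_colon"]


def alpha_metrics(rarefied: pd.DataFrame, shannon_base: float = np.e) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index (natural log by default)."""
    mat = rarefied.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        bad = rarefied.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    richness = (mat > 0).sum(axis=1)
    p = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(shannon_base)
    return pd.DataFrame({"richness": richness, "shannon": shannon}, index=rarefied.index)


def compare_alpha_ileum(values: pd.Series, info: pd.DataFrame):
    """Fixed-effects Group + Cohort + interaction comparison (one sample/patient)."""
    return compare_groups(values, info, mixed=False)


def compare_alpha_colon(values: pd.Series, info: pd.DataFrame):
    """As the ileal model plus a patient random intercept (REML) for the
    repeated colonic segments."""
    return compare_groups(values, info, mixed=True)
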