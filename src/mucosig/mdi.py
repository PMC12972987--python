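"""Microbial dysbiosis index (clr formulation) and clinical correlations.

The index is the classic log-ratio of disease-increased over
disease-decreased signature taxa; on clr-transformed data the log of a
product ratio becomes a difference of sums, so per sample

    MDI = sum(clr over increased taxa) - sum(clr over decreased taxa).

Group comparisons reuse the fixed/mixed cohort-aware models. Clinical
correlations on repeated-measures (colonic) data use the resampled
Spearman procedure: 100 iterations, each on one randomly chosen sample
per patient; a correlation is reported significant only if at least
90 of the 100 iterations reach p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import compare_groups
from .stats import bh_adjust, spearman_test
from .synthetic import Signature

__all__ = [
    "mdi",
    "compare_mdi",
    "correlate_repeated",
    "taxon_clinical_heatmap",
    "CorrelationSummary",
]


def mdi(clr: pd.DataFrame, sig: Signature) -> pd.Series:
    """Per-sample dysbiosis index from a clr matrix and a signature.

    Signature taxa missing from the columns are dropped with a warning;
    an error is raised only if both sets end up empty.
    """
    inc = [t for t in sorted(sig.increased) if t in clr.columns]
    dec = [t for t in sorted(sig.decreased) if t in clr.columns]
    missing = (sig.increased | sig.decreased) - set(clr.columns)
    if missing:
        warnings.warn(f"{len(missing)} signature taxa absent from clr columns; dropped")
    if not inc and not dec:
        raise ValueError("no signature taxa present in the clr matrix")
    values = clr[inc].sum(axis=1) - clr[dec].sum(axis=1)
    values.name = "mdi"
    return values


def compare_mdi(values: pd.Series, info: pd.DataFrame, mixed: bool = False):
    """Group comparison of MDI with the same fixed/mixed machinery as
    alpha diversity (mixed=True for repeated colonic segments)."""
    return compare_groups(values, info, mixed=mixed)


@dataclass
class CorrelationSummary:
    covariate: str
    mean_rho: float
    n_significant: int
    n_iterations: int
    final_significant: bool


def correlate_repeated(
    values: pd.Series,
    covariate: pd.Series,
    info: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    min_patients: int = 10,
    name: str = "covariate",
) -> CorrelationSummary:
    """Repeated one-sample-per-patient Spearman correlation.

    Each iteration draws exactly one sample per patient uniformly at
    random and computes Spearman's rho and p between `values` and
    `covariate` (both indexed by sample). The final correlation is the
    mean rho; it is declared significant when at least 90% of iterations
    reach p < `alpha`. With one sample per patient every iteration is
    identical and the procedure reduces to a single plain Spearman test.
    """
    df = pd.DataFrame(
        {
            "value": values,
            "cov": covariate.reindex(values.index),
            "patient": info.loc[values.index, "patient_id"],
        }
    ).dropna()
    n_pat = df["patient"].nunique()
    if n_pat == 0:
        raise ValueError("covariate missing for all samples")
    if n_pat < min_patients:
        raise ValueError(f"covariate available for only {n_pat} patients (< {min_patients})")
    rng = np.random.default_rng(seed)
    val_arr = df["value"].to_numpy(dtype=float)
    cov_arr = df["cov"].to_numpy(dtype=float)
    codes, _ = pd.factorize(df["patient"])
    positions = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
    rhos = np.empty(n_iter)
    n_sig = 0
    for i in range(n_iter):
        picked = np.array([pos[rng.integers(len(pos))] for pos in positions])
        rho, p = spearman_test(val_arr[picked], cov_arr[picked])
        rhos[i] = rho
        if np.isfinite(p) and p < alpha:
            n_sig += 1
    need = int(np.ceil(0.9 * n_iter))
    return CorrelationSummary(
        covariate=name,
        mean_rho=float(np.nanmean(rhos)),
        n_significant=n_sig,
        n_iterations=n_iter,
        final_significant=n_sig >= need,
    )


def clinical_per_sample(clinical: pd.DataFrame, info: pd.DataFrame, covariate: str) -> pd.Series:
    """Broadcast a patient-level covariate onto samples."""
    return info["patient_id"].map(clinical[covariate]).rename(covariate)


def taxon_clinical_heatmap(
    clr: pd.DataFrame,
    sig: Signature,
    clinical: pd.DataFrame,
    info: pd.DataFrame,
    covariates=None,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated Spearman correlation of every signature taxon with every
    clinical covariate, BH-corrected across the taxon x covariate family.

    The per-cell p used for BH is the median p across iterations; the
    >=90/100 significance rule is reported alongside.
    """
    taxa = [t for t in sorted(sig.taxa) if t in clr.columns]
    if covariates is None:
        covariates = [
            c for c in clinical.columns if c not in ("patient_id", "cohort")
        ]
    rows = []
    rng = np.random.default_rng(seed)
    for taxon in taxa:
        for cov in covariates:
            cov_s = clinical_per_sample(clinical, info.loc[clr.index], cov)
            df = pd.DataFrame(
                {
                    "value": clr[taxon],
                    "cov": cov_s,
                    "patient": info.loc[clr.index, "patient_id"],
                }
            ).dropna()
            if df["patient"].nunique() < 10:
                continue
            val_arr = df["value"].to_numpy(dtype=float)
            cov_arr = df["cov"].to_numpy(dtype=float)
            codes, _ = pd.factorize(df["patient"])
            positions = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
            rhos, ps = np.empty(n_iter), np.empty(n_iter)
            for i in range(n_iter):
                picked = np.array([pos[rng.integers(len(pos))] for pos in positions])
                rhos[i], ps[i] = spearman_test(val_arr[picked], cov_arr[picked])
            n_sig = int(np.sum(ps < 0.05))
            rows.append(
                {
                    "taxon": taxon,
                    "covariate": cov,
                    "mean_rho": float(np.nanmean(rhos)),
                    "p_median": float(np.nanmedian(ps)),
                    "n_significant": n_sig,
                    "final_significant": n_sig >= int(np.ceil(0.9 * n_iter)),
                }
            )
    out = pd.DataFrame(
        rows, columns=["taxon", "covariate", "mean_rho", "p_median", "n_significant",
                       "final_significant"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p_median"])
    else:
        out["q"] = []
    return out
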