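"""Cohort-aware group comparison models shared by several pipeline stages.

Per-sample responses (alpha diversity metrics, dysbiosis index values)
are modelled as Group + Cohort + Group x Cohort. Single-sample-per-patient
data (terminal ileum) use an ordinary least-squares fit; repeated-measures
data (multiple colonic segments per patient) add a patient-level random
intercept estimated by REML. Cohort is effect-coded (+-1/2) so group
coefficients are cohort-averaged; pairwise group contrasts are BH-corrected
within the family, and contrasts whose Group x Cohort interaction is
significant trigger per-cohort post hoc fits.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["compare_groups"]

INTERACTION_ALPHA = 0.05


def _ordered_groups(series: pd.Series) -> list:
    groups = sorted(series.unique())
    if "HC" in groups:  # HC as reference level when present
        groups.remove("HC")
        groups = ["HC"] + groups
    return groups


def _design_matrix(df: pd.DataFrame, groups: list, cohorts: list):
    n = len(df)
    cols, names = [np.ones(n)], ["const"]
    gcols = {groups[0]: None}
    for g in groups[1:]:
        cols.append((df["group"] == g).astype(float).values)
        names.append(f"g[{g}]")
        gcols[g] = len(cols) - 1
    icols = {}
    if len(cohorts) == 2:
        x_c = np.where(df["cohort"] == cohorts[1], 0.5, -0.5)
        cols.append(x_c)
        names.append("cohort")
        cells = pd.crosstab(df["group"], df["cohort"])
        for g in groups[1:]:
            if g in cells.index and (cells.loc[g] > 0).all() and (cells.loc[groups[0]] > 0).all():
                cols.append(cols[gcols[g]] * x_c)
                names.append(f"g[{g}]:cohort")
                icols[g] = len(cols) - 1
            else:
                warnings.warn(f"group {g!r} missing in a cohort; interaction cell dropped")
    elif len(cohorts) > 2:
        raise ValueError("at most two cohorts are supported")
    return np.column_stack(cols), names, gcols, icols


def _fit(y, X, patient=None, reml=True):
    if patient is not None:
        counts = pd.Series(patient).value_counts()
        if (counts > 1).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, X, groups=np.asarray(patient)).fit(reml=reml)
            return fit, True
        warnings.warn("all patients contribute a single sample; using a fixed-effects fit")
    return sm.OLS(y, X).fit(), False


def _contrast(fit, is_mixed, c, k):
    params = np.asarray(fit.params)[:k]
    cov = np.asarray(fit.cov_params())[:k, :k]
    est = float(c @ params)
    se = float(np.sqrt(max(c @ cov @ c, 0.0)))
    if se < 1e-14:  # degenerate (e.g. constant response): no evidence either way
        return est, se, 1.0 if abs(est) < 1e-12 else np.nan
    t = est / se
    if is_mixed:
        p = 2 * sps.norm.sf(abs(t))
    else:
        p = 2 * sps.t.sf(abs(t), df=fit.df_resid)
    return est, se, float(p)


def _posthoc(df, g1, g2, cohort, mixed):
    sub = df[(df["cohort"] == cohort) & (df["group"].isin([g1, g2]))]
    if sub["group"].nunique() < 2:
        return np.nan, np.nan
    X = np.column_stack([np.ones(len(sub)), (sub["group"] == g1).astype(float).values])
    fit, is_mixed = _fit(
        sub["_y"].values, X, sub["patient_id"].values if mixed else None
    )
    est, _, p = _contrast(fit, is_mixed, np.array([0.0, 1.0]), 2)
    return est, p


def compare_groups(
    values: pd.Series, info: pd.DataFrame, mixed: bool = False
) -> tuple[pd.DataFrame, object]:
    """Fit the Group + Cohort + interaction model and report pairwise contrasts.

    Returns a tidy summary (one row per unordered group pair: estimate of
    group_a - group_b, SE, p, BH q across pairs, interaction p, and
    per-cohort post hoc estimates when the interaction is significant)
    together with the fitted statsmodels results object.
    """
    df = info.loc[values.index].copy()
    df["_y"] = np.asarray(values, dtype=float)
    groups = _ordered_groups(df["group"])
    cohorts = sorted(df["cohort"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    X, names, gcols, icols = _design_matrix(df, groups, cohorts)
    k = X.shape[1]
    fit, is_mixed = _fit(df["_y"].values, X, df["patient_id"].values if mixed else None)

    rows = []
    for g2, g1 in combinations(groups, 2):
        # estimate is g1 - g2, so contrasts read disease_vs_HC etc.
        c = np.zeros(k)
        if gcols[g1] is not None:
            c[gcols[g1]] = 1.0
        if gcols[g2] is not None:
            c[gcols[g2]] = -1.0
        est, se, p = _contrast(fit, is_mixed, c, k)
        row = {
            "contrast": f"{g1}_vs_{g2}",
            "group_a": g1,
            "group_b": g2,
            "estimate": est,
            "se": se,
            "p": p,
        }
        ip = np.nan
        # the pair's interaction contrast is defined only if every
        # non-reference group in the pair kept its interaction column
        ok_int = all(g == groups[0] or g in icols for g in (g1, g2))
        if len(cohorts) == 2 and ok_int and (g1 in icols or g2 in icols):
            ci = np.zeros(k)
            if g1 in icols:
                ci[icols[g1]] = 1.0
            if g2 in icols:
                ci[icols[g2]] = -1.0
            _, _, ip = _contrast(fit, is_mixed, ci, k)
        row["interaction_p"] = ip
        if np.isfinite(ip) and ip < INTERACTION_ALPHA:
            ests, ps = [], []
            for cohort in cohorts:
                e_c, p_c = _posthoc(df, g1, g2, cohort, mixed)
                row[f"estimate_{cohort}"] = e_c
                row[f"p_{cohort}"] = p_c
                ests.append(e_c)
                ps.append(p_c)
            row["posthoc_consistent"] = bool(
                np.all(np.isfinite(ests))
                and np.all(np.asarray(ps) < 0.05)
                and len({np.sign(e) for e in ests}) == 1
            )
        else:
            for cohort in cohorts:
                row[f"estimate_{cohort}"] = np.nan
                row[f"p_{cohort}"] = np.nan
            row["posthoc_consistent"] = None
        rows.append(row)

    out = pd.DataFrame(rows)
    out.insert(6, "q", bh_adjust(out["p"]))
    out.attrs["model"] = "mixed" if is_mixed else "fixed"
    return out, fit
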