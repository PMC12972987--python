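"""Consensus differential abundance and disease-signature construction.

Two independent per-taxon procedures are run on every contrast:

* ``da_clr_lm`` — linear models on clr-transformed abundances whose raw
  group coefficients are bias-corrected by subtracting the mode of the
  across-taxa coefficient distribution (Gaussian-kernel density, Silverman
  bandwidth). Under the compositional assumption that most taxa are not
  differential, the mode estimates the shared log-ratio bias.
* ``da_logtss_lm`` — total-sum scaling to proportions, log transform with
  half the smallest nonzero proportion as pseudocount, per-taxon linear
  model on the same design.

Differentially abundant taxa are the intersection of the two methods
(same direction, both BH-significant); taxa with a significant
Group x Cohort interaction must additionally be significant with the same
effect sign in each cohort separately. A disease signature is the
direction-consistent intersection of the disease-vs-control contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import clr_transform
from .stats import bh_adjust
from .synthetic import Signature

__all__ = [
    "da_clr_lm",
    "da_logtss_lm",
    "consensus",
    "cohort_consistency_filter",
    "derive_signature",
    "signature_difference",
    "directions",
]


def _mass_ols(Y: np.ndarray, X: np.ndarray):
    """OLS of every column of Y on X at once; returns beta, se, df_resid."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k x T
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return beta, se, df


def _mode(values: np.ndarray) -> float:
    """Mode of a coefficient distribution via Gaussian KDE (Silverman)."""
    v = values[np.isfinite(values)]
    if v.size < 3 or np.ptp(v) == 0:
        return float(np.median(v)) if v.size else 0.0
    kde = sps.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _design(sub: pd.DataFrame, g1: str, g2: str):
    cohorts = sorted(sub["cohort"].unique())
    cols = [np.ones(len(sub)), (sub["group"] == g1).astype(float).values]
    has_interaction = False
    if len(cohorts) == 2:
        x_c = np.where(sub["cohort"] == cohorts[1], 0.5, -0.5)
        cells = pd.crosstab(sub["group"], sub["cohort"])
        cols.append(x_c)
        if (cells.values > 0).all():
            cols.append(cols[1] * x_c)
            has_interaction = True
    elif len(cohorts) > 2:
        raise ValueError("at most two cohorts are supported")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"degenerate design for contrast {g1} vs {g2}")
    return X, cohorts, has_interaction


def _fit_contrast(Y: pd.DataFrame, info: pd.DataFrame, g1: str, g2: str, correct_mode: bool):
    sub = info.loc[Y.index]
    for g in (g1, g2):
        if (sub["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} absent from the data")
    X, cohorts, has_interaction = _design(sub, g1, g2)
    beta, se, df = _mass_ols(Y.to_numpy(dtype=float), X)

    eff = beta[1].copy()
    if correct_mode:
        eff -= _mode(beta[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / se[1]
    p = 2 * sps.t.sf(np.abs(t), df=df)

    out = pd.DataFrame(
        {
            "taxon": Y.columns,
            "effect": eff,
            "se": se[1],
            "p": p,
            "q": bh_adjust(p),
        }
    ).set_index("taxon", drop=False)
    out["direction"] = np.sign(out["effect"]).astype(int)

    if has_interaction:
        ti = beta[3] / se[3]
        out["interaction_p"] = 2 * sps.t.sf(np.abs(ti), df=df)
    else:
        out["interaction_p"] = np.nan

    for cohort in cohorts:
        cs = sub["cohort"] == cohort
        Yc = Y.loc[cs.values]
        Xc = np.column_stack(
            [np.ones(cs.sum()), (sub.loc[cs.values, "group"] == g1).astype(float).values]
        )
        if np.linalg.matrix_rank(Xc) < 2:
            out[f"effect_{cohort}"] = np.nan
            out[f"p_{cohort}"] = np.nan
            out[f"q_{cohort}"] = np.nan
            continue
        bc, sec, dfc = _mass_ols(Yc.to_numpy(dtype=float), Xc)
        ec = bc[1].copy()
        if correct_mode:
            ec -= _mode(bc[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            tc = ec / sec[1]
        pc = 2 * sps.t.sf(np.abs(tc), df=dfc)
        out[f"effect_{cohort}"] = ec
        out[f"p_{cohort}"] = pc
        out[f"q_{cohort}"] = bh_adjust(pc)
    out.attrs["contrast"] = f"{g1}_vs_{g2}"
    out.attrs["cohorts"] = cohorts
    return out


def da_clr_lm(
    table: pd.DataFrame,
    info: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """clr linear-model differential abundance with mode bias correction."""
    g1, g2 = contrast
    sub = info.loc[table.index]
    mask = sub["group"].isin([g1, g2]).values
    Y = clr_transform(table.loc[mask], pseudocount=pseudocount)
    out = _fit_contrast(Y, info, g1, g2, correct_mode=True)
    out.attrs["method"] = "clr_lm"
    return out


def da_logtss_lm(
    table: pd.DataFrame, info: pd.DataFrame, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Log total-sum-scaled linear-model differential abundance."""
    g1, g2 = contrast
    sub = info.loc[table.index]
    mask = sub["group"].isin([g1, g2]).values
    counts = table.loc[mask].to_numpy(dtype=float)
    props = counts / counts.sum(axis=1, keepdims=True)
    nz = props[props > 0]
    if nz.size == 0:
        raise ValueError("table contains no nonzero counts")
    pseudo = 0.5 * nz.min()
    Y = pd.DataFrame(np.log(props + pseudo), index=table.index[mask], columns=table.columns)
    out = _fit_contrast(Y, info, g1, g2, correct_mode=False)
    out.attrs["method"] = "logtss_lm"
    return out


def consensus(a: pd.DataFrame, b: pd.DataFrame, q_cut: float = 0.05) -> set:
    """Taxa significant in BOTH methods with agreeing effect direction."""
    if set(a.index) != set(b.index):
        raise ValueError("DA results cover different taxa universes")
    b = b.loc[a.index]
    hit = (a["q"] < q_cut) & (b["q"] < q_cut) & (a["direction"] == b["direction"])
    hit &= a["direction"] != 0
    return set(a.index[hit])


def cohort_consistency_filter(
    candidates: set,
    a: pd.DataFrame,
    b: pd.DataFrame,
    q_cut: float = 0.05,
    interaction_alpha: float = 0.05,
) -> set:
    """Drop candidates whose cohort-specific behaviour is inconsistent.

    For taxa with a significant Group x Cohort interaction (in either
    method), the per-cohort post hoc fits must be significant with the
    same effect sign in both cohorts; taxa without a significant
    interaction pass through unchanged.
    """
    kept = set()
    for taxon in candidates:
        ok = True
        for res in (a, b):
            cohorts = res.attrs.get("cohorts") or []
            if len(cohorts) != 2:
                continue
            row = res.loc[taxon]
            for c in cohorts:
                if f"q_{c}" not in res.columns:
                    raise ValueError(f"missing per-cohort fit for cohort {c!r}")
            ip = row["interaction_p"]
            if np.isfinite(ip) and ip < interaction_alpha:
                qs = [row[f"q_{c}"] for c in cohorts]
                effs = [row[f"effect_{c}"] for c in cohorts]
                if not (
                    np.all(np.isfinite(qs))
                    and np.all(np.asarray(qs) < q_cut)
                    and np.all(np.isfinite(effs))
                    and len({np.sign(e) for e in effs}) == 1
                ):
                    ok = False
        if ok:
            kept.add(taxon)
    return kept


def directions(result: pd.DataFrame, taxa) -> dict:
    """Taxon -> effect sign (+1/-1) extracted from a DA result."""
    return {t: int(result.loc[t, "direction"]) for t in taxa}


def derive_signature(
    dirs_a: dict, dirs_b: dict, contrast: str = "PSC_vs_HC", provenance: dict | None = None
) -> Signature:
    """Direction-consistent intersection of two contrast hit sets.

    Taxa present in both with the same sign are partitioned into
    increased/decreased; direction conflicts are excluded with a warning.
    """
    common = set(dirs_a) & set(dirs_b)
    inc, dec = set(), set()
    for taxon in common:
        if dirs_a[taxon] != dirs_b[taxon]:
            warnings.warn(f"direction conflict for {taxon!r}; excluded from signature")
            continue
        (inc if dirs_a[taxon] > 0 else dec).add(taxon)
    return Signature(
        increased=frozenset(inc),
        decreased=frozenset(dec),
        contrast=contrast,
        provenance=provenance or {},
    )


def signature_difference(psc: Signature, other: Signature) -> Signature:
    """Taxa in `psc` not shared (same direction) with `other` — the
    disease-specificity contrast against a second liver-disease signature."""
    return Signature(
        increased=psc.increased - other.increased,
        decreased=psc.decreased - other.decreased,
        contrast=f"{psc.contrast}_specific",
        provenance={"minus": other.contrast},
    )
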