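"""Small shared statistical primitives used across the pipeline."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "auc_score", "spearman_test"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries are ignored in the correction and propagated as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def auc_score(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Ties in `scores` contribute half a concordant pair. `labels` must
    contain both classes (coded 0/1 or boolean).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = sps.rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_test(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks handle ties. For n <= `exact_max_n` the p-value comes from
    exhaustive enumeration of all rank permutations (two-sided on |rho|);
    above that the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return np.nan, np.nan
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= exact_max_n:
        count = total = 0
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))
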