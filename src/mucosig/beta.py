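"""Beta diversity: robust Aitchison distances, PCoA, permutational ANOVA.

The PERMANOVA here partitions squared distances sequentially (type-I) over
Group + Cohort + Group x Cohort via the Gower-centered inner-product matrix
and hat-matrix traces, permuting either free sample labels or whole-patient
blocks (each patient's samples keep their design attributes together) for
repeated-measures data. A significant interaction triggers the two post hoc
families: Group tested within each cohort, Cohort tested within each group,
BH-corrected within family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as _iperm

import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.spatial.distance import pdist, squareform

from .stats import bh_adjust

__all__ = ["robust_aitchison", "pcoa", "permanova", "PermanovaResult"]


def robust_aitchison(table: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on robust-clr rows.

    Each sample's nonzero counts are log-transformed and centered by the
    mean log over that sample's nonzero entries; zeros stay at zero. On a
    zero-free table this equals the classical Aitchison distance.
    """
    mat = table.to_numpy(dtype=float)
    nz = mat > 0
    if not nz.any(axis=1).all():
        bad = table.index[~nz.any(axis=1)][0]
        raise ValueError(f"sample {bad!r} is all zero")
    logm = np.zeros_like(mat)
    np.log(mat, where=nz, out=logm)
    means = logm.sum(axis=1) / nz.sum(axis=1)
    rclr = np.where(nz, logm - means[:, None], 0.0)
    d = squareform(pdist(rclr))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def pcoa(dist: pd.DataFrame, k: int = 2):
    """Classical multidimensional scaling of a distance matrix.

    Returns (coordinates DataFrame, explained-variance fractions), with
    explained variance normalised by the sum of positive eigenvalues.
    """
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    explained = evals[:k] / evals[pos].sum()
    coords = pd.DataFrame(
        coords, index=dist.index, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return coords, explained


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # term, df, ss, r2, pseudo_f, p
    n_permutations: int
    post_hoc: pd.DataFrame | None = None


def _blocks(df: pd.DataFrame, terms):
    """Design-matrix blocks per model term (drop-first dummy coding)."""
    out = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols = []
            for la in sorted(df[a].unique())[1:]:
                for lb in sorted(df[b].unique())[1:]:
                    cols.append(((df[a] == la) & (df[b] == lb)).astype(float).values)
            block = np.column_stack(cols) if cols else np.empty((len(df), 0))
        else:
            levels = sorted(df[term].unique())[1:]
            block = np.column_stack([(df[term] == l).astype(float).values for l in levels])
        out.append(block)
    return out


def _sequential_stats(blocks, g, n):
    """Sequential SS, df, and pseudo-F per term from hat-matrix traces."""
    ss_total = np.trace(g)
    cum = np.ones((n, 1))
    tr_prev, rank_prev = 0.0, 1
    ss, dfs = [], []
    for block in blocks:
        cum = np.column_stack([cum, block])
        u = orth(cum)
        tr = float(np.sum((u.T @ g) * u.T))
        ss.append(tr - tr_prev)
        dfs.append(u.shape[1] - rank_prev)
        tr_prev, rank_prev = tr, u.shape[1]
    ss_res = ss_total - tr_prev
    df_res = n - rank_prev
    ss, dfs = np.array(ss), np.array(dfs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss / dfs) / (ss_res / df_res)
    return ss, dfs, f, ss_total, ss_res, df_res


def permanova(
    dist: pd.DataFrame,
    info: pd.DataFrame,
    terms=("group", "cohort", "group:cohort"),
    n_perm: int = 999,
    strata: str | None = None,
    seed: int = 0,
    permutations: str = "random",
    _post_hoc: bool = True,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    `strata` names a column (typically patient_id); when given, the design
    attributes are permuted as whole blocks so a patient's samples are
    never split across permuted units. `permutations="exhaustive"`
    enumerates all distinct label orderings (small toys only).
    """
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives poor p-value resolution")
    df = info.loc[dist.index].copy()
    factors = sorted({f for t in terms for f in t.split(":")})
    for fac in factors:
        vc = df[fac].value_counts()
        if (vc < 2).any():
            raise ValueError(f"factor {fac!r} has a level with fewer than 2 samples")
    n = len(df)
    d2 = dist.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j

    obs_blocks = _blocks(df, terms)
    ss, dfs, f_obs, ss_total, ss_res, df_res = _sequential_stats(obs_blocks, g, n)

    # permutation units: whole patients under strata, else samples
    if strata is not None:
        units = df.drop_duplicates(strata).set_index(strata)[factors]
        unit_of_sample = df[strata].values
    else:
        units = df[factors].reset_index(drop=True)
        unit_of_sample = np.arange(n)
    unit_ids = np.asarray(units.index if strata is not None else units.index)
    pos = {u: i for i, u in enumerate(unit_ids)}
    sample_unit_idx = np.array([pos[u] for u in unit_of_sample])
    unit_attrs = units.to_numpy()

    def f_for(order: np.ndarray) -> np.ndarray:
        perm_df = pd.DataFrame(
            unit_attrs[order][sample_unit_idx], columns=factors, index=df.index
        )
        blocks = _blocks(perm_df, terms)
        return _sequential_stats(blocks, g, n)[2]

    m = len(unit_ids)
    if permutations == "exhaustive":
        if m > 8:
            raise ValueError("exhaustive enumeration supported only for <= 8 units")
        tuples = [tuple(r) for r in unit_attrs]
        seen, orders = set(), []
        for order in _iperm(range(m)):
            key = tuple(tuples[i] for i in order)
            if key not in seen:
                seen.add(key)
                orders.append(np.array(order))
        f_perm = np.array([f_for(o) for o in orders])
        count = (f_perm >= f_obs[None, :] - 1e-12).sum(axis=0)
        p = count / len(orders)
        n_used = len(orders)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            count += f_for(rng.permutation(m)) >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm

    terms_df = pd.DataFrame(
        {
            "term": list(terms) + ["residual"],
            "df": list(dfs.astype(int)) + [int(df_res)],
            "ss": list(ss) + [ss_res],
            "r2": list(ss / ss_total) + [ss_res / ss_total],
            "pseudo_f": list(f_obs) + [np.nan],
            "p": list(p) + [np.nan],
        }
    )

    post = None
    interaction = [t for t in terms if ":" in t]
    if _post_hoc and interaction:
        ip = terms_df.set_index("term").loc[interaction[0], "p"]
        if np.isfinite(ip) and ip < 0.05:
            a, b = interaction[0].split(":")
            rows = []
            for family, within, tested in ((f"{a}_within_{b}", b, a), (f"{b}_within_{a}", a, b)):
                for level in sorted(df[within].unique()):
                    idx = df.index[df[within] == level]
                    sub = df.loc[idx]
                    if sub[tested].nunique() < 2 or (sub[tested].value_counts() < 2).any():
                        continue
                    res = permanova(
                        dist.loc[idx, idx],
                        sub,
                        terms=(tested,),
                        n_perm=n_perm,
                        strata=strata,
                        seed=seed,
                        permutations="random",
                        _post_hoc=False,
                    )
                    r = res.terms.iloc[0]
                    rows.append(
                        {
                            "family": family,
                            "stratum": level,
                            "term": tested,
                            "pseudo_f": r["pseudo_f"],
                            "r2": r["r2"],
                            "p": r["p"],
                        }
                    )
            if rows:
                post = pd.DataFrame(rows)
                post["q"] = np.nan
                for family in post["family"].unique():
                    mask = post["family"] == family
                    post.loc[mask, "q"] = bh_adjust(post.loc[mask, "p"])
    return PermanovaResult(terms=terms_df, n_permutations=n_used, post_hoc=post)
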