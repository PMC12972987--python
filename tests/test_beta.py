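"""Robust Aitchison distance, PCoA and PERMANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from mucosig.beta import pcoa, permanova, robust_aitchison
from mucosig.synthetic import DesignSpec, generate_cohort
from mucosig import preprocess as pp
from tests.conftest import ILEUM_ONLY, make_info


def dense_table(rows):
    arr = np.atleast_2d(rows)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])])


def hand_aitchison(a, b):
    """Classical Aitchison distance computed from first principles."""
    ca = np.log(a) - np.mean(np.log(a))
    cb = np.log(b) - np.mean(np.log(b))
    return float(np.sqrt(((ca - cb) ** 2).sum()))


class TestRobustAitchison:
    def test_identical_rows_zero(self):
        d = robust_aitchison(dense_table([[3, 5, 9], [3, 5, 9]]))
        assert d.iloc[0, 1] == 0

    def test_scale_invariance_on_dense_rows(self):
        d = robust_aitchison(dense_table([[1, 1, 1, 1], [2, 2, 2, 2]]))
        assert np.isclose(d.iloc[0, 1], 0.0, atol=1e-12)

    def test_equals_hand_computed_aitchison_on_dense_rows(self):
        a, b = np.array([3.0, 7.0, 11.0, 2.0]), np.array([5.0, 1.0, 6.0, 9.0])
        d = robust_aitchison(dense_table([a, b]))
        assert np.isclose(d.iloc[0, 1], hand_aitchison(a, b), atol=1e-12)

    def test_zeros_stay_zero_in_transform(self):
        # a zero entry contributes 0, not -inf
        d = robust_aitchison(dense_table([[4, 0, 2], [4, 1, 2]]))
        assert np.isfinite(d.values).all()

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all zero"):
            robust_aitchison(dense_table([[0, 0, 0], [1, 2, 3]]))

    def test_symmetry_and_zero_diagonal(self, rng):
        t = dense_table(rng.integers(0, 50, size=(8, 12)) + 1)
        d = robust_aitchison(t)
        assert np.allclose(d.values, d.values.T, atol=1e-10)
        assert np.allclose(np.diag(d.values), 0)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=list("abc"), columns=list("abc"))
        coords, explained = pcoa(d, k=2)
        assert np.isclose(explained[0], 1.0, atol=1e-10)

    def test_roundtrip_from_known_coordinates(self, rng):
        pts = rng.normal(size=(10, 2))
        d2 = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        d = pd.DataFrame(d2)
        coords, explained = pcoa(d, k=2)
        # distances are recovered exactly (coordinates up to rotation/reflection)
        rec = np.sqrt(((coords.values[:, None, :] - coords.values[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d2, atol=1e-8)
        assert np.isclose(explained.sum(), 1.0, atol=1e-10)

    def test_duplicate_samples_coincide(self):
        t = dense_table([[5, 2, 9], [5, 2, 9], [1, 8, 3]])
        coords, _ = pcoa(robust_aitchison(t), k=1)
        assert np.allclose(coords.iloc[0].values, coords.iloc[1].values, atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        t = dense_table(rng.integers(1, 100, size=(12, 20)))
        d = robust_aitchison(t)
        coords, explained = pcoa(d, k=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, ids=list(d.index)))
        ref_expl = ref.proportion_explained.values[:3]
        # same convention: eigenvalue / sum of positive eigenvalues
        assert np.allclose(explained, ref_expl, atol=1e-6)

    def test_k_truncated_with_warning(self):
        x = np.array([0.0, 1.0, 3.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = pcoa(d, k=3)
        assert coords.shape[1] < 3


def brute_force_single_factor(dist, labels):
    """Text-book PERMANOVA pseudo-F from group-wise sums of squared distances."""
    d2 = dist**2
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in set(labels):
        idx = np.flatnonzero(np.asarray(labels) == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(set(labels))
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _toy(self, rng, n=6):
        t = dense_table(rng.integers(1, 60, size=(n, 8)))
        labels = ["X"] * (n // 2) + ["Y"] * (n - n // 2)
        info = make_info(
            [(f"s{i}", f"P{i}", "A", labels[i], "ileum") for i in range(n)]
        )
        return robust_aitchison(t), info, labels

    def test_pseudo_f_matches_brute_force(self, rng):
        dist, info, labels = self._toy(rng)
        res = permanova(dist, info, terms=("group",), permutations="exhaustive")
        f_oracle = brute_force_single_factor(dist.values, labels)
        assert np.isclose(res.terms["pseudo_f"].iloc[0], f_oracle, atol=1e-10)

    def test_p_matches_exhaustive_enumeration(self, rng):
        from itertools import permutations as iperm

        dist, info, labels = self._toy(rng)
        res = permanova(dist, info, terms=("group",), permutations="exhaustive")
        f_obs = brute_force_single_factor(dist.values, labels)
        seen, fs = set(), []
        for perm in iperm(labels):
            if perm in seen:
                continue
            seen.add(perm)
            fs.append(brute_force_single_factor(dist.values, list(perm)))
        p_oracle = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        assert np.isclose(res.terms["p"].iloc[0], p_oracle, atol=1e-12)
        assert res.n_permutations == len(fs)

    def test_r2_sums_to_one(self, rng):
        spec = DesignSpec(
            n_patients_per_group_per_cohort=8,
            groups=("HC", "pre_LTx"),
            segments_per_patient=ILEUM_ONLY,
            n_taxa=40,
            seed=5,
        )
        counts, info, _, _ = generate_cohort(spec)
        counts = pp.filter_depth(counts)
        dist = robust_aitchison(counts)
        res = permanova(dist, info.loc[counts.index], n_perm=99, seed=1)
        assert np.isclose(res.terms["r2"].sum(), 1.0, atol=1e-8)

    def test_pseudo_f_independent_of_seed(self, rng):
        dist, info, _ = self._toy(rng, n=10)
        r1 = permanova(dist, info, terms=("group",), n_perm=99, seed=1)
        r2 = permanova(dist, info, terms=("group",), n_perm=99, seed=99)
        assert np.allclose(
            r1.terms["pseudo_f"].dropna(), r2.terms["pseudo_f"].dropna(), atol=1e-12
        )

    def test_saturation_under_strong_shift(self):
        rng = np.random.default_rng(8)
        base = rng.integers(20, 60, size=(20, 10)).astype(float)
        base[10:, :3] *= 40  # huge shift for group Y
        labels = ["X"] * 10 + ["Y"] * 10
        info = make_info(
            [(f"s{i}", f"P{i}", "A", labels[i], "ileum") for i in range(20)]
        )
        dist = robust_aitchison(dense_table(base))
        res = permanova(dist, info, terms=("group",), n_perm=199, seed=0)
        assert np.isclose(res.terms["p"].iloc[0], 1 / 200)

    def test_null_calibration(self):
        rng = np.random.default_rng(33)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            t = dense_table(rng.integers(1, 200, size=(20, 15)))
            labels = ["X"] * 10 + ["Y"] * 10
            info = make_info(
                [(f"s{i}", f"P{i}", "A", labels[i], "ileum") for i in range(20)]
            )
            res = permanova(
                robust_aitchison(t), info, terms=("group",), n_perm=99,
                seed=int(rng.integers(2**31)),
            )
            rejections += res.terms["p"].iloc[0] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_block_permutation_keeps_patients_together(self):
        # two patients with 3 samples each: only 2 distinct block orders,
        # so the group term's exhaustive p can only be 0.5 or 1
        rng = np.random.default_rng(4)
        t = dense_table(rng.integers(1, 50, size=(6, 6)))
        info = make_info(
            [(f"s{i}", f"P{i // 3}", "A", "X" if i < 3 else "Y", "cecum") for i in range(6)]
        )
        res = permanova(
            robust_aitchison(t), info, terms=("group",), strata="patient_id",
            permutations="exhaustive",
        )
        assert res.n_permutations == 2
        assert res.terms["p"].iloc[0] in (0.5, 1.0)

    def test_interaction_triggers_posthoc(self):
        rng = np.random.default_rng(9)
        rows, data = [], []
        i = 0
        for cohort in ("A", "B"):
            for group in ("HC", "pre_LTx"):
                for _ in range(8):
                    i += 1
                    rows.append((f"s{i}", f"P{i}", cohort, group, "ileum"))
                    base = rng.integers(20, 60, size=10).astype(float)
                    if group == "pre_LTx" and cohort == "A":
                        base[:3] *= 30  # group effect only in cohort A
                    data.append(base)
        info = make_info(rows)
        dist = robust_aitchison(dense_table(data).set_index(info.index))
        res = permanova(dist, info, n_perm=199, seed=2)
        ip = res.terms.set_index("term").loc["group:cohort", "p"]
        assert ip < 0.05
        assert res.post_hoc is not None
        assert set(res.post_hoc["family"]) == {"group_within_cohort", "cohort_within_group"}
        assert "q" in res.post_hoc.columns

    def test_low_permutation_warning(self, rng):
        dist, info, _ = self._toy(rng, n=8)
        with pytest.warns(UserWarning, match="resolution"):
            permanova(dist, info, terms=("group",), n_perm=49, seed=0)
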