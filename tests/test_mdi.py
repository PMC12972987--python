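"""Dysbiosis index arithmetic and the resampled correlation procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucosig import preprocess as pp
from mucosig.diversity import alpha_metrics
from mucosig.mdi import (
    clinical_per_sample,
    compare_mdi,
    correlate_repeated,
    mdi,
    taxon_clinical_heatmap,
)
from mucosig.stats import spearman_test
from mucosig.synthetic import Signature
from tests.conftest import make_info


def clr_frame(rows, columns):
    return pd.DataFrame(np.atleast_2d(rows), columns=columns,
                        index=[f"s{i}" for i in range(np.atleast_2d(rows).shape[0])])


SIG = Signature(frozenset({"A"}), frozenset({"B"}), "toy")


class TestMdi:
    def test_two_term_sum(self):
        clr = clr_frame([[1.2, -0.7, -0.5]], ["A", "B", "C"])
        assert np.isclose(mdi(clr, SIG).iloc[0], 1.9)

    def test_antisymmetric_under_signature_swap(self):
        clr = clr_frame([[1.2, -0.7, -0.5], [0.3, 0.9, -1.2]], ["A", "B", "C"])
        swapped = Signature(SIG.decreased, SIG.increased, "toy")
        assert np.allclose(mdi(clr, SIG).values, -mdi(clr, swapped).values)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(-5, 5))
    def test_constant_shift_dependence(self, c):
        """Adding c to every clr entry shifts MDI by c * (|inc| - |dec|)."""
        sig = Signature(frozenset({"A", "B"}), frozenset({"C"}), "toy")
        clr = clr_frame([[0.4, -1.0, 0.6, 0.0]], ["A", "B", "C", "D"])
        base = mdi(clr, sig).iloc[0]
        shifted = mdi(clr + c, sig).iloc[0]
        assert np.isclose(shifted - base, c * (2 - 1), atol=1e-10)

    def test_missing_taxa_dropped_with_warning(self):
        clr = clr_frame([[1.0, -1.0]], ["A", "X"])
        with pytest.warns(UserWarning, match="absent"):
            v = mdi(clr, SIG)
        assert np.isclose(v.iloc[0], 1.0)

    def test_all_taxa_missing_errors(self):
        clr = clr_frame([[1.0]], ["X"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no signature taxa"):
                mdi(clr, SIG)

    def test_disease_above_hc_on_planted_data(self, filtered_two_group):
        filt, info, _, truth = filtered_two_group
        clr = pp.clr_transform(filt)
        v = mdi(clr, truth.signature)
        assert v[info.group == "pre_LTx"].mean() > v[info.group == "HC"].mean()

    def test_inverse_correlation_with_shannon(self, filtered_two_group):
        filt, info, _, truth = filtered_two_group
        clr = pp.clr_transform(filt)
        v = mdi(clr, truth.signature)
        shannon = alpha_metrics(filt)["shannon"]
        rho, _ = spearman_test(v.values, shannon.values)
        assert rho < 0


class TestCompareMdi:
    def test_planted_signature_separates_groups(self, filtered_two_group):
        filt, info, _, truth = filtered_two_group
        clr = pp.clr_transform(filt)
        v = mdi(clr, truth.signature)
        ileum = info[info.segment == "ileum"]
        summary, _ = compare_mdi(v.loc[ileum.index], ileum, mixed=False)
        row = summary.set_index("contrast").loc["pre_LTx_vs_HC"]
        assert row["estimate"] > 0 and row["q"] < 0.05

    def test_constant_mdi_no_effect(self):
        info = make_info(
            [(f"s{i}", f"P{i}", "A" if i % 2 else "B", "HC" if i < 10 else "pre_LTx", "ileum")
             for i in range(20)]
        )
        v = pd.Series(1.5, index=info.index)
        summary, _ = compare_mdi(v, info, mixed=False)
        assert (summary["p"] >= 0.999).all()


def repeated_info(rng, n_patients=60, n_seg=(2, 4)):
    rows = []
    for i in range(n_patients):
        for s in range(rng.integers(*n_seg)):
            rows.append((f"P{i}_{s}", f"P{i}", "A", "HC", "cecum"))
    return make_info(rows)


class TestCorrelateRepeated:
    def test_self_correlation_saturates(self, rng):
        info = repeated_info(rng)
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        s = correlate_repeated(v, v.copy(), info, n_iter=100, seed=1)
        assert s.mean_rho == 1.0 and s.n_significant == 100 and s.final_significant

    def test_significance_rule_threshold(self, rng):
        """final_significant is exactly the >=90/100 iteration rule."""
        info = repeated_info(rng)
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        s_null = correlate_repeated(
            v, pd.Series(rng.normal(size=len(info)), index=info.index), info, seed=2
        )
        assert s_null.final_significant == (s_null.n_significant >= 90)
        assert not s_null.final_significant

    def test_single_sample_per_patient_reduces_to_plain_spearman(self, rng):
        info = repeated_info(rng, n_patients=30, n_seg=(1, 2))
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        cov = pd.Series(v.values + rng.normal(0, 0.5, len(info)), index=info.index)
        s = correlate_repeated(v, cov, info, n_iter=100, seed=3)
        rho, p = spearman_test(v.values, cov.values)
        assert np.isclose(s.mean_rho, rho, atol=1e-12)
        assert s.n_significant in (0, 100)  # all iterations identical

    def test_null_calibration_of_final_rule(self):
        """The >=90/100 rule is conservative: null covariates almost never
        reach final significance."""
        rng = np.random.default_rng(7)
        n_final = 0
        for _ in range(150):
            info = repeated_info(rng)
            v = pd.Series(rng.normal(size=len(info)), index=info.index)
            cov = pd.Series(rng.normal(size=len(info)), index=info.index)
            s = correlate_repeated(v, cov, info, n_iter=100, seed=int(rng.integers(2**31)))
            n_final += s.final_significant
        assert n_final / 150 <= 0.02

    def test_planted_link_recovered(self, rng):
        info = repeated_info(rng, n_patients=60)
        u = {f"P{i}": rng.normal() for i in range(60)}
        v = pd.Series(
            [u[p] + rng.normal(0, 0.4) for p in info.patient_id], index=info.index
        )
        cov = pd.Series(
            [1.2 * u[p] + rng.normal(0, 0.5) for p in info.patient_id], index=info.index
        )
        s = correlate_repeated(v, cov, info, n_iter=100, seed=4)
        assert s.mean_rho > 0.4 and s.final_significant

    def test_all_missing_errors(self, rng):
        info = repeated_info(rng, n_patients=12)
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        cov = pd.Series(np.nan, index=info.index)
        with pytest.raises(ValueError, match="missing"):
            correlate_repeated(v, cov, info)

    def test_too_few_patients_errors(self, rng):
        info = repeated_info(rng, n_patients=5)
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        with pytest.raises(ValueError, match="patients"):
            correlate_repeated(v, v.copy(), info)

    def test_deterministic_given_seed(self, rng):
        info = repeated_info(rng)
        v = pd.Series(rng.normal(size=len(info)), index=info.index)
        cov = pd.Series(rng.normal(size=len(info)), index=info.index)
        s1 = correlate_repeated(v, cov, info, seed=11)
        s2 = correlate_repeated(v, cov, info, seed=11)
        assert s1 == s2


class TestHeatmap:
    @staticmethod
    def _setup(rng, loading=1.5):
        sig = Signature(frozenset({"g__A"}), frozenset({"g__B"}), "toy")
        info = repeated_info(rng, n_patients=50)
        pats = sorted(info.patient_id.unique())
        u = {p: rng.normal() for p in pats}
        clr = pd.DataFrame(
            {
                "g__A": [u[p] + rng.normal(0, 0.4) for p in info.patient_id],
                "g__B": rng.normal(size=len(info)),
                "g__C": rng.normal(size=len(info)),
            },
            index=info.index,
        )
        clinical = pd.DataFrame(
            {
                "patient_id": pats,
                "ALP": [loading * u[p] + rng.normal(0, 0.4) for p in pats],
                "calprotectin": rng.normal(size=len(pats)),
            }
        ).set_index("patient_id", drop=False)
        return sig, info, clr, clinical

    def test_planted_loading_detected(self, rng):
        sig, info, clr, clinical = self._setup(rng)
        out = taxon_clinical_heatmap(clr, sig, clinical, info, n_iter=50, seed=1)
        cell = out[(out.taxon == "g__A") & (out.covariate == "ALP")].iloc[0]
        assert cell["final_significant"] and cell["q"] < 0.05
        null_cell = out[(out.taxon == "g__B") & (out.covariate == "calprotectin")].iloc[0]
        assert not null_cell["final_significant"]

    def test_permuted_covariates_calibrated(self):
        rng = np.random.default_rng(19)
        sig = Signature(frozenset({f"g__{i}" for i in range(8)}),
                        frozenset({f"g__{i}" for i in range(8, 16)}), "toy")
        info = repeated_info(rng, n_patients=40)
        clr = pd.DataFrame(
            rng.normal(size=(len(info), 16)),
            columns=[f"g__{i}" for i in range(16)],
            index=info.index,
        )
        pats = sorted(info.patient_id.unique())
        clinical = pd.DataFrame(
            {"patient_id": pats, "c1": rng.normal(size=len(pats)),
             "c2": rng.normal(size=len(pats)), "c3": rng.normal(size=len(pats))}
        ).set_index("patient_id", drop=False)
        out = taxon_clinical_heatmap(clr, sig, clinical, info, n_iter=30, seed=2)
        assert (out["q"] < 0.05).mean() <= 0.08

    def test_empty_signature_gives_empty_table(self, rng):
        sig = Signature(frozenset(), frozenset(), "toy")
        _, info, clr, clinical = self._setup(rng)
        out = taxon_clinical_heatmap(clr, sig, clinical, info, n_iter=5, seed=3)
        assert len(out) == 0


def test_clinical_per_sample_broadcasts(rng):
    info = repeated_info(rng, n_patients=3)
    clinical = pd.DataFrame(
        {"patient_id": ["P0", "P1", "P2"], "ALP": [1.0, 2.0, 3.0]}
    ).set_index("patient_id", drop=False)
    s = clinical_per_sample(clinical, info, "ALP")
    assert (s.loc[info.patient_id == "P1"] == 2.0).all()
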