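"""Microbial dysbiosis index and its clinical correlations.

Computes the clr-based MDI per sample from each segment's recovered
signature, compares groups with the fixed/mixed models, and correlates
MDI with the clinical covariates — plain Spearman in the ileum (one
sample per patient), the 100-iteration one-sample-per-patient resampling
with the >=90/100 significance rule in the colon. Also reports the
MDI-Shannon relationship.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from mucosig import diversity, preprocess as pp
from mucosig.mdi import clinical_per_sample, correlate_repeated, compare_mdi, mdi
from mucosig.stats import spearman_test
from mucosig.synthetic import Signature

DERIVED = Path("scratch/derived")
SCRATCH = Path("scratch/synthetic")
RESULTS = Path("results/analysis")
SEED = 20250905


def main():
    info = pd.read_csv(DERIVED / "metadata_filtered.tsv", sep="\t").set_index(
        "sample_id", drop=False
    )
    info["group"] = info["group"].replace(
        {"post_nonrPSC": "post_LTx", "post_rPSC": "post_LTx"}
    )
    clinical = pd.read_csv(SCRATCH / "clinical.tsv", sep="\t", index_col=0)
    clinical["patient_id"] = clinical.index
    covs = [c for c in clinical.columns if c not in ("patient_id", "cohort")]
    RESULTS.mkdir(parents=True, exist_ok=True)

    model_rows, corr_rows = [], []
    for seg, mixed in (("ileum", False), ("colon", True)):
        sig_d = json.loads((RESULTS / f"signature_{seg}.json").read_text())
        sig = Signature(frozenset(sig_d["increased"]), frozenset(sig_d["decreased"]), "PSC_vs_HC")
        filt = pd.read_csv(DERIVED / f"genus_{seg}.tsv", sep="\t", index_col=0)
        seg_info = info.loc[filt.index]
        clr = pp.clr_transform(filt)
        v = mdi(clr, sig)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary, _ = compare_mdi(v, seg_info, mixed=mixed)
        summary.insert(0, "segment", seg)
        model_rows.append(summary)

        shannon = diversity.alpha_metrics(filt)["shannon"]
        rho, p = spearman_test(v.values, shannon.values)
        print(f"{seg}: MDI means by group "
              + ", ".join(f"{g} {v[seg_info.group == g].mean():+.1f}"
                          for g in ("HC", "pre_LTx", "post_LTx"))
              + f"; Spearman(MDI, Shannon) = {rho:+.2f} (p {p:.2g})")

        n_iter = 100 if mixed else 1
        for cov in covs:
            cov_s = clinical_per_sample(clinical, seg_info, cov)
            try:
                s = correlate_repeated(
                    v, cov_s, seg_info, n_iter=n_iter, seed=SEED, name=cov
                )
            except ValueError:
                continue
            corr_rows.append({"segment": seg, **s.__dict__})
        sig_corrs = [r for r in corr_rows
                     if r["segment"] == seg and r["final_significant"]]
        print(f"  clinically correlated covariates: "
              + (", ".join(f"{r['covariate']} (rho {r['mean_rho']:+.2f})"
                           for r in sig_corrs) or "none"))

    pd.concat(model_rows, ignore_index=True).to_csv(
        RESULTS / "mdi_models.tsv", sep="\t", index=False
    )
    pd.DataFrame(corr_rows).to_csv(
        RESULTS / "mdi_clinical_correlations.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
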