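"""Beta diversity: robust Aitchison distances, PCoA, PERMANOVA.

Tests Group, Cohort and their interaction on the robust Aitchison
distance matrix per segment (299 permutations here; colon permutes
whole patients to respect repeated measures) and stores the first two
ordination axes.
"""

from pathlib import Path

import pandas as pd

from mucosig import beta

DERIVED = Path("scratch/derived")
RESULTS = Path("results/analysis")
SEED = 20250903
N_PERM = 299


def main():
    info = pd.read_csv(DERIVED / "metadata_filtered.tsv", sep="\t").set_index(
        "sample_id", drop=False
    )
    info["group"] = info["group"].replace(
        {"post_nonrPSC": "post_LTx", "post_rPSC": "post_LTx"}
    )
    RESULTS.mkdir(parents=True, exist_ok=True)
    tables = []
    for seg in ("ileum", "colon"):
        filt = pd.read_csv(DERIVED / f"genus_{seg}.tsv", sep="\t", index_col=0)
        dist = beta.robust_aitchison(filt)
        coords, explained = beta.pcoa(dist, k=2)
        coords.to_csv(RESULTS / f"pcoa_{seg}.tsv", sep="\t")
        res = beta.permanova(
            dist,
            info.loc[filt.index],
            n_perm=N_PERM,
            strata="patient_id" if seg == "colon" else None,
            seed=SEED,
        )
        t = res.terms.copy()
        t.insert(0, "segment", seg)
        tables.append(t)
        print(f"{seg}: PCo1 {explained[0]:.1%}, PCo2 {explained[1]:.1%} explained")
        for _, r in res.terms.iterrows():
            if r["term"] != "residual":
                print(f"  {r['term']:13s} R2 {r['r2']:.3f}  p {r['p']:.4f}")
        if res.post_hoc is not None:
            res.post_hoc.assign(segment=seg).to_csv(
                RESULTS / f"permanova_posthoc_{seg}.tsv", sep="\t", index=False
            )
            print(f"  interaction significant -> post hoc written")
    pd.concat(tables, ignore_index=True).to_csv(
        RESULTS / "permanova.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
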