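"""Configuration-driven end-to-end runs of the full analysis workflow.

A run executes, per gut-segment class (terminal ileum; unified colon):
preprocessing -> alpha diversity models -> robust Aitchison PERMANOVA and
PCoA -> two-method consensus differential abundance with cohort
consistency -> disease signature -> grouped-bootstrap elastic-net
classification -> dysbiosis index with clinical correlations; and writes
TSV/JSON artifacts plus a manifest freezing the config hash, seeds and
thresholds.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import beta, classify, da, diversity, mdi as mdi_mod, preprocess
from .synthetic import DesignSpec, generate_cohort, spec_to_dict

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    clinical_path: str | None = None
    design: DesignSpec | None = None
    segment_scheme: str = "colon_unified"
    contrasts: tuple = (("pre_LTx", "HC"), ("post_LTx", "HC"))
    classifier_contrast: tuple = ("pre_LTx", "HC")
    min_reads: int = 10000
    rarefaction_depth: int = 10000
    q_cut: float = 0.05
    calprotectin_cut: float = 250.0
    n_boot: int = 500
    n_perm: int = 999
    correlation_iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.design is None:
            for p in (self.counts_path, self.metadata_path):
                if p is None:
                    raise ValueError("either a DesignSpec or counts+metadata paths required")
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        for name in ("min_reads", "rarefaction_depth", "n_boot", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.q_cut < 1:
            raise ValueError("q_cut must be in (0, 1)")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "design"
        }
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["classifier_contrast"] = list(self.classifier_contrast)
        d["design"] = spec_to_dict(self.design) if self.design is not None else None
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _collapse_post(info: pd.DataFrame) -> pd.DataFrame:
    """Pool post-transplant subgroups into one post_LTx group for the
    first-step disease-vs-control contrasts."""
    out = info.copy()
    out["group"] = out["group"].replace(
        {"post_nonrPSC": "post_LTx", "post_rPSC": "post_LTx"}
    )
    return out


def _load(config: RunConfig):
    if config.design is not None:
        counts, info, clinical, _ = generate_cohort(config.design)
        return counts, info, clinical
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    info = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
    info.index.name = "sample_id"
    if "sample_id" not in info.columns:
        info["sample_id"] = info.index
    clinical = None
    if config.clinical_path:
        clinical = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
        if "patient_id" not in clinical.columns:
            clinical["patient_id"] = clinical.index
    return counts, info, clinical


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full workflow and return the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        "rarefaction": config.seed,
        "permanova": config.seed + 1,
        "bootstrap": config.seed + 2,
        "correlation": config.seed + 3,
        "tuning": config.seed + 4,
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "stages": {},
    }
    report_lines = [f"run {manifest['config_hash'][:12]}"]
    t0 = time.time()

    def stage(name):
        class _Stage:
            def __enter__(self_):
                self_.t = time.time()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.time() - self_.t, 2),
                }
                return False

        return _Stage()

    with stage("load"):
        counts, info, clinical = _load(config)
        info = preprocess.merge_segments(info, config.segment_scheme)

    with stage("preprocess"):
        genus = preprocess.aggregate_genus(counts)
        genus = preprocess.filter_depth(genus, config.min_reads)
        info = info.loc[genus.index]
        asv_deep = preprocess.filter_depth(counts, config.min_reads)
        rarefied = preprocess.rarefy(
            asv_deep, config.rarefaction_depth, seed=seeds["rarefaction"]
        )

    segment_outputs = {}
    for seg_class in sorted(info["segment_class"].unique()):
        seg_dir = outdir / seg_class
        seg_dir.mkdir(exist_ok=True)
        idx = info.index[info["segment_class"] == seg_class]
        seg_info = _collapse_post(info.loc[idx])
        mixed = seg_info.groupby("patient_id").size().max() > 1
        seg_counts = preprocess.filter_near_zero_variance(genus.loc[idx])

        with stage(f"{seg_class}/alpha"):
            alpha = diversity.alpha_metrics(rarefied.loc[idx])
            alpha.to_csv(seg_dir / "alpha_per_sample.tsv", sep="\t")
            summaries = []
            for metric in alpha.columns:
                cmp_fn = diversity.compare_alpha_colon if mixed else diversity.compare_alpha_ileum
                summary, _ = cmp_fn(alpha[metric], seg_info)
                summary.insert(0, "metric", metric)
                summaries.append(summary)
            pd.concat(summaries).to_csv(seg_dir / "alpha_models.tsv", sep="\t", index=False)

        with stage(f"{seg_class}/beta"):
            dist = beta.robust_aitchison(seg_counts)
            coords, explained = beta.pcoa(dist, k=2)
            coords.to_csv(seg_dir / "pcoa_coordinates.tsv", sep="\t")
            res = beta.permanova(
                dist,
                seg_info,
                n_perm=config.n_perm,
                strata="patient_id" if mixed else None,
                seed=seeds["permanova"],
            )
            res.terms.to_csv(seg_dir / "permanova.tsv", sep="\t", index=False)
            if res.post_hoc is not None:
                res.post_hoc.to_csv(seg_dir / "permanova_posthoc.tsv", sep="\t", index=False)

        with stage(f"{seg_class}/differential_abundance"):
            hit_dirs = {}
            for g1, g2 in config.contrasts:
                label = f"{g1}_vs_{g2}"
                r1 = da.da_clr_lm(seg_counts, seg_info, (g1, g2))
                r2 = da.da_logtss_lm(seg_counts, seg_info, (g1, g2))
                r1.to_csv(seg_dir / f"da_clr_lm_{label}.tsv", sep="\t", index=False)
                r2.to_csv(seg_dir / f"da_logtss_lm_{label}.tsv", sep="\t", index=False)
                hits = da.consensus(r1, r2, q_cut=config.q_cut)
                hits = da.cohort_consistency_filter(hits, r1, r2, q_cut=config.q_cut)
                hit_dirs[label] = da.directions(r1, hits)

        with stage(f"{seg_class}/signature"):
            labels = [f"{g1}_vs_{g2}" for g1, g2 in config.contrasts]
            signature = da.derive_signature(
                hit_dirs[labels[0]],
                hit_dirs[labels[1]],
                contrast="PSC_vs_HC",
                provenance={"intersected": labels, "segment": seg_class},
            )
            (seg_dir / "signature.json").write_text(json.dumps(signature.to_dict(), indent=2))

        with stage(f"{seg_class}/classifier"):
            g1, g2 = config.classifier_contrast
            mask = seg_info["group"].isin([g1, g2]).values
            clr = preprocess.clr_transform(seg_counts.loc[mask])
            y = (seg_info.loc[mask, "group"] == g1).astype(int).values
            groups = seg_info.loc[mask, "patient_id"].values
            params = classify.tune_enet(clr, y, groups=groups, seed=seeds["tuning"])
            rep = classify.bootstrap_validate(
                clr,
                y,
                groups,
                n_boot=config.n_boot,
                seed=seeds["bootstrap"],
                hyperparameters=params,
            )
            (seg_dir / "classifier_report.json").write_text(json.dumps(rep.to_dict(), indent=2))
            pd.Series(rep.boot_aucs, name="oob_auc").to_csv(
                seg_dir / "classifier_boot_aucs.tsv", sep="\t", index=False
            )

        with stage(f"{seg_class}/mdi"):
            if signature.taxa:
                clr_all = preprocess.clr_transform(seg_counts)
                values = mdi_mod.mdi(clr_all, signature)
                values.to_frame().to_csv(seg_dir / "mdi.tsv", sep="\t")
                summary, _ = mdi_mod.compare_mdi(values, seg_info, mixed=mixed)
                summary.to_csv(seg_dir / "mdi_models.tsv", sep="\t", index=False)
                if clinical is not None:
                    corr_rows = []
                    covs = [
                        c for c in clinical.columns if c not in ("patient_id", "cohort")
                    ]
                    n_iter = config.correlation_iterations if mixed else 1
                    for cov in covs:
                        cov_s = mdi_mod.clinical_per_sample(clinical, seg_info, cov)
                        try:
                            s = mdi_mod.correlate_repeated(
                                values,
                                cov_s,
                                seg_info,
                                n_iter=n_iter,
                                seed=seeds["correlation"],
                                name=cov,
                            )
                        except ValueError:
                            continue
                        corr_rows.append(s.__dict__)
                    if corr_rows:
                        pd.DataFrame(corr_rows).to_csv(
                            seg_dir / "mdi_clinical_correlations.tsv", sep="\t", index=False
                        )
            else:
                warnings.warn(f"{seg_class}: empty signature; MDI skipped")
                manifest["stages"][f"{seg_class}/mdi_note"] = "empty signature"

        segment_outputs[seg_class] = sorted(p.name for p in seg_dir.iterdir())
        report_lines.append(
            f"{seg_class}: {len(seg_counts.columns)} taxa after filtering, "
            f"{len(idx)} samples, signature {len(signature.increased)} up / "
            f"{len(signature.decreased)} down, enet mean OOB AUC {rep.mean_auc:.3f}"
        )

    manifest["outputs"] = segment_outputs
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
    return outdir
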