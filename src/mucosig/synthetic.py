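"""Synthetic two-cohort mucosal microbiota generator with planted truth.

Emulates a cross-sectional, repeated-measures ileocolonic 16S design:
two geographic cohorts, disease groups sampled at several gut segments
per patient, genus-level counts with a planted disease signature shared
(same sign, same magnitude) across cohorts, cohort-wide batch effects,
patient random effects carried across that patient's segments, variable
library sizes including a fraction below the 10,000-read QC cut, and
clinical chemistry covariates driven by each patient's latent dysbiosis.

Every downstream stage of the pipeline (filtering, diversity models,
differential abundance, classification, dysbiosis index, clinical
correlation) is testable against the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "SyntheticTruth", "Signature", "generate_cohort", "shuffle_labels"]

HC = "HC"

#: default segment layout: cohort A samples ileum + cecum + rectum,
#: cohort B ileum + three colonic sites, mirroring a two-country design
DEFAULT_SEGMENTS = {
    "A": ("ileum", "cecum", "rectum"),
    "B": ("ileum", "ascending", "descending", "sigmoid"),
}

#: latent-score loadings of the clinical covariates: cholestasis markers
#: and fibrosis indices rise with dysbiosis, albumin falls, fecal
#: calprotectin is deliberately uncoupled (intestinal inflammation is
#: not part of the planted liver-disease axis)
DEFAULT_CLINICAL_LOADINGS = {
    "ALP": 1.2,
    "GGT": 1.0,
    "AST": 0.6,
    "APRI": 0.8,
    "FIB4": 0.6,
    "albumin": -0.8,
    "calprotectin": 0.0,
}


@dataclass(frozen=True)
class Signature:
    """Two disjoint taxon sets defining a disease-associated signature."""

    increased: frozenset
    decreased: frozenset
    contrast: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.increased & self.decreased:
            raise ValueError("increased and decreased sets must be disjoint")

    @property
    def taxa(self) -> frozenset:
        return self.increased | self.decreased

    def to_dict(self) -> dict:
        return {
            "increased": sorted(self.increased),
            "decreased": sorted(self.decreased),
            "contrast": self.contrast,
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class DesignSpec:
    n_patients_per_group_per_cohort: int = 40
    groups: tuple = (HC, "pre_LTx", "post_nonrPSC", "post_rPSC")
    cohorts: tuple = ("A", "B")
    segments_per_patient: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))
    n_taxa: int = 126
    n_signature_up: int = 7
    n_signature_down: int = 15
    effect_size: float = 1.0
    cohort_batch_sd: float = 0.3
    patient_sd: float = 0.3
    sample_sd: float = 0.3
    baseline_sd: float = 2.0
    latent_sd: float = 0.35
    overdispersion: float = 0.0
    depth_range: tuple = (12000, 60000)
    frac_low_depth: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_per_group_per_cohort < 1:
            raise ValueError("n_patients_per_group_per_cohort must be positive")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.n_signature_up < 0 or self.n_signature_down < 0:
            raise ValueError("signature sizes must be nonnegative")
        if self.n_signature_up + self.n_signature_down > self.n_taxa:
            raise ValueError("n_signature_up + n_signature_down exceeds n_taxa")
        if HC not in self.groups:
            raise ValueError("groups must include HC")
        for c in self.cohorts:
            segs = self.segments_per_patient.get(c, ())
            if len(segs) < 1:
                raise ValueError(f"segments_per_patient: cohort {c!r} has no segments")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < min <= max")
        if not 0.0 <= self.frac_low_depth <= 1.0:
            raise ValueError("frac_low_depth must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    signature: Signature
    clinical_loadings: dict
    group_effects: pd.DataFrame  # groups x taxa expected log-fold shifts
    latent_scores: pd.Series  # per-patient dysbiosis score
    library_sizes: pd.Series  # per-sample drawn depths


def _taxon_labels(n_taxa: int) -> list:
    return [f"g__Genus{i:03d}" for i in range(1, n_taxa + 1)]


def generate_cohort(spec: DesignSpec):
    """Draw a full synthetic study: counts, metadata, clinical covariates, truth.

    Per-sample genus counts are multinomial draws at the sample's library
    size from softmax(baseline + group effect + cohort batch + patient
    effect + sample noise) on the log scale; deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    taxa = _taxon_labels(spec.n_taxa)

    planted = rng.choice(spec.n_taxa, spec.n_signature_up + spec.n_signature_down, replace=False)
    up_idx = np.sort(planted[: spec.n_signature_up])
    down_idx = np.sort(planted[spec.n_signature_up :])
    signature = Signature(
        increased=frozenset(taxa[i] for i in up_idx),
        decreased=frozenset(taxa[i] for i in down_idx),
        contrast="disease_vs_HC",
        provenance={"planted": True},
    )

    baseline = rng.normal(0.0, spec.baseline_sd, spec.n_taxa)
    cohort_eff = {c: rng.normal(0.0, spec.cohort_batch_sd, spec.n_taxa) for c in spec.cohorts}

    sign = np.zeros(spec.n_taxa)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0
    group_effects = pd.DataFrame(
        {g: (0.0 if g == HC else spec.effect_size) * sign for g in spec.groups},
        index=taxa,
    ).T

    patients, latent = [], {}
    pat_eff = {}
    pid = 0
    for cohort in spec.cohorts:
        for group in spec.groups:
            for _ in range(spec.n_patients_per_group_per_cohort):
                pid += 1
                name = f"P{pid:04d}"
                u = rng.normal(0.0 if group == HC else 1.0, spec.latent_sd)
                latent[name] = u
                pat_eff[name] = rng.normal(0.0, spec.patient_sd, spec.n_taxa)
                patients.append((name, cohort, group))

    rows, meta = [], []
    for name, cohort, group in patients:
        u = latent[name]
        shift = sign * spec.effect_size * u if group != HC else np.zeros(spec.n_taxa)
        base = baseline + shift + cohort_eff[cohort] + pat_eff[name]
        for segment in spec.segments_per_patient[cohort]:
            logab = base + rng.normal(0.0, spec.sample_sd, spec.n_taxa)
            rows.append(logab)
            meta.append((f"{name}_{segment}", name, cohort, group, segment))

    info = pd.DataFrame(meta, columns=["sample_id", "patient_id", "cohort", "group", "segment"])
    info = info.set_index("sample_id", drop=False)
    n = len(info)

    lo, hi = spec.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), n)).astype(int)
    n_low = int(round(spec.frac_low_depth * n))
    if n_low:
        low_at = rng.choice(n, n_low, replace=False)
        depths[low_at] = np.exp(rng.uniform(np.log(2000), np.log(9999), n_low)).astype(int)
        depths[low_at] = np.minimum(depths[low_at], 9999)

    counts = np.empty((n, spec.n_taxa), dtype=np.int64)
    for i, logab in enumerate(rows):
        p = np.exp(logab - logab.max())
        p /= p.sum()
        if spec.overdispersion > 0:
            p = rng.dirichlet(p / spec.overdispersion)
        counts[i] = rng.multinomial(depths[i], p)
    counts = pd.DataFrame(counts, index=info.index, columns=taxa)

    pat_index = pd.Index([p for p, _, _ in patients], name="patient_id")
    u_series = pd.Series([latent[p] for p in pat_index], index=pat_index, name="latent_dysbiosis")
    clin = {"patient_id": pat_index, "cohort": [c for _, c, _ in patients]}
    for cov, loading in DEFAULT_CLINICAL_LOADINGS.items():
        clin[cov] = loading * u_series.values + rng.normal(0.0, 0.5, len(pat_index))
    clinical = pd.DataFrame(clin).set_index("patient_id", drop=False)
    # one cohort's healthy controls lack laboratory values, as is common
    # when controls are endoscopy volunteers without blood sampling
    hc_b = [p for p, c, g in patients if g == HC and c == spec.cohorts[-1]]
    clinical.loc[hc_b, list(DEFAULT_CLINICAL_LOADINGS)] = np.nan

    truth = SyntheticTruth(
        signature=signature,
        clinical_loadings=dict(DEFAULT_CLINICAL_LOADINGS),
        group_effects=group_effects,
        latent_scores=u_series,
        library_sizes=pd.Series(depths, index=info.index, name="library_size"),
    )
    return counts, info, clinical, truth


def shuffle_labels(info: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute group labels at the patient level.

    All of a patient's samples receive the same shuffled label and the
    patient-level multiset of group labels is preserved, so any residual
    classifier performance reflects overfitting rather than signal.
    """
    if "group" not in info.columns:
        raise ValueError("SampleInfo must have a 'group' column")
    rng = np.random.default_rng(seed)
    pat_groups = info.drop_duplicates("patient_id").set_index("patient_id")["group"]
    shuffled = pd.Series(
        rng.permutation(pat_groups.values), index=pat_groups.index, name="group"
    )
    out = info.copy()
    out["group"] = out["patient_id"].map(shuffled).values
    return out


def spec_to_dict(spec: DesignSpec) -> dict:
    d = asdict(spec)
    d["groups"] = list(spec.groups)
    d["cohorts"] = list(spec.cohorts)
    d["depth_range"] = list(spec.depth_range)
    d["segments_per_patient"] = {k: list(v) for k, v in spec.segments_per_patient.items()}
    return d
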