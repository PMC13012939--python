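"""Synthetic cohort generation and participant labeling rules.

Generates a seeded three-group cohort (CN / EMCI / LMCI) whose demographic,
cognitive and biomarker summaries are calibrated to published group-level
targets, plus per-subject ROI-level morphometric sample vectors carrying
configurable group effects in selected regions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .atlases import AAL116, DK68, METRICS, atlas_for_metric, atlas_labels

GROUPS = ("CN", "EMCI", "LMCI")

#: CSF Abeta42 amyloid-positivity cutoff, pg/mL
ABETA42_CUTOFF = 192.0
#: amyloid-PET SUVR positivity cutoffs by tracer (strictly above => positive)
SUVR_CUTOFF = {"FBP": 1.11, "FBB": 1.08}

#: minimum number of morphometric samples per ROI for stable density estimation
MIN_SAMPLES = 10

# Logical Memory II education strata: (cn_min, emci_lo, emci_hi, lmci_max).
# Stratum keys are lower education bounds: 16+, 8-15 and 0-7 years.
_LM2_STRATA = (
    (16, (9, 9, 11, 8)),
    (8, (5, 5, 9, 4)),
    (0, (3, 3, 6, 2)),
)


@dataclass
class SubjectRecord:
    """One participant's metadata row."""

    subject_id: str
    group: str
    age: float
    sex: str  # "M" / "F"
    education: float
    apoe4: int
    tiv: float  # mL
    mmse: float
    moca: float
    adas13: float
    lm2: float
    abeta42: float
    ptau: float
    ttau: float
    suvr: float | None = None
    tracer: str = "none"  # "FBP" / "FBB" / "none"
    amyloid: str = "unknown"  # "Apos" / "Aneg" / "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"invalid group {self.group!r}")
        if not 55.0 <= self.age <= 90.0:
            raise ValueError(f"age {self.age} outside [55, 90]")
        if self.education < 0:
            raise ValueError("education must be >= 0")
        if self.tiv <= 0:
            raise ValueError("tiv must be > 0")
        if self.apoe4 not in (0, 1):
            raise ValueError("apoe4 must be 0 or 1")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE outside [0, 30]")
        if not 0 <= self.moca <= 30:
            raise ValueError("MoCA outside [0, 30]")
        if self.sex not in ("M", "F"):
            raise ValueError(f"invalid sex {self.sex!r}")


@dataclass
class RoiSampleSet:
    """Per subject x metric x atlas morphometric sample vectors."""

    subject_id: str
    metric: str
    atlas: str
    samples: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        expected = atlas_labels(self.atlas)
        if atlas_for_metric(self.metric) != self.atlas:
            raise ValueError(
                f"metric {self.metric!r} pairs with {atlas_for_metric(self.metric)}, "
                f"not {self.atlas!r}"
            )
        missing = [lab for lab in expected if lab not in self.samples]
        if missing:
            raise ValueError(f"missing ROI labels: {missing[:3]}{'...' if len(missing) > 3 else ''}")
        extra = set(self.samples) - set(expected)
        if extra:
            raise ValueError(f"unknown ROI labels: {sorted(extra)[:3]}")
        for lab, v in self.samples.items():
            arr = np.asarray(v, dtype=float)
            if arr.size < MIN_SAMPLES:
                raise ValueError(f"ROI {lab!r} has {arr.size} samples, need >= {MIN_SAMPLES}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite sample values in ROI {lab!r}")
            self.samples[lab] = arr

    @property
    def labels(self) -> tuple[str, ...]:
        return atlas_labels(self.atlas)


@dataclass(frozen=True)
class EffectConfig:
    """Group-effect injection parameters for the ROI sample generator.

    Effect sizes are standardized mean shifts in units of the between-subject
    SD (negative = atrophy relative to the CN baseline).
    """

    affected_rois: tuple[tuple[str, str], ...] = ()
    effect_size_emci: float = 0.0
    effect_size_lmci: float = 0.0
    cognition_coupling: float = 0.0
    noise_sd: float = 1.0
    samples_per_roi_mean: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.samples_per_roi_mean < MIN_SAMPLES:
            raise ValueError(f"samples_per_roi_mean must be >= {MIN_SAMPLES}")
        object.__setattr__(self, "affected_rois", tuple(tuple(p) for p in self.affected_rois))
        for atlas, roi in self.affected_rois:
            if roi not in atlas_labels(atlas):
                raise ValueError(f"unknown ROI label {roi!r} for atlas {atlas}")


#: default volumetric effect: hippocampal/thalamic atrophy, graded EMCI < LMCI
DEFAULT_GMV_EFFECT = EffectConfig(
    affected_rois=(
        (AAL116, "Hippocampus_L"),
        (AAL116, "Hippocampus_R"),
        (AAL116, "Thalamus_L"),
    ),
    effect_size_emci=-0.3,
    effect_size_lmci=-0.8,
    cognition_coupling=-2.0,
    noise_sd=2.0,
    samples_per_roi_mean=500,
)

#: default cortical-thickness effect: LMCI-only left-hemisphere thinning
DEFAULT_CT_EFFECT = EffectConfig(
    affected_rois=(
        (DK68, "lh-entorhinal"),
        (DK68, "lh-isthmuscingulate"),
        (DK68, "lh-supramarginal"),
    ),
    effect_size_emci=0.0,
    effect_size_lmci=-0.6,
    cognition_coupling=0.0,
    noise_sd=2.0,
    samples_per_roi_mean=300,
)


# ---------------------------------------------------------------------------
# labeling rules
# ---------------------------------------------------------------------------

def assign_amyloid_status(
    abeta42: float | None,
    suvr: float | None = None,
    tracer: str = "none",
) -> str:
    """Amyloid positivity: CSF Abeta42 < 192 pg/mL, CSF definitive over PET;
    PET-only positivity requires SUVR strictly above the tracer cutoff."""
    if suvr is not None and tracer not in SUVR_CUTOFF:
        raise ValueError("suvr given without a valid tracer (FBP or FBB)")
    if abeta42 is not None:
        return "Apos" if abeta42 < ABETA42_CUTOFF else "Aneg"
    if suvr is not None:
        return "Apos" if suvr > SUVR_CUTOFF[tracer] else "Aneg"
    return "unknown"


def lm2_cutoffs(education: float) -> tuple[int, int, int, int]:
    """(cn_min, emci_lo, emci_hi, lmci_max) for the education stratum."""
    if education < 0:
        raise ValueError("education must be >= 0")
    for lower, cuts in _LM2_STRATA:
        if education >= lower:
            return cuts
    raise AssertionError("unreachable")


def assign_group_label(lm2: float, education: float, amyloid: str) -> str:
    """Assign CN / EMCI / LMCI / excluded from the education-stratified
    Logical Memory II cutoffs and the amyloid status.

    CN requires amyloid negativity; both MCI stages require positivity, so
    the numeric overlap between the CN and EMCI score ranges is resolved by
    amyloid status.
    """
    if lm2 < 0:
        raise ValueError("lm2 must be >= 0")
    if amyloid not in ("Apos", "Aneg"):
        raise ValueError(f"amyloid status must be known, got {amyloid!r}")
    cn_min, emci_lo, emci_hi, lmci_max = lm2_cutoffs(education)
    if amyloid == "Aneg":
        return "CN" if lm2 >= cn_min else "excluded"
    if emci_lo <= lm2 <= emci_hi:
        return "EMCI"
    if lm2 <= lmci_max:
        return "LMCI"
    return "excluded"


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------

# mean/SD targets per group for normally-distributed variables,
# truncation bounds applied at draw time
_MEAN_SD = {
    "age": {"CN": (71.48, 5.93), "EMCI": (72.78, 6.78), "LMCI": (72.00, 7.20)},
    "moca": {"CN": (26.28, 2.56), "EMCI": (23.69, 3.22), "LMCI": (21.64, 3.16)},
    "adas13": {"CN": (8.62, 4.51), "EMCI": (13.56, 5.06), "LMCI": (20.06, 6.63)},
    "abeta42": {"CN": (231.97, 23.31), "EMCI": (143.06, 25.27), "LMCI": (131.40, 23.03)},
    "education": {"CN": (16.76, 2.58), "EMCI": (16.35, 2.76), "LMCI": (16.67, 2.66)},
}

_MALE_FRAC = {"CN": 0.507, "EMCI": 0.614, "LMCI": 0.483}
_APOE4_FRAC = {"CN": 0.134, "EMCI": 0.578, "LMCI": 0.741}

# median / (Q1, Q3) targets
_PTAU_MED_IQR = {
    "CN": (27.60, 22.38, 38.82),
    "EMCI": (40.40, 28.82, 59.30),
    "LMCI": (53.00, 39.62, 71.50),
}

# MMSE: discrete pmfs over scores, matched to the printed median and IQR
# endpoints (CN 30 (29,30); EMCI 29 (28,30); LMCI 28 (26,29))
_MMSE_PMF = {
    "CN": {27: 0.05, 28: 0.10, 29: 0.30, 30: 0.55},
    "EMCI": {26: 0.05, 27: 0.10, 28: 0.20, 29: 0.35, 30: 0.30},
    "LMCI": {24: 0.04, 25: 0.06, 26: 0.15, 27: 0.15, 28: 0.25, 29: 0.25, 30: 0.10},
}

_MMSE_MED_IQR = {"CN": (30, 29, 30), "EMCI": (29, 28, 30), "LMCI": (28, 26, 29)}

# not reported in the calibration table; plausible fixed values
_TIV_MEAN_SD = (1475.0, 145.0)
_TTAU_PTAU_RATIO = (3.0, 0.25)

DEFAULT_GROUP_SIZES = {"CN": 67, "EMCI": 83, "LMCI": 58}


def _calibrated_truncnorm_loc(
    target_mean: float, sd: float, lower: float, upper: float
) -> float:
    """Location parameter such that the [lower, upper]-truncated normal with
    scale *sd* has mean exactly *target_mean*."""

    def f(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    span = 6.0 * sd
    return optimize.brentq(f, target_mean - span, target_mean + span, xtol=1e-10)


def _draw_truncnorm(
    rng: np.random.Generator,
    n: int,
    target_mean: float,
    sd: float,
    lower: float,
    upper: float,
) -> np.ndarray:
    loc = _calibrated_truncnorm_loc(target_mean, sd, lower, upper)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _draw_lognormal_med_iqr(
    rng: np.random.Generator, n: int, median: float, q1: float, q3: float
) -> np.ndarray:
    # lognormal matched to the printed median and quartile spread
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75))
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def _draw_lm2(rng: np.random.Generator, group: str, education: float) -> int:
    cn_min, emci_lo, emci_hi, lmci_max = lm2_cutoffs(education)
    if group == "CN":
        return int(cn_min + rng.integers(0, 10))
    if group == "EMCI":
        return int(rng.integers(emci_lo, emci_hi + 1))
    return int(rng.integers(0, lmci_max + 1))


def _draw_suvr(rng: np.random.Generator, amyloid: str, tracer: str) -> float:
    cut = SUVR_CUTOFF[tracer]
    # status-consistent PET signal (CSF remains definitive either way)
    if amyloid == "Apos":
        return float(cut + abs(rng.normal(0.18, 0.08)) + 0.01)
    return float(max(cut - abs(rng.normal(0.10, 0.05)) - 0.01, 0.5))


def generate_cohort(
    n_cn: int = DEFAULT_GROUP_SIZES["CN"],
    n_emci: int = DEFAULT_GROUP_SIZES["EMCI"],
    n_lmci: int = DEFAULT_GROUP_SIZES["LMCI"],
    seed: int = 0,
    suvr_fraction: float = 0.5,
) -> list[SubjectRecord]:
    """Generate a calibrated synthetic cohort.

    Group labels are self-consistent under :func:`assign_amyloid_status` and
    :func:`assign_group_label`: CN subjects draw Abeta42 above the positivity
    cutoff, MCI subjects below it, and LM-II scores are drawn inside the
    assigned group's education-stratified range.
    """
    for name, n in (("n_cn", n_cn), ("n_emci", n_emci), ("n_lmci", n_lmci)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    counts = {"CN": n_cn, "EMCI": n_emci, "LMCI": n_lmci}
    group_seeds = np.random.SeedSequence(seed).spawn(len(GROUPS))
    records: list[SubjectRecord] = []
    for group, ss in zip(GROUPS, group_seeds):
        n = counts[group]
        if n == 0:
            continue
        rng = np.random.default_rng(ss)
        age = _draw_truncnorm(rng, n, *_MEAN_SD["age"][group], 55.0, 90.0)
        education = _draw_truncnorm(rng, n, *_MEAN_SD["education"][group], 0.0, 26.0)
        moca = _draw_truncnorm(rng, n, *_MEAN_SD["moca"][group], 0.0, 30.0)
        adas13 = _draw_truncnorm(rng, n, *_MEAN_SD["adas13"][group], 0.0, 85.0)
        if group == "CN":
            abeta42 = _draw_truncnorm(
                rng, n, *_MEAN_SD["abeta42"][group], ABETA42_CUTOFF, 400.0
            )
        else:
            abeta42 = _draw_truncnorm(
                rng, n, *_MEAN_SD["abeta42"][group], 40.0, ABETA42_CUTOFF - 1e-9
            )
        sex = np.where(rng.random(n) < _MALE_FRAC[group], "M", "F")
        apoe4 = (rng.random(n) < _APOE4_FRAC[group]).astype(int)
        mmse_scores = np.array(sorted(_MMSE_PMF[group]), dtype=float)
        mmse_probs = np.array([_MMSE_PMF[group][int(s)] for s in mmse_scores])
        mmse = rng.choice(mmse_scores, size=n, p=mmse_probs / mmse_probs.sum())
        ptau = _draw_lognormal_med_iqr(rng, n, *_PTAU_MED_IQR[group])
        ttau = ptau * np.clip(rng.normal(*_TTAU_PTAU_RATIO, size=n), 1.5, 5.0)
        tiv = np.clip(rng.normal(*_TIV_MEAN_SD, size=n), 900.0, 2200.0)
        has_pet = rng.random(n) < suvr_fraction
        tracers = rng.choice(["FBP", "FBB"], size=n)
        for i in range(n):
            amyloid = assign_amyloid_status(float(abeta42[i]))
            tracer = str(tracers[i]) if has_pet[i] else "none"
            suvr = _draw_suvr(rng, amyloid, tracer) if has_pet[i] else None
            lm2 = _draw_lm2(rng, group, float(education[i]))
            rec = SubjectRecord(
                subject_id=f"sub-{group}-{i:04d}",
                group=group,
                age=float(age[i]),
                sex=str(sex[i]),
                education=float(education[i]),
                apoe4=int(apoe4[i]),
                tiv=float(tiv[i]),
                mmse=float(mmse[i]),
                moca=float(moca[i]),
                adas13=float(adas13[i]),
                lm2=float(lm2),
                abeta42=float(abeta42[i]),
                ptau=float(ptau[i]),
                ttau=float(ttau[i]),
                suvr=suvr,
                tracer=tracer,
                amyloid=amyloid,
            )
            assert assign_group_label(rec.lm2, rec.education, rec.amyloid) == group
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# ROI sample generation
# ---------------------------------------------------------------------------

# metric -> (baseline lo, baseline hi, between-subject SD, within-ROI SD)
_METRIC_SCALES = {
    "GMV": (0.30, 0.70, 0.05, 0.10),
    "CT": (2.00, 3.50, 0.15, 0.30),
    "SD": (5.00, 15.0, 1.00, 2.00),
    "FD": (2.20, 2.60, 0.04, 0.08),
    "GI": (2.00, 4.00, 0.25, 0.50),
}

_GROUP_EFFECT_FIELD = {"CN": None, "EMCI": "effect_size_emci", "LMCI": "effect_size_lmci"}


def generate_roi_samples(
    cohort: Sequence[SubjectRecord],
    metric: str,
    atlas: str | None = None,
    cfg: EffectConfig = DEFAULT_GMV_EFFECT,
) -> list[RoiSampleSet]:
    """Draw per-subject, per-ROI morphometric sample vectors.

    Each subject's ROI samples come from a subject-specific Gaussian whose
    mean is the ROI baseline plus the group effect (in between-subject SD
    units) plus subject-level noise. When ``cfg.cognition_coupling`` is
    non-zero, each record's ``adas13`` is regenerated in place as the group
    baseline plus the coupling times the subject's standardized mean value
    over the affected ROIs, so regional atrophy propagates into cognition.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    atlas = atlas or atlas_for_metric(metric)
    if atlas_for_metric(metric) != atlas:
        raise ValueError(f"metric {metric!r} pairs with {atlas_for_metric(metric)!r}")
    labels = atlas_labels(atlas)
    lo, hi, bsd, wsd = _METRIC_SCALES[metric]
    affected = [roi for a, roi in cfg.affected_rois if a == atlas]
    affected_idx = [labels.index(r) for r in affected]

    root = np.random.SeedSequence((cfg.seed, METRICS.index(metric)))
    base_ss, *subj_ss = root.spawn(1 + len(cohort))
    base_rng = np.random.default_rng(base_ss)
    roi_base = base_rng.uniform(lo, hi, size=len(labels))

    out: list[RoiSampleSet] = []
    subj_affected_mean = np.zeros(len(cohort))
    for k, (rec, ss) in enumerate(zip(cohort, subj_ss)):
        rng = np.random.default_rng(ss)
        eff_field = _GROUP_EFFECT_FIELD[rec.group]
        shift = getattr(cfg, eff_field) if eff_field else 0.0
        subj_means = roi_base + rng.normal(0.0, bsd, size=len(labels))
        if affected_idx:
            subj_means[affected_idx] += shift * bsd
        counts = np.maximum(
            rng.poisson(cfg.samples_per_roi_mean, size=len(labels)), MIN_SAMPLES
        )
        samples = {
            lab: rng.normal(subj_means[j], wsd, size=int(counts[j]))
            for j, lab in enumerate(labels)
        }
        out.append(RoiSampleSet(rec.subject_id, metric, atlas, samples))
        if affected_idx:
            subj_affected_mean[k] = np.mean(
                (subj_means[affected_idx] - roi_base[affected_idx]) / bsd
            )
    if affected_idx and cfg.cognition_coupling != 0.0:
        cog_rng = np.random.default_rng(root.spawn(1)[0])
        for k, rec in enumerate(cohort):
            base = _MEAN_SD["adas13"][rec.group][0]
            val = base + cfg.cognition_coupling * subj_affected_mean[k]
            val += cog_rng.normal(0.0, cfg.noise_sd)
            rec.adas13 = float(np.clip(val, 0.0, 85.0))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education", "apoe4", "tiv",
    "mmse", "moca", "adas13", "lm2", "abeta42", "ptau", "ttau",
    "suvr", "tracer", "amyloid",
]


def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {c: (getattr(r, c) if getattr(r, c) is not None else np.nan) for c in COHORT_COLUMNS}
        for r in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in df.iterrows():
        suvr = row["suvr"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                apoe4=int(row["apoe4"]),
                tiv=float(row["tiv"]),
                mmse=float(row["mmse"]),
                moca=float(row["moca"]),
                adas13=float(row["adas13"]),
                lm2=float(row["lm2"]),
                abeta42=float(row["abeta42"]),
                ptau=float(row["ptau"]),
                ttau=float(row["ttau"]),
                suvr=None if pd.isna(suvr) else float(suvr),
                tracer=str(row["tracer"]),
                amyloid=str(row["amyloid"]),
            )
        )
    return records


def samples_to_frame(sample_sets: Sequence[RoiSampleSet]) -> pd.DataFrame:
    frames = []
    for ss in sample_sets:
        for lab in ss.labels:
            vals = ss.samples[lab]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": ss.subject_id,
                        "atlas": ss.atlas,
                        "roi_label": lab,
                        "value": vals,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["subject_id", "atlas", "roi_label", "value"])
    return pd.concat(frames, ignore_index=True)


def frame_to_samples(df: pd.DataFrame, metric: str) -> list[RoiSampleSet]:
    out = []
    for (sid, atlas), sub in df.groupby(["subject_id", "atlas"], sort=False):
        samples = {
            str(lab): grp["value"].to_numpy(dtype=float)
            for lab, grp in sub.groupby("roi_label", sort=False)
        }
        out.append(RoiSampleSet(str(sid), metric, str(atlas), samples))
    return out


def write_cohort(
    cohort: Sequence[SubjectRecord],
    roi_samples: Mapping[str, Sequence[RoiSampleSet]],
    directory: str | os.PathLike,
) -> dict[str, str]:
    """Write cohort.csv plus one long-format roi_samples_<metric>.tsv per
    metric; returns the mapping of artifact name to path."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    try:
        cohort_path = os.path.join(directory, "cohort.csv")
        cohort_to_frame(cohort).to_csv(cohort_path, index=False, float_format="%.17g")
        paths["cohort"] = cohort_path
        for metric, sets in roi_samples.items():
            if metric not in METRICS:
                raise ValueError(f"unknown metric {metric!r}")
            p = os.path.join(directory, f"roi_samples_{metric}.tsv")
            samples_to_frame(sets).to_csv(p, sep="\t", index=False, float_format="%.17g")
            paths[f"roi_samples_{metric}"] = p
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {directory}: {exc}") from exc
    return paths


def read_cohort(directory: str | os.PathLike) -> list[SubjectRecord]:
    path = os.path.join(directory, "cohort.csv")
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str,
                                  "tracer": str, "amyloid": str},
                     float_precision="round_trip")
    return frame_to_cohort(df)


def read_roi_samples(directory: str | os.PathLike, metric: str) -> list[RoiSampleSet]:
    path = os.path.join(directory, f"roi_samples_{metric}.tsv")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"subject_id": str, "atlas": str, "roi_label": str})
    return frame_to_samples(df, metric)
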