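"""Synthetic longitudinal infant cohort with known ground truth.

Emulates the design of a two-site infant neuroimaging study over the first
27 postnatal months (0-810 days, 1 month = 30 days): unbalanced longitudinal
sampling with a majority of singleton subjects, two sexes, subject random
intercepts, structure-specific growth curves (log-saturating for five
subcortical structures, linear for the amygdala analog), intracranial-volume
(ICV) co-growth, and behavioral scores with planted volume-ratio effects.

The generator returns the ground truth alongside the data so every
downstream stage (trajectory fitting, growth inference, surface expansion,
behavior association) can be tested for parameter recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "STRUCTURES",
    "HEMISPHERES",
    "MULLEN_SCORES",
    "DAYS_PER_MONTH",
    "AGE_MAX_DAYS",
    "CohortConfig",
    "StructureCurve",
    "GrowthTruth",
    "ScanRecord",
    "default_truth",
    "flat_truth",
    "generate_cohort",
    "generate_mullen",
]

STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
)
HEMISPHERES = ("L", "R")
MULLEN_SCORES = ("GM", "FM", "VR", "RL", "EL", "ELC")
DAYS_PER_MONTH = 30.0
AGE_MAX_DAYS = 810  # 27 months


def volume_column(structure: str, hemisphere: str) -> str:
    return f"vol_{structure}_{hemisphere}"


def _check_probs(name, probs):
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-8):
        raise ValueError(
            f"{name} must be nonnegative and sum to 1; got {probs}"
        )


@dataclass
class CohortConfig:
    """Sampling design of the synthetic cohort.

    Defaults follow the emulated study: 231 subjects, two scan sites, ages
    0-810 days with denser sampling between 3 and 15 months, 45% of subjects
    with two or more scans and 12% with three or more.
    """

    n_subjects: int = 231
    age_range: tuple[int, int] = (0, AGE_MAX_DAYS)
    scans_per_subject_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.33, 3: 0.08, 4: 0.04}
    )
    site_probabilities: dict[str, float] = field(
        default_factory=lambda: {"siteA": 0.5, "siteB": 0.5}
    )
    sex_probabilities: dict[str, float] = field(
        default_factory=lambda: {"female": 0.545, "male": 0.455}
    )
    noise_sd: float = 60.0             # residual volume noise, mm^3
    random_intercept_sd: float = 60.0  # subject intercept SD, mm^3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.random_intercept_sd < 0:
            raise ValueError(
                f"random_intercept_sd must be >= 0, got {self.random_intercept_sd}"
            )
        lo, hi = self.age_range
        if not (0 <= lo < hi <= AGE_MAX_DAYS):
            raise ValueError(
                f"age_range must satisfy 0 <= lo < hi <= {AGE_MAX_DAYS}, "
                f"got {self.age_range}"
            )
        _check_probs("scans_per_subject_distribution",
                     self.scans_per_subject_distribution)
        _check_probs("site_probabilities", self.site_probabilities)
        _check_probs("sex_probabilities", self.sex_probabilities)


@dataclass(frozen=True)
class StructureCurve:
    """Closed-form population growth curve of one structure (one hemisphere).

    families:
        log_saturating: V(t) = a + b * log(1 + t / c)
        logistic:       V(t) = a + b / (1 + exp(-(t - m) / s))
        linear:         V(t) = a + b * t
    """

    family: str
    params: dict[str, float]

    def value(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "log_saturating":
            return p["a"] + p["b"] * np.log1p(t / p["c"])
        if self.family == "logistic":
            return p["a"] + p["b"] / (1.0 + np.exp(-(t - p["m"]) / p["s"]))
        if self.family == "linear":
            return p["a"] + p["b"] * t
        raise ValueError(f"unknown curve family {self.family!r}")

    def derivative(self, t):
        """dV/dt in volume units per day (closed form)."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "log_saturating":
            return p["b"] / (p["c"] + t)
        if self.family == "logistic":
            z = np.exp(-(t - p["m"]) / p["s"])
            return p["b"] * z / (p["s"] * (1.0 + z) ** 2)
        if self.family == "linear":
            return np.full_like(t, p["b"], dtype=float)
        raise ValueError(f"unknown curve family {self.family!r}")


@dataclass
class GrowthTruth:
    """Ground truth behind a synthetic cohort.

    curves : per (structure, hemisphere) population curve.
    sex_gain : per structure, fractional male surplus that accrues with
        growth: Delta(t) = sex_gain * (V(t) - V(0)), added for males.
    site_offsets : per site, per structure, additive volume offset (mm^3).
    icv_curve : population ICV growth curve.
    icv_coefficient : per structure, volume change per mm^3 of a subject's
        ICV deviation from the population ICV curve.
    behavior_effects : {(structure, score): coefficient}, in score units per
        SD of the log volume-to-ICV ratio.
    mesh_truth : planted surface patches, filled by mesh generation.
    """

    curves: dict
    sex_gain: dict
    site_offsets: dict
    icv_curve: StructureCurve
    icv_coefficient: dict
    behavior_effects: dict = field(default_factory=dict)
    behavior_noise_sd: float = 5.0
    behavior_subject_sd: float = 3.0
    mesh_truth: object = None

    def expected_volume(self, structure, hemisphere, age_days, sex, site, icv):
        """Deterministic part of a scan's volume given its realized ICV."""
        curve = self.curves[(structure, hemisphere)]
        v = curve.value(age_days)
        if sex == "male":
            v = v + self.sex_gain[structure] * (v - curve.value(0.0))
        v = v + self.site_offsets[site][structure]
        v = v + self.icv_coefficient[structure] * (
            np.asarray(icv, dtype=float) - self.icv_curve.value(age_days)
        )
        return v

    def population_curve(
        self, structure, hemisphere, ages, sex=None,
        sex_probabilities=None, site_probabilities=None,
    ):
        """Population-level truth curve at mean ICV, averaged over sites.

        ``sex=None`` averages over sexes with the given probabilities.
        """
        ages = np.asarray(ages, dtype=float)
        curve = self.curves[(structure, hemisphere)]
        v = curve.value(ages)
        growth = v - curve.value(0.0)
        if sex == "male":
            v = v + self.sex_gain[structure] * growth
        elif sex is None:
            p_male = (sex_probabilities or {"male": 0.5}).get("male", 0.5)
            v = v + p_male * self.sex_gain[structure] * growth
        site_probs = site_probabilities or {
            s: 1.0 / len(self.site_offsets) for s in self.site_offsets
        }
        v = v + sum(
            p * self.site_offsets[s][structure] for s, p in site_probs.items()
        )
        return v


@dataclass
class ScanRecord:
    """One longitudinal observation (one MRI scan of one subject)."""

    subject_id: str
    age_days: int
    sex: str
    site: str
    icv: float
    volumes: dict
    income: int | None = None
    maternal_education: int | None = None
    mullen: dict | None = None

    def validate(self, age_range=(0, AGE_MAX_DAYS)) -> None:
        lo, hi = age_range
        if not (lo <= self.age_days <= hi):
            raise ValueError(
                f"age_days={self.age_days} outside [{lo}, {hi}] for "
                f"subject {self.subject_id}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex level {self.sex!r}")
        bad = [k for k, v in self.volumes.items() if v <= 0]
        if bad:
            raise ValueError(f"nonpositive volume for {bad}")
        if self.icv <= max(self.volumes.values()):
            raise ValueError("icv must exceed every single-structure volume")


# --------------------------------------------------------------------------- #
# default ground truth
# --------------------------------------------------------------------------- #

# per-hemisphere volumes at birth (mm^3) and fractional growth to 24 months,
# with a time constant controlling how front-loaded the growth is
_TRUTH_SPEC = {
    # structure: (V0, growth 0-24M, c days)
    "thalamus": (3800.0, 0.45, 60.0),
    "caudate": (1600.0, 1.06, 150.0),
    "putamen": (1750.0, 1.15, 140.0),
    "pallidum": (650.0, 0.97, 45.0),
    "hippocampus": (1500.0, 0.66, 120.0),
}
_AMYGDALA_V0 = 480.0
_AMYGDALA_GROWTH = 0.52  # fractional growth by 24 months, linear in time
_HEMI_FACTOR = {"L": 1.0, "R": 0.97}  # mild lateral difference
_SEX_GAIN = {
    "thalamus": 0.08,
    "caudate": 0.02,
    "putamen": 0.07,
    "pallidum": 0.08,
    "hippocampus": 0.06,
    "amygdala": 0.04,
}
_ICV_SUBJECT_CV = 0.045  # between-subject ICV scale SD (fraction)
_DAY_24M = 720.0


def default_truth() -> GrowthTruth:
    """Ground truth mirroring the qualitative growth shapes of the study."""
    curves = {}
    for hemi in HEMISPHERES:
        f = _HEMI_FACTOR[hemi]
        for name, (v0, growth, c) in _TRUTH_SPEC.items():
            b = growth * v0 / math.log1p(_DAY_24M / c)
            curves[(name, hemi)] = StructureCurve(
                "log_saturating", {"a": v0 * f, "b": b * f, "c": c}
            )
        curves[("amygdala", hemi)] = StructureCurve(
            "linear",
            {"a": _AMYGDALA_V0 * f,
             "b": _AMYGDALA_GROWTH * _AMYGDALA_V0 * f / _DAY_24M},
        )
    icv_curve = StructureCurve(
        "log_saturating",
        {"a": 450_000.0, "b": 650_000.0 / math.log1p(_DAY_24M / 90.0),
         "c": 90.0},
    )
    site_offsets = {
        "siteA": {s: +0.01 * _birth_volume(s) for s in STRUCTURES},
        "siteB": {s: -0.01 * _birth_volume(s) for s in STRUCTURES},
    }
    icv_coef = {
        s: 0.5 * _birth_volume(s) / icv_curve.value(0.0) for s in STRUCTURES
    }
    behavior_effects = {
        ("thalamus", "RL"): 3.5,
        ("thalamus", "EL"): 3.0,
        ("caudate", "FM"): 2.0,
        ("putamen", "FM"): 2.2,
    }
    return GrowthTruth(
        curves=curves,
        sex_gain=dict(_SEX_GAIN),
        site_offsets=site_offsets,
        icv_curve=icv_curve,
        icv_coefficient=icv_coef,
        behavior_effects=behavior_effects,
    )


def flat_truth() -> GrowthTruth:
    """Null ground truth: constant volumes, no sex gain (calibration runs)."""
    truth = default_truth()
    flat_curves = {
        key: StructureCurve("linear", {"a": c.value(0.0), "b": 0.0})
        for key, c in truth.curves.items()
    }
    truth.curves = flat_curves
    truth.sex_gain = {s: 0.0 for s in STRUCTURES}
    truth.behavior_effects = {}
    return truth


def _birth_volume(structure: str) -> float:
    if structure == "amygdala":
        return _AMYGDALA_V0
    return _TRUTH_SPEC[structure][0]


# --------------------------------------------------------------------------- #
# cohort generation
# --------------------------------------------------------------------------- #

def _sample_ages(rng, n_scans, lo, hi):
    """Scan ages in days, mimicking an infant visit design qualitatively:
    a neonatal-visit component near the lower bound, a dense component
    around 3-15 months, and a uniform component covering the full span."""
    ages = set()
    mode = min(max(270.0, lo + 1.0), hi - 1.0)
    while len(ages) < n_scans:
        u = rng.random()
        if u < 0.15:
            a = rng.uniform(lo, min(lo + 90.0, hi))
        elif u < 0.75:
            a = rng.triangular(lo, mode, hi)
        else:
            a = rng.uniform(lo, hi)
        ages.add(int(round(a)))
    return sorted(ages)


def generate_cohort(
    config: CohortConfig, truth: GrowthTruth | None = None
) -> tuple[pd.DataFrame, GrowthTruth]:
    """Generate a longitudinal cohort table and the truth that produced it.

    Returns a DataFrame with one row per scan (columns: subject_id,
    age_days, sex, site, icv, income, maternal_education and one
    ``vol_<structure>_<hemi>`` column per structure/hemisphere) plus the
    :class:`GrowthTruth`.  Deterministic given ``config.seed``.
    """
    config.validate()
    if truth is None:
        truth = default_truth()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    scan_counts = list(config.scans_per_subject_distribution.keys())
    scan_probs = list(config.scans_per_subject_distribution.values())
    sites = list(config.site_probabilities.keys())
    site_probs = list(config.site_probabilities.values())
    sexes = list(config.sex_probabilities.keys())
    sex_probs = list(config.sex_probabilities.values())

    rows = []
    for i in range(config.n_subjects):
        sid = f"sub{i:04d}"
        sex = str(rng.choice(sexes, p=sex_probs))
        site = str(rng.choice(sites, p=site_probs))
        n_scans = int(rng.choice(scan_counts, p=scan_probs))
        ages = _sample_ages(rng, n_scans, lo, hi)
        income = int(rng.integers(1, 6))
        edu = int(rng.random() < 0.5)
        icv_scale = math.exp(rng.normal(0.0, _ICV_SUBJECT_CV))
        intercepts = {
            (s, h): rng.normal(0.0, config.random_intercept_sd)
            for s in STRUCTURES for h in HEMISPHERES
        }
        for age in ages:
            icv = truth.icv_curve.value(age) * icv_scale + rng.normal(0, 2000.0)
            row = {
                "subject_id": sid,
                "age_days": age,
                "sex": sex,
                "site": site,
                "icv": float(icv),
                "income": income,
                "maternal_education": edu,
            }
            for s in STRUCTURES:
                for h in HEMISPHERES:
                    v = truth.expected_volume(s, h, age, sex, site, icv)
                    v = v + intercepts[(s, h)] + rng.normal(0, config.noise_sd)
                    if v <= 0:
                        raise ValueError(
                            f"generated nonpositive volume for {s}_{h}; "
                            "noise_sd and/or random_intercept_sd too large "
                            "for the smallest structure"
                        )
                    row[volume_column(s, h)] = float(v)
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame, truth


# --------------------------------------------------------------------------- #
# behavior scores
# --------------------------------------------------------------------------- #

def generate_mullen(
    records: pd.DataFrame,
    truth: GrowthTruth,
    seed: int,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Fill Mullen-style standardized scores (mean ~50, SD ~10) per scan.

    Each score is a linear combination of standardized household covariates
    plus the planted effects of standardized log volume-to-ICV ratios (from
    ``truth.behavior_effects``), a subject intercept, and Gaussian noise.
    The composite ELC additionally aggregates FM, VR, RL and EL.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    if n == 0:
        raise ValueError("no records to score")

    age = out["age_days"].to_numpy(dtype=float)
    age_design = np.column_stack([np.ones(n), age])
    zratio = {}
    for s in STRUCTURES:
        cols = [volume_column(s, h) for h in HEMISPHERES]
        if any(c not in out.columns for c in cols):
            log.warning("missing volumes for %s; structure skipped", s)
            continue
        vol = out[cols].sum(axis=1).to_numpy()
        ratio = np.log(vol / out["icv"].to_numpy())
        # scores are age-normalized, so the planted effect acts on the
        # age-adjusted relative volume: the coefficient is then exactly the
        # partial effect an age-controlled association model estimates
        coef, *_ = np.linalg.lstsq(age_design, ratio, rcond=None)
        resid = ratio - age_design @ coef
        zratio[s] = (resid - resid.mean()) / max(resid.std(), 1e-12)

    z_income = _zscore(out["income"].to_numpy(dtype=float))
    z_edu = _zscore(out["maternal_education"].to_numpy(dtype=float))

    subjects, sub_idx = np.unique(out["subject_id"], return_inverse=True)
    base_scores = [s for s in MULLEN_SCORES if s != "ELC"]
    u = rng.normal(0.0, truth.behavior_subject_sd, (subjects.size, len(base_scores)))

    raw = {}
    for j, score in enumerate(base_scores):
        eta = 1.0 * z_income + 1.0 * z_edu
        for s, z in zratio.items():
            beta = truth.behavior_effects.get((s, score), 0.0)
            eta = eta + beta * z
        raw[score] = (
            50.0 + eta + u[sub_idx, j]
            + rng.normal(0.0, truth.behavior_noise_sd, n)
        )
    raw["ELC"] = np.mean([raw[s] for s in ("FM", "VR", "RL", "EL")], axis=0)

    for score in MULLEN_SCORES:
        vals = raw[score]
        if missing_rate > 0:
            mask = rng.random(n) < missing_rate
            vals = np.where(mask, np.nan, vals)
        out[f"mullen_{score}"] = vals
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
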