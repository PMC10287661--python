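"""Interval growth rates and stratified-bootstrap inference.

The population-level growth rate between two ages is the fractional change
of the fitted curve, [Y(t2) - Y(t1)] / Y(t1).  Uncertainty comes from a
stratified bootstrap for longitudinal data: whole subjects are resampled
with replacement (all scans of a drawn subject move together), within
strata that preserve the design margins (site x number-of-scans category by
default).  Each replicate is refit with the point estimate's smoothing
parameters held fixed; a Z-statistic |Y(t2) - Y(t1)| / SD[Y(t2) - Y(t1)]
with the bootstrap SD gives two-sided normal p-values, Bonferroni-corrected
over the simultaneous cells of a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DAYS_PER_MONTH
from .gamm import FittedCurve, TrajectoryModel

log = logging.getLogger(__name__)

__all__ = [
    "IntervalSpec",
    "DEFAULT_INTERVALS",
    "interval_growth_rate",
    "BootstrapCurves",
    "stratified_bootstrap",
    "growth_significance",
    "growth_table",
    "sex_effect_test",
    "asymmetry_index",
]


@dataclass(frozen=True)
class IntervalSpec:
    """A growth interval in months (converted to days at 30 days/month)."""

    t1: float
    t2: float

    def __post_init__(self):
        if not (0 <= self.t1 < self.t2 <= 27):
            raise ValueError(
                f"interval must satisfy 0 <= t1 < t2 <= 27 months, got "
                f"({self.t1}, {self.t2})"
            )

    @property
    def days(self) -> tuple[float, float]:
        return self.t1 * DAYS_PER_MONTH, self.t2 * DAYS_PER_MONTH

    @property
    def label(self) -> str:
        return f"{_fmt(self.t1)}M-{_fmt(self.t2)}M"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


#: the nine reporting intervals of the growth-rate tables
DEFAULT_INTERVALS = tuple(
    IntervalSpec(a, b)
    for a, b in [(0, 3), (3, 6), (6, 9), (9, 12), (12, 18), (18, 24),
                 (0, 6), (0, 12), (0, 24)]
)


def interval_growth_rate(curve: FittedCurve, interval: IntervalSpec) -> float:
    """Fractional growth of the fitted curve over the interval."""
    d1, d2 = interval.days
    y1 = float(curve.at(d1))
    y2 = float(curve.at(d2))
    if y1 <= 0:
        raise ValueError(
            f"curve value at {interval.t1}M is nonpositive ({y1:g}); "
            "growth rate undefined"
        )
    return (y2 - y1) / y1


# --------------------------------------------------------------------------- #
# stratified bootstrap
# --------------------------------------------------------------------------- #

@dataclass
class BootstrapCurves:
    """Replicate population curves from a subject-level bootstrap."""

    grid: np.ndarray                  # days
    curves: dict                      # stratum -> (B, len(grid)) array
    betas: np.ndarray                 # (B, q) replicate coefficients
    n_requested: int
    n_failed: int
    seed: int

    @property
    def n_replicates(self) -> int:
        return next(iter(self.curves.values())).shape[0]

    def values_at(self, age_days: float, stratum: str) -> np.ndarray:
        arr = self.curves[stratum]
        return np.array(
            [np.interp(age_days, self.grid, arr[b]) for b in range(len(arr))]
        )


def _scan_category(n: int) -> str:
    return "1" if n == 1 else ("2" if n == 2 else "3+")


def _strata_labels(subject_table: pd.DataFrame, strata_by) -> np.ndarray:
    if strata_by is None:
        strata_by = ("site", "scan_category")
    tab = subject_table.copy()
    tab["scan_category"] = tab["n_scans"].map(_scan_category)
    missing = [c for c in strata_by if c not in tab.columns]
    if missing:
        raise KeyError(f"unknown stratification variables: {missing}")
    return tab[list(strata_by)].astype(str).agg("|".join, axis=1).to_numpy()


def stratified_bootstrap(
    model: TrajectoryModel,
    grid,
    B: int = 1000,
    seed: int = 0,
    strata_by=None,
    strata: np.ndarray | None = None,
    refit_lambda: bool = False,
) -> BootstrapCurves:
    """Subject-level stratified bootstrap of the population curves.

    Subjects are resampled with replacement within strata (default:
    site x {1, 2, 3+} scans), preserving each stratum's subject count; all
    scans of a drawn subject enter together.  Replicates reuse the point
    estimate's smoothing parameters and variance ratio unless
    ``refit_lambda`` is set.  Deterministic given ``seed``.
    """
    if model.engine is None:
        raise ValueError("model lacks fitting-time state; refit before bootstrap")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if B < 500:
        log.warning(
            "B=%d bootstrap replicates; inference below 500 is rough", B
        )
    eng = model.engine
    # subject order inside the engine (np.unique order)
    subj_order = pd.DataFrame({"subject_id": eng.subjects}).merge(
        model.subject_table, on="subject_id", how="left", sort=False
    )
    labels = (
        np.asarray(strata)
        if strata is not None
        else _strata_labels(subj_order, strata_by)
    )
    if labels.shape[0] != eng.S:
        raise ValueError("strata labels must have one entry per subject")

    rng = np.random.default_rng(seed)
    uniq = np.unique(labels)
    members = {u: np.flatnonzero(labels == u) for u in uniq}

    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    sex_strata = ["male", "female"] if model.with_sex else []
    design = {s: model.design(grid, s) for s in sex_strata + (
        [] if model.with_sex else ["pooled"])}
    icv_col = model.icv_col
    if icv_col is not None:
        D_icv = model._icv_design(grid)
    # subject-level quantities for replicate-specific pooling weights
    n_scans_s = subj_order["n_scans"].to_numpy(dtype=float)
    male_s = (subj_order["sex"].to_numpy() == "male").astype(float) \
        if model.with_sex else None

    betas = []
    curves = {s: [] for s in (sex_strata + ["pooled"]
                              if model.with_sex else ["pooled"])}
    n_failed = 0
    for _ in range(B):
        w = np.zeros(eng.S)
        for u in uniq:
            idx = members[u]
            draws = rng.integers(0, idx.size, idx.size)
            w[idx] += np.bincount(draws, minlength=idx.size)
        try:
            if refit_lambda:
                beta = _refit_full(eng, model, w)
            else:
                beta = eng.bootstrap_beta(
                    model.fit.lambdas, model.fit.ratio, model.rstats, w
                )
        except np.linalg.LinAlgError:
            n_failed += 1
            log.warning("bootstrap replicate failed to fit; dropped")
            continue
        # the cohort mean-ICV reference is itself resampled
        d_icv = 0.0
        if icv_col is not None:
            icv_coef = model.icv_engine.bootstrap_beta(
                model.icv_lambdas, model.icv_ratio, model.icv_rstats, w
            )
            d_icv = (D_icv @ (icv_coef - model.icv_ref_coef)) * beta[icv_col]
        if model.with_sex:
            male = design["male"] @ beta + d_icv
            female = design["female"] @ beta + d_icv
            wn = w * n_scans_s
            p_rep = float((wn * male_s).sum() / wn.sum())
            curves["male"].append(male)
            curves["female"].append(female)
            curves["pooled"].append((1 - p_rep) * female + p_rep * male)
        else:
            curves["pooled"].append(design["pooled"] @ beta + d_icv)
        betas.append(beta)
    if n_failed > 0.05 * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to fit"
        )
    betas = np.asarray(betas)
    curves = {s: np.asarray(v) for s, v in curves.items()}
    return BootstrapCurves(
        grid=grid,
        curves=curves,
        betas=betas,
        n_requested=B,
        n_failed=n_failed,
        seed=seed,
    )


def _refit_full(eng, model, w):
    """Replicate with smoothing parameters re-optimized.

    Warm-started at the point estimate with a loose tolerance: replicate
    criteria are smooth and close to the original, so a short quasi-Newton
    run recovers the replicate's own smoothing choice.
    """
    from scipy import optimize

    rstats = model.rstats

    def obj(theta):
        lam = np.exp(theta[:-1])
        r = np.exp(theta[-1])
        try:
            return eng.neg2loglik(lam, r, rstats, weights=w)
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.clip(np.concatenate(
        [np.log(model.fit.lambdas), [np.log(model.fit.ratio)]]
    ), -12.0, 28.0)
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B",
        bounds=[(-12.0, 28.0)] * x0.size,
        options={"ftol": 1e-6, "gtol": 1e-4, "maxiter": 40},
    )
    lam = np.exp(res.x[:-1])
    r = float(np.exp(res.x[-1]))
    return eng.bootstrap_beta(lam, r, rstats, w)


# --------------------------------------------------------------------------- #
# significance tables
# --------------------------------------------------------------------------- #

def growth_significance(
    point_curve: FittedCurve,
    boot: BootstrapCurves,
    intervals=DEFAULT_INTERVALS,
    m: int | None = None,
    stratum: str = "pooled",
) -> pd.DataFrame:
    """Z-tests of interval volume changes against zero for one curve.

    SD[Y(t2) - Y(t1)] comes from the bootstrap replicate distribution;
    Bonferroni correction uses ``m`` simultaneous tests (default: the number
    of intervals here — pass the full table size when combining).
    """
    rows = []
    m_eff = m if m is not None else len(intervals)
    for iv in intervals:
        d1, d2 = iv.days
        y1, y2 = float(point_curve.at(d1)), float(point_curve.at(d2))
        rate = interval_growth_rate(point_curve, iv)
        r1 = boot.values_at(d1, stratum)
        r2 = boot.values_at(d2, stratum)
        diffs = r2 - r1
        if len(diffs) < 2:
            raise ValueError("need >= 2 bootstrap replicates per cell")
        sd = float(diffs.std(ddof=1))
        delta = y2 - y1
        if sd == 0.0:
            z = 0.0 if delta == 0 else np.inf
            p = 1.0 if delta == 0 else 0.0
            if delta != 0:
                log.warning(
                    "zero bootstrap SD with nonzero change in %s; p set to 0",
                    iv.label,
                )
        else:
            z = abs(delta) / sd
            p = 2.0 * stats.norm.sf(z)
        p_adj = min(1.0, m_eff * p)
        rows.append(
            {
                "interval": iv.label,
                "t1_months": iv.t1,
                "t2_months": iv.t2,
                "stratum": stratum,
                "growth_rate": rate,
                "boot_sd_diff": sd,
                "z": z,
                "p": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < 0.05,
            }
        )
    return pd.DataFrame(rows)


def growth_table(
    models: dict,
    bootstraps: dict,
    intervals=DEFAULT_INTERVALS,
    strata=("male", "female"),
) -> pd.DataFrame:
    """Tidy growth-rate table over responses x sex strata x intervals.

    ``models`` maps response name -> TrajectoryModel, ``bootstraps`` maps the
    same keys -> BootstrapCurves.  Bonferroni m = cells in the whole table.
    """
    from .gamm import predict_curve

    m_total = len(models) * len(strata) * len(intervals)
    parts = []
    for name, model in models.items():
        boot = bootstraps[name]
        for s in strata:
            curve = predict_curve(model, boot.grid, s)
            tab = growth_significance(
                curve, boot, intervals, m=m_total, stratum=s
            )
            tab.insert(0, "response", name)
            parts.append(tab)
    return pd.concat(parts, ignore_index=True)


def sex_effect_test(
    model: TrajectoryModel, grid, boot: BootstrapCurves
) -> pd.DataFrame:
    """Pointwise bootstrap Z-test of the male-minus-female fitted difference."""
    if not model.with_sex:
        raise ValueError("model was fitted without a sex term")
    if "male" not in boot.curves or "female" not in boot.curves:
        raise ValueError("bootstrap lacks sex-stratified replicate curves")
    from .gamm import predict_curve

    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    diff = (
        predict_curve(model, grid, "male").estimate
        - predict_curve(model, grid, "female").estimate
    )
    rep_diff = np.vstack(
        [
            np.interp(grid, boot.grid, boot.curves["male"][b])
            - np.interp(grid, boot.grid, boot.curves["female"][b])
            for b in range(boot.n_replicates)
        ]
    )
    sd = rep_diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(diff) / sd, np.where(diff == 0, 0, np.inf))
    p = 2.0 * stats.norm.sf(z)
    return pd.DataFrame(
        {
            "age_days": grid,
            "male_minus_female": diff,
            "boot_sd": sd,
            "z": z,
            "p": p,
            "significant": p < 0.05,
        }
    )


def asymmetry_index(left: FittedCurve, right: FittedCurve) -> FittedCurve:
    """Left-right asymmetry AI(t) = (L - R) / ((L + R) / 2); positive = leftward."""
    if left.ages.shape != right.ages.shape or not np.allclose(
        left.ages, right.ages
    ):
        raise ValueError("curves must share a common age grid")
    mean = 0.5 * (left.estimate + right.estimate)
    if np.any(mean <= 0):
        raise ValueError("L + R must be positive everywhere")
    ai = (left.estimate - right.estimate) / mean
    return FittedCurve(
        ages=left.ages,
        estimate=ai,
        lower=np.full_like(ai, np.nan),
        upper=np.full_like(ai, np.nan),
        stratum=left.stratum,
        response=f"AI({left.response},{right.response})",
        units="asymmetry index",
    )
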