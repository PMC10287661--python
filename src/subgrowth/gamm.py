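"""Penalized-spline growth-trajectory models (GAMM) for volumes.

Two model forms are supported, for a response y_i(t) (a structure volume or
a vertex area) of subject i at age t (days):

    with sex:    y_i(t) = site_i + b*ICV_i(t) + f(t) + D(t)*male_i + a_i + e_i(t)
    without sex: y_i(t) = site_i + b*ICV_i(t) + f(t) + a_i + e_i(t)

f and D are penalized cubic splines (sum-to-zero constrained), a_i is a
subject random intercept, e iid Gaussian.  Smoothing parameters and the
variance ratio are selected by maximizing the exact Gaussian marginal
likelihood (REML optional).  Population-level curves are predicted at the
site-frequency-weighted reference and the cohort mean ICV-versus-age curve
(30-day binned means, linearly interpolated); derivatives are analytic and
reported per month (30 days).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import LMMFit, PenalizedLMM
from .cohort import DAYS_PER_MONTH, volume_column
from .splines import SplineBasis, build_spline_basis

log = logging.getLogger(__name__)

__all__ = [
    "FittedCurve",
    "TrajectoryModel",
    "fit_gamm",
    "predict_curve",
    "derivative_curve",
    "normalized_curve",
]

_Z95 = 1.959963984540054


@dataclass
class FittedCurve:
    """A fitted population curve with a pointwise 95% confidence band."""

    ages: np.ndarray       # days
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    stratum: str           # "male", "female" or "pooled"
    response: str = ""
    units: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_days": self.ages,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "stratum": self.stratum,
                "response": self.response,
                "units": self.units,
            }
        )

    def at(self, age):
        """Linear interpolation of the point estimate at ``age`` (days)."""
        age = np.asarray(age, dtype=float)
        lo, hi = float(self.ages.min()), float(self.ages.max())
        if np.any(age < lo - 1e-9) or np.any(age > hi + 1e-9):
            raise ValueError(f"age outside curve grid [{lo:g}, {hi:g}]")
        return np.interp(age, self.ages, self.estimate)


def _smooth_transform(basis: SplineBasis, design_ages: np.ndarray):
    """Sum-to-zero constraint + natural reparametrization of the penalty.

    Returns (T_null, T_range): K x d0 and K x dr maps from the raw B-spline
    basis to an unpenalized null-space column block and a penalized block
    with identity penalty.
    """
    B = basis.evaluate(design_ages)
    c = B.mean(axis=0)
    K = basis.k
    Q, _ = np.linalg.qr(np.column_stack([c / np.linalg.norm(c), np.eye(K)]))
    Zc = Q[:, 1:K]
    S = Zc.T @ basis.penalty() @ Zc
    d, U = np.linalg.eigh(S)
    tol = max(d.max(), 1e-12) * 1e-9
    null = d < tol
    T_null = Zc @ U[:, null]
    T_range = Zc @ (U[:, ~null] / np.sqrt(d[~null]))
    return T_null, T_range


@dataclass
class TrajectoryModel:
    """A fitted growth-trajectory model (coefficients + prediction recipe)."""

    response: str
    with_sex: bool
    fit: LMMFit
    basis_f: SplineBasis
    t_null_f: np.ndarray
    t_range_f: np.ndarray
    basis_sex: SplineBasis | None
    t_null_sex: np.ndarray | None
    t_range_sex: np.ndarray | None
    site_levels: list
    site_freqs: np.ndarray
    p_male: float
    include_icv: bool
    icv_mean: float
    icv_ref_coef: np.ndarray | None  # [const, null, range] coefs on basis_f
    span: tuple[float, float]
    units: str = "mm^3"
    # fitting-time objects (not serialized); enable fast subject bootstrap
    engine: PenalizedLMM | None = field(default=None, repr=False)
    rstats: tuple | None = field(default=None, repr=False)
    subject_table: pd.DataFrame | None = field(default=None, repr=False)
    icv_engine: PenalizedLMM | None = field(default=None, repr=False)
    icv_rstats: tuple | None = field(default=None, repr=False)
    icv_lambdas: np.ndarray | None = field(default=None, repr=False)
    icv_ratio: float | None = field(default=None, repr=False)

    @property
    def icv_col(self) -> int | None:
        """Column index of the ICV covariate in the design/coefficients."""
        if not self.include_icv:
            return None
        return 1 + max(len(self.site_levels) - 1, 0)

    # ---------------- design construction ---------------- #

    def _icv_design(self, ages, deriv=False):
        B = (
            self.basis_f.derivative(ages)
            if deriv
            else self.basis_f.evaluate(ages)
        )
        const = np.zeros(len(B)) if deriv else np.ones(len(B))
        return np.column_stack([const, B @ self.t_null_f, B @ self.t_range_f])

    def _icv_ref(self, ages):
        """Cohort mean ICV-versus-age curve (penalized-spline smooth)."""
        return self._icv_design(ages) @ self.icv_ref_coef

    def _icv_ref_deriv(self, ages):
        return self._icv_design(ages, deriv=True) @ self.icv_ref_coef

    def _g_value(self, stratum: str) -> float:
        if not self.with_sex:
            if stratum not in ("pooled", None):
                raise ValueError(
                    "model was fitted without a sex term; use stratum='pooled'"
                )
            return 0.0
        return {"male": 1.0, "female": 0.0, "pooled": self.p_male}[stratum]

    def design(self, ages, stratum="pooled", deriv=False) -> np.ndarray:
        """Population-level design rows (or their d/dt) at ``ages`` (days)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        n = ages.size
        g = self._g_value(stratum)
        cols = []
        z = np.zeros(n)
        cols.append(z if deriv else np.ones(n))                    # intercept
        for j in range(1, len(self.site_levels)):                  # sites
            w = self.site_freqs[j]
            cols.append(z if deriv else np.full(n, w))
        if self.include_icv:
            cols.append(
                self._icv_ref_deriv(ages)
                if deriv
                else self._icv_ref(ages) - self.icv_mean
            )
        if self.with_sex:
            cols.append(z if deriv else np.full(n, g))             # sex main
        Bf = (
            self.basis_f.derivative(ages)
            if deriv
            else self.basis_f.evaluate(ages)
        )
        cols.append(Bf @ self.t_null_f)
        if self.with_sex:
            Bd = (
                self.basis_sex.derivative(ages)
                if deriv
                else self.basis_sex.evaluate(ages)
            )
            cols.append(g * (Bd @ self.t_null_sex))
        cols.append(Bf @ self.t_range_f)
        if self.with_sex:
            cols.append(g * (Bd @ self.t_range_sex))
        return np.column_stack(cols)

    def _curve(self, ages, stratum, deriv=False, scale=1.0) -> FittedCurve:
        C = self.design(ages, stratum, deriv=deriv) * scale
        est = C @ self.fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, self.fit.cov_beta, C))
        return FittedCurve(
            ages=np.atleast_1d(np.asarray(ages, dtype=float)),
            estimate=est,
            lower=est - _Z95 * se,
            upper=est + _Z95 * se,
            stratum=stratum if self.with_sex else "pooled",
            response=self.response,
            units=self.units,
        )

    def fitted_values(self, include_random: bool = True) -> np.ndarray:
        """Fitted values at the observed design points."""
        if self.engine is None:
            raise ValueError("model was deserialized; refit for fitted values")
        yhat = self.engine.W @ self.fit.beta
        if include_random and self.fit.alpha is not None:
            yhat = yhat + self.fit.alpha[self.engine.subject_index()]
        return yhat

    def to_dict(self) -> dict:
        """JSON-serializable form (prediction-capable; no bootstrap state)."""
        d = {
            "response": self.response,
            "with_sex": self.with_sex,
            "beta": self.fit.beta.tolist(),
            "cov_beta": self.fit.cov_beta.tolist(),
            "lambdas": self.fit.lambdas.tolist(),
            "ratio": self.fit.ratio if np.isfinite(self.fit.ratio) else None,
            "sigma2": self.fit.sigma2,
            "sigma2_subject": self.fit.sigma2_subject,
            "loglik": self.fit.loglik,
            "edf": self.fit.edf,
            "method": self.fit.method,
            "n_obs": self.fit.n_obs,
            "knots_f": self.basis_f.knots.tolist(),
            "k_f": self.basis_f.k,
            "t_null_f": self.t_null_f.tolist(),
            "t_range_f": self.t_range_f.tolist(),
            "site_levels": list(self.site_levels),
            "site_freqs": self.site_freqs.tolist(),
            "p_male": self.p_male,
            "include_icv": self.include_icv,
            "icv_mean": self.icv_mean,
            "icv_ref_coef": (
                self.icv_ref_coef.tolist() if self.include_icv else None
            ),
            "span": list(self.span),
            "units": self.units,
        }
        if self.with_sex:
            d["knots_sex"] = self.basis_sex.knots.tolist()
            d["k_sex"] = self.basis_sex.k
            d["t_null_sex"] = self.t_null_sex.tolist()
            d["t_range_sex"] = self.t_range_sex.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModel":
        fit = LMMFit(
            beta=np.asarray(d["beta"]),
            lambdas=np.asarray(d["lambdas"]),
            ratio=np.inf if d["ratio"] is None else float(d["ratio"]),
            sigma2=d["sigma2"],
            sigma2_subject=d["sigma2_subject"],
            loglik=d["loglik"],
            cov_beta=np.asarray(d["cov_beta"]),
            alpha=None,
            edf=d["edf"],
            converged=True,
            method=d["method"],
            n_obs=d["n_obs"],
        )
        with_sex = d["with_sex"]
        basis_sex = t_null_sex = t_range_sex = None
        if with_sex:
            basis_sex = SplineBasis(np.asarray(d["knots_sex"]), d["k_sex"])
            t_null_sex = np.asarray(d["t_null_sex"])
            t_range_sex = np.asarray(d["t_range_sex"])
        return cls(
            response=d["response"],
            with_sex=with_sex,
            fit=fit,
            basis_f=SplineBasis(np.asarray(d["knots_f"]), d["k_f"]),
            t_null_f=np.asarray(d["t_null_f"]),
            t_range_f=np.asarray(d["t_range_f"]),
            basis_sex=basis_sex,
            t_null_sex=t_null_sex,
            t_range_sex=t_range_sex,
            site_levels=list(d["site_levels"]),
            site_freqs=np.asarray(d["site_freqs"]),
            p_male=d["p_male"],
            include_icv=d["include_icv"],
            icv_mean=d["icv_mean"],
            icv_ref_coef=(
                np.asarray(d["icv_ref_coef"]) if d["include_icv"] else None
            ),
            span=tuple(d["span"]),
            units=d.get("units", "mm^3"),
        )


def _parse_response(records: pd.DataFrame, response) -> tuple[str, np.ndarray]:
    if isinstance(response, (tuple, list)):
        response = volume_column(*response)
    if response in records.columns:
        return response, records[response].to_numpy(dtype=float)
    col = f"vol_{response}"
    if col in records.columns:
        return col, records[col].to_numpy(dtype=float)
    raise KeyError(f"response column {response!r} not found in records")


def fit_gamm(
    records: pd.DataFrame,
    response,
    with_sex: bool = True,
    k: int = 10,
    k_sex: int = 5,
    reml: bool = False,
    include_icv: bool = True,
    include_site: bool = True,
    span: tuple[float, float] | None = None,
    fixed_lambdas=None,
    fixed_ratio=None,
) -> TrajectoryModel:
    """Fit a growth-trajectory GAMM to one response column.

    Parameters
    ----------
    records : one row per scan; needs subject_id, age_days, sex, site, icv
        and the response column (``vol_<structure>_<hemi>`` or explicit).
    response : column name, "structure_H" shorthand, or (structure, hemi).
    with_sex : include the sex main effect and sex-specific smooth.
    k, k_sex : basis dimensions of the age smooth and the sex smooth.
    reml : use REML instead of ML for smoothness/variance selection.
    span : age span (days) for the spline bases; defaults to the observed
        range.  Pass (0, 810) to anchor curves at term birth.
    fixed_lambdas, fixed_ratio : pin smoothing parameters / the noise-to-
        intercept variance ratio instead of optimizing (limit checks,
        bootstrap refits).
    """
    name, y = _parse_response(records, response)
    t = records["age_days"].to_numpy(dtype=float)
    subjects = records["subject_id"].to_numpy()

    if len(records) < 20:
        warnings.warn(
            f"only {len(records)} scans; growth-model fits are unreliable "
            "below ~20 observations",
            stacklevel=2,
        )
    n_repeat = (records.groupby("subject_id").size() >= 2).sum()
    if n_repeat < 2:
        warnings.warn(
            "fewer than 2 subjects with repeated scans; the subject "
            "random-intercept variance is weakly identified",
            stacklevel=2,
        )

    if span is not None:
        lo, hi = span
        if t.min() < lo or t.max() > hi:
            raise ValueError("span does not cover the observed ages")
        basis_ages = np.concatenate([[lo], t, [hi]])
    else:
        basis_ages = t
    basis_f = _basis_over_span(basis_ages, k)
    t_null_f, t_range_f = _smooth_transform(basis_f, t)
    Bf = basis_f.evaluate(t)

    cols = [np.ones(len(t))]
    site_levels, site_freqs = ["(none)"], np.array([1.0])
    if include_site:
        site_levels, inv = np.unique(records["site"], return_inverse=True)
        site_levels = list(site_levels)
        counts = np.bincount(inv, minlength=len(site_levels))
        site_freqs = counts / counts.sum()
        if len(site_levels) < 2:
            log.info("single site %r: site effect dropped", site_levels[0])
        for j in range(1, len(site_levels)):
            cols.append((inv == j).astype(float))
    icv_mean = 0.0
    icv_ref_coef = None
    icv_engine = icv_rstats = icv_lambdas = icv_ratio = None
    if include_icv:
        icv = records["icv"].to_numpy(dtype=float)
        icv_mean = float(icv.mean())
        cols.append(icv - icv_mean)
        icv_ref_coef, icv_engine, icv_rstats, icv_lambdas, icv_ratio = (
            _fit_icv_reference(icv, Bf, t_null_f, t_range_f, subjects)
        )
    g = None
    basis_sex = t_null_sex = t_range_sex = None
    p_male = 0.5
    if with_sex:
        g = (records["sex"].to_numpy() == "male").astype(float)
        p_male = float(g.mean())
        cols.append(g)
    cols.append(Bf @ t_null_f)
    if with_sex:
        basis_sex = _basis_over_span(basis_ages, k_sex)
        t_null_sex, t_range_sex = _smooth_transform(basis_sex, t)
        Bd = basis_sex.evaluate(t)
        cols.append(g[:, None] * (Bd @ t_null_sex))
    X = np.column_stack(cols)

    blocks = [Bf @ t_range_f]
    if with_sex:
        blocks.append(g[:, None] * (Bd @ t_range_sex))

    engine = PenalizedLMM(X, blocks, subject_ids=subjects)
    fit = engine.fit(
        y, reml=reml, fixed_lambdas=fixed_lambdas, fixed_ratio=fixed_ratio
    )
    rstats = engine.response_stats(y)

    subj_tab = (
        records.groupby("subject_id")
        .agg(site=("site", "first"), sex=("sex", "first"),
             n_scans=("age_days", "size"))
        .reset_index()
    )

    return TrajectoryModel(
        response=name,
        with_sex=with_sex,
        fit=fit,
        basis_f=basis_f,
        t_null_f=t_null_f,
        t_range_f=t_range_f,
        basis_sex=basis_sex,
        t_null_sex=t_null_sex,
        t_range_sex=t_range_sex,
        site_levels=site_levels,
        site_freqs=site_freqs,
        p_male=p_male,
        include_icv=include_icv,
        icv_mean=icv_mean,
        icv_ref_coef=icv_ref_coef,
        span=basis_f.span,
        engine=engine,
        rstats=rstats,
        subject_table=subj_tab,
        icv_engine=icv_engine,
        icv_rstats=icv_rstats,
        icv_lambdas=icv_lambdas,
        icv_ratio=icv_ratio,
    )


def _basis_over_span(ages, k):
    return build_spline_basis(ages, k=k)


_ICV_RIDGE = 1e-4  # numerical regularization only: no smoothing selection


def _fit_icv_reference(icv, Bf, t_null_f, t_range_f, subject_ids=None):
    """Cohort mean ICV-versus-age curve (subject random intercepts).

    Uses the model's own spline basis essentially unpenalized (a tiny fixed
    ridge for conditioning): the ICV trend is strong, so the basis is well
    identified, and avoiding smoothing selection keeps the reference free
    of shrinkage bias and makes its subject bootstrap exact at fixed
    penalty.  The fitted engine and sufficient statistics are returned so a
    bootstrap can resample the reference curve with the model coefficients.
    """
    X = np.column_stack([np.ones(len(Bf)), Bf @ t_null_f])
    eng = PenalizedLMM(X, [Bf @ t_range_f], subject_ids=subject_ids)
    y = np.asarray(icv, dtype=float)
    fit = eng.fit(y, fixed_lambdas=[_ICV_RIDGE])
    return fit.beta, eng, eng.response_stats(y), fit.lambdas, fit.ratio


# --------------------------------------------------------------------------- #
# curve extraction
# --------------------------------------------------------------------------- #

def predict_curve(model: TrajectoryModel, grid, stratum="pooled") -> FittedCurve:
    """Population-level fitted curve with a 95% pointwise band.

    Prediction is at the site-frequency-weighted reference and the cohort
    mean ICV trajectory; extrapolation beyond the fitted span raises.
    """
    return model._curve(grid, stratum)


def derivative_curve(
    model: TrajectoryModel, grid, stratum="pooled"
) -> FittedCurve:
    """Analytic first derivative of the fitted curve, per month."""
    curve = model._curve(grid, stratum, deriv=True, scale=DAYS_PER_MONTH)
    curve.units = f"{model.units}/month"
    return curve


def normalized_curve(
    model: TrajectoryModel, grid, stratum="pooled"
) -> FittedCurve:
    """Fitted curve normalized to the prediction at term birth, Y(t)/Y(0)."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    C = model.design(grid, stratum)
    c0 = model.design(np.array([0.0]), stratum)[0]
    y0 = float(c0 @ model.fit.beta)
    if y0 <= 0:
        raise ValueError(f"prediction at t=0 is nonpositive ({y0:g})")
    y = C @ model.fit.beta
    ratio = y / y0
    # delta method for the band of Y(t)/Y(0)
    grad = C / y0 - np.outer(ratio / y0, c0)
    var = np.einsum("ij,jk,ik->i", grad, model.fit.cov_beta, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    return FittedCurve(
        ages=grid,
        estimate=ratio,
        lower=ratio - _Z95 * se,
        upper=ratio + _Z95 * se,
        stratum=stratum if model.with_sex else "pooled",
        response=model.response,
        units="ratio to birth",
    )
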