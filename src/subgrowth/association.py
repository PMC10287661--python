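"""Mixed-model associations between morphometry and behavioral scores.

Each association fits a random-intercept linear mixed model

    score ~ age + sex + site + income + edu + ICV + predictor + (1 | subject)

where the predictor is either a structure's log volume-to-ICV ratio or a
vertex's local surface area.  Covariates and the predictor are standardized
to zero mean and unit variance before the fit, so the reported coefficient
is standardized.  Significance uses Satterthwaite's approximate-d.f. t-test;
families of tests are corrected with Benjamini-Hochberg FDR.  Nested models
are compared with a Wald F-test on the added predictors (ML fits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._engine import PenalizedLMM
from .cohort import MULLEN_SCORES, STRUCTURES, volume_column

log = logging.getLogger(__name__)

__all__ = [
    "AssociationSpec",
    "AssociationResult",
    "log_volume_ratio",
    "fit_association_lmm",
    "fdr_adjust",
    "compare_models",
    "vertex_association",
    "association_table",
    "join_scores",
]

DEFAULT_COVARIATES = (
    "age_days", "sex", "site", "income", "maternal_education", "icv",
)
_RATIO_BOUND = np.exp(26.0)  # treat the variance ratio at bound as no intercept


@dataclass
class AssociationSpec:
    """One association test: a score, a predictor, and nuisance covariates."""

    score: str                                  # e.g. "RL" or "mullen_RL"
    predictor: str                              # structure name or column
    covariates: tuple = DEFAULT_COVARIATES
    random_intercept: bool = True
    reml: bool = True

    @property
    def score_column(self) -> str:
        s = self.score
        return s if s.startswith("mullen_") else f"mullen_{s}"


@dataclass
class AssociationResult:
    beta: float            # standardized coefficient of the predictor
    se: float
    t: float
    df: float              # Satterthwaite degrees of freedom
    p: float
    score: str
    predictor: str
    n_obs: int
    q_value: float | None = None
    sigma2: float = np.nan
    sigma2_subject: float = np.nan
    extra: dict = field(default_factory=dict)


def log_volume_ratio(volume, icv):
    """log(volume / ICV); both inputs must be positive."""
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(volume <= 0) or np.any(icv <= 0):
        raise ValueError("volume and icv must be positive")
    return np.log(volume / icv)


def _standardize(x, name):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"covariate {name!r} is constant; cannot standardize")
    return (x - x.mean()) / sd


def _encode(records: pd.DataFrame, name: str) -> np.ndarray:
    col = records[name]
    if name == "sex":
        return (col.to_numpy() == "male").astype(float)
    if col.dtype == object or str(col.dtype) == "category":
        levels = np.unique(col)
        if levels.size != 2:
            raise ValueError(
                f"covariate {name!r} has {levels.size} levels; only binary "
                "categorical covariates are supported"
            )
        return (col.to_numpy() == levels[1]).astype(float)
    return col.to_numpy(dtype=float)


def _structure_ratio(records: pd.DataFrame, structure: str) -> np.ndarray:
    cols = [volume_column(structure, h) for h in ("L", "R")]
    vol = records[cols].sum(axis=1).to_numpy()
    return log_volume_ratio(vol, records["icv"].to_numpy())


def _design(records, spec, predictor_values=None):
    """(y, X, column names, subject ids) with standardized covariates."""
    score_col = spec.score_column
    if score_col not in records.columns:
        raise KeyError(f"score column {score_col!r} not found")
    ok = records[score_col].notna().to_numpy()
    rec = records.loc[ok]
    y = rec[score_col].to_numpy(dtype=float)
    if len(y) < 30:
        log.warning("only %d score observations; association is fragile", len(y))
    cols, names = [np.ones(len(y))], ["intercept"]
    for cov in spec.covariates:
        cols.append(_standardize(_encode(rec, cov), cov))
        names.append(cov)
    if predictor_values is not None:
        pred = np.asarray(predictor_values, dtype=float)[ok]
    elif spec.predictor in rec.columns:
        pred = rec[spec.predictor].to_numpy(dtype=float)
    elif spec.predictor in STRUCTURES:
        pred = _structure_ratio(rec, spec.predictor)
    else:
        raise KeyError(f"unknown predictor {spec.predictor!r}")
    cols.append(_standardize(pred, spec.predictor))
    names.append(spec.predictor)
    X = np.column_stack(cols)
    return y, X, names, rec["subject_id"].to_numpy()


# --------------------------------------------------------------------------- #
# Satterthwaite machinery
# --------------------------------------------------------------------------- #

def _reml_neg2ll_and_var(engine, rstats, j):
    """Closures: -2 REML loglik and Var(beta_j), both over (log s2, log s2a)."""
    n = engine.n
    p = engine.q
    hs, ts, yys = rstats

    def parts(log_s2, log_s2a):
        s2, s2a = np.exp(log_s2), np.exp(log_s2a)
        ratio = s2 / s2a
        beta, pls, n_eff, M, cho = engine.solve(
            np.empty(0), ratio, rstats
        )
        logdet_subj = float(np.log(engine.ns + ratio).sum())
        logdet_A = 2.0 * float(np.log(np.diag(cho[0])).sum())
        neg2 = (
            (n_eff - p) * log_s2
            + logdet_subj + logdet_A
            - engine.S * np.log(ratio)
            + pls / s2
            + (n_eff - p) * np.log(2 * np.pi)
        )
        from scipy import linalg

        cov = s2 * linalg.cho_solve(cho, np.eye(p))
        return float(neg2), float(cov[j, j])

    return parts


def _satterthwaite_df(engine, rstats, fit, j):
    """Approximate d.f. for the j-th coefficient's t-test.

    df = 2 phi^2 / (grad' I^{-1} grad) with phi = Var(beta_j) as a function
    of the variance components and I the observed REML information, both
    evaluated numerically on the log-variance scale.
    """
    theta = np.log([fit.sigma2, max(fit.sigma2_subject, 1e-12)])
    parts = _reml_neg2ll_and_var(engine, rstats, j)
    h = 1e-4

    def phi(th):
        return parts(th[0], th[1])[1]

    def nll(th):
        return parts(th[0], th[1])[0]

    grad = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        grad[i] = (phi(theta + e) - phi(theta - e)) / (2 * h)
    # observed information = 0.5 * Hessian of -2 loglik
    H = np.zeros((2, 2))
    for i in range(2):
        for k in range(i, 2):
            ei, ek = np.zeros(2), np.zeros(2)
            ei[i] = h
            ek[k] = h
            H[i, k] = H[k, i] = (
                nll(theta + ei + ek) - nll(theta + ei - ek)
                - nll(theta - ei + ek) + nll(theta - ei - ek)
            ) / (4 * h * h)
    info = 0.5 * H
    try:
        vtheta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(engine.n - engine.q)
    phi0 = phi(theta)
    denom = float(grad @ vtheta @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(engine.n - engine.q)
    df = 2.0 * phi0**2 / denom
    return float(np.clip(df, 1e-8, engine.n - engine.q))


def fit_association_lmm(
    records: pd.DataFrame,
    spec: AssociationSpec,
    predictor_values=None,
) -> AssociationResult:
    """Random-intercept LMM association with a Satterthwaite t-test.

    With a singular (boundary) random-intercept variance the model reduces
    to OLS and the d.f. falls back to n - p.
    """
    y, X, names, subjects = _design(records, spec, predictor_values)
    j = len(names) - 1
    n, p = X.shape

    if spec.random_intercept:
        engine = PenalizedLMM(X, (), subject_ids=subjects)
        fit = engine.fit(y, reml=spec.reml)
        rstats = engine.response_stats(y)
        boundary = (
            fit.ratio > _RATIO_BOUND
            or fit.sigma2_subject < 1e-10 * fit.sigma2
        )
        if boundary:
            log.warning(
                "random-intercept variance at boundary; falling back to "
                "OLS with df = n - p"
            )
    else:
        boundary = True
        engine = fit = rstats = None

    if boundary:
        engine = PenalizedLMM(X, (), subject_ids=None)
        fit = engine.fit(y, reml=spec.reml, fixed_ratio=np.inf)
        df = float(n - p)
    else:
        df = _satterthwaite_df(engine, rstats, fit, j)

    beta = float(fit.beta[j])
    se = float(np.sqrt(fit.cov_beta[j, j]))
    t = beta / se
    pval = 2.0 * stats.t.sf(abs(t), df=df)
    return AssociationResult(
        beta=beta,
        se=se,
        t=t,
        df=df,
        p=float(pval),
        score=spec.score,
        predictor=spec.predictor,
        n_obs=n,
        sigma2=fit.sigma2,
        sigma2_subject=fit.sigma2_subject,
    )


# --------------------------------------------------------------------------- #
# multiple testing and model comparison
# --------------------------------------------------------------------------- #

def fdr_adjust(pvalues, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, within groups if given."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if groups is None:
        q[:] = multipletests(p, method="fdr_bh")[1]
        return q
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


def compare_models(
    records: pd.DataFrame,
    score: str,
    added_predictors,
    covariates=DEFAULT_COVARIATES,
    random_intercept: bool = True,
) -> tuple[float, float]:
    """Wald F-test of the added predictors against the covariates-only null.

    Both models share the covariates (nested by construction); the full
    model adds the log volume ratios of ``added_predictors``.  Fits use ML
    for comparability.  Returns (F, p).
    """
    added = list(added_predictors)
    if len(added) == 0:
        return 0.0, 1.0
    spec = AssociationSpec(score=score, predictor=added[0],
                           covariates=tuple(covariates),
                           random_intercept=random_intercept, reml=False)
    score_col = spec.score_column
    ok = records[score_col].notna().to_numpy()
    rec = records.loc[ok]
    y = rec[score_col].to_numpy(dtype=float)
    cols, names = [np.ones(len(y))], ["intercept"]
    for cov in covariates:
        cols.append(_standardize(_encode(rec, cov), cov))
        names.append(cov)
    for pred in added:
        vals = (
            _structure_ratio(rec, pred)
            if pred in STRUCTURES
            else rec[pred].to_numpy(dtype=float)
        )
        cols.append(_standardize(vals, pred))
        names.append(pred)
    X = np.column_stack(cols)
    n, p = X.shape
    qn = len(added)

    engine = PenalizedLMM(
        X, (), subject_ids=rec["subject_id"].to_numpy()
        if random_intercept else None,
    )
    fit = engine.fit(y, reml=False)
    idx = np.arange(p - qn, p)
    b = fit.beta[idx]
    Vb = fit.cov_beta[np.ix_(idx, idx)]
    F = float(b @ np.linalg.solve(Vb, b)) / qn
    pF = float(stats.f.sf(F, qn, n - p))
    return F, pF


def association_table(
    records: pd.DataFrame,
    structures=STRUCTURES,
    scores=MULLEN_SCORES,
    covariates=DEFAULT_COVARIATES,
    fdr_within: str = "score",
) -> pd.DataFrame:
    """All structure x score associations with BH-FDR q-values.

    ``fdr_within="score"`` corrects across structures within each score
    (6 tests per family); ``"all"`` pools every cell into one family.
    """
    rows = []
    for score in scores:
        for s in structures:
            res = fit_association_lmm(
                records,
                AssociationSpec(score=score, predictor=s,
                                covariates=tuple(covariates)),
            )
            rows.append(
                {
                    "score": score,
                    "structure": s,
                    "beta": res.beta,
                    "se": res.se,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "n_obs": res.n_obs,
                }
            )
    tab = pd.DataFrame(rows)
    groups = tab["score"].to_numpy() if fdr_within == "score" else None
    tab["q_value"] = fdr_adjust(tab["p"].to_numpy(), groups)
    tab["significant"] = tab["q_value"] < 0.05
    return tab


# --------------------------------------------------------------------------- #
# vertex-wise association
# --------------------------------------------------------------------------- #

def join_scores(
    records: pd.DataFrame,
    score_visits: pd.DataFrame,
    window_days: float = 45.0,
) -> pd.DataFrame:
    """Attach behavioral visits to scans by nearest age within a window.

    ``score_visits`` has subject_id, age_days and mullen_* columns; scans
    with no visit inside ``window_days`` get missing scores (logged).
    """
    out = records.copy()
    score_cols = [c for c in score_visits.columns if c.startswith("mullen_")]
    for c in score_cols:
        out[c] = np.nan
    n_dropped = 0
    for sid, grp in out.groupby("subject_id"):
        visits = score_visits[score_visits["subject_id"] == sid]
        if visits.empty:
            n_dropped += len(grp)
            continue
        vages = visits["age_days"].to_numpy(dtype=float)
        for i in grp.index:
            gaps = np.abs(vages - float(out.at[i, "age_days"]))
            k = int(np.argmin(gaps))
            if gaps[k] <= window_days:
                for c in score_cols:
                    out.at[i, c] = visits.iloc[k][c]
            else:
                n_dropped += 1
    if n_dropped:
        log.info(
            "%d scans had no behavioral visit within %g days", n_dropped,
            window_days,
        )
    return out


def vertex_association(
    records: pd.DataFrame,
    vertex_areas: np.ndarray,
    spec: AssociationSpec,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-vertex association between local area and a score.

    ``vertex_areas`` is (n_scans, V) aligned with ``records`` rows.  Each
    vertex's local area is the standardized predictor in the same mixed
    model; BH-FDR is applied across the structure's vertices.
    """
    vertex_areas = np.asarray(vertex_areas, dtype=float)
    if vertex_areas.shape[0] != len(records):
        raise ValueError("vertex_areas rows must align with records")
    V = vertex_areas.shape[1]
    rows = []
    for v in range(V):
        res = fit_association_lmm(
            records, spec, predictor_values=vertex_areas[:, v]
        )
        rows.append(
            {"vertex": v, "beta": res.beta, "t": res.t, "df": res.df,
             "p": res.p}
        )
    tab = pd.DataFrame(rows)
    tab["q_value"] = fdr_adjust(tab["p"].to_numpy())
    tab["significant"] = tab["q_value"] < alpha
    return tab
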