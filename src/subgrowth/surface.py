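"""Vertex-wise surface-area expansion on corresponded meshes.

Given per-scan triangle meshes with vertex-to-vertex correspondence, this
module computes local vertex areas (one third of each incident triangle),
fits a growth trajectory per vertex (the no-sex model: site + ICV + spline
of age + subject intercept), evaluates monthly relative expansion-rate maps
(dA/dt)/A, and detects high-/low-growth regions: the top and bottom 20% of
vertices by rate whose rates differ significantly from the cross-vertex
median (t-statistic against the bootstrap SD of the vertex rate, d.f. B-1,
Benjamini-Hochberg FDR across the tested vertices at each month).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._engine import PenalizedLMM
from .cohort import DAYS_PER_MONTH
from .gamm import _fit_icv_reference, _smooth_transform
from .splines import SplineBasis, build_spline_basis

log = logging.getLogger(__name__)

__all__ = [
    "CorrespondedMeshSeries",
    "vertex_local_area",
    "VertexTrajectories",
    "fit_vertex_trajectories",
    "expansion_rate_map",
    "bootstrap_rate_maps",
    "detect_growth_regions",
    "MONTH_GRID",
]

#: monthly evaluation grid for expansion maps (30-day months)
MONTH_GRID = np.arange(0, 25)


@dataclass
class CorrespondedMeshSeries:
    """Per-scan meshes sharing one triangulation (vertex k corresponds)."""

    faces: np.ndarray      # (F, 3) int
    vertices: np.ndarray   # (n_scans, V, 3) float, mm
    meta: pd.DataFrame     # one row per scan: subject_id, age_days, ...

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=int)
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must have shape (n_scans, V, 3)")
        if len(self.meta) != self.n_scans:
            raise ValueError("meta must have one row per scan")

    @property
    def n_scans(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    def validate(self) -> None:
        """Closed-2-manifold checks: Euler characteristic 2, every edge
        shared by exactly two triangles, no degenerate triangles."""
        V, F = self.n_vertices, len(self.faces)
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            bad = uniq[counts != 2][:3]
            raise ValueError(f"non-manifold edges (e.g. {bad.tolist()})")
        if V - len(uniq) + F != 2:
            raise ValueError(
                f"Euler characteristic {V - len(uniq) + F} != 2; "
                "mesh is not a closed sphere-topology surface"
            )
        areas = _triangle_areas(self.vertices, self.faces)
        if np.any(areas <= 0):
            scan, tri = np.argwhere(areas <= 0)[0]
            raise ValueError(
                f"degenerate triangle {tri} in scan {scan} (zero area)"
            )

    def vertex_areas(self) -> np.ndarray:
        """Local vertex areas for every scan, shape (n_scans, V), mm^2."""
        return _vertex_areas_all(self.vertices, self.faces)


def _triangle_areas(vertices, faces):
    tri = vertices[..., faces, :]  # (..., F, 3, 3)
    cross = np.cross(
        tri[..., 1, :] - tri[..., 0, :], tri[..., 2, :] - tri[..., 0, :]
    )
    return 0.5 * np.linalg.norm(cross, axis=-1)


def _vertex_areas_all(vertices, faces):
    single = vertices.ndim == 2
    verts = vertices[None] if single else vertices
    tri_areas = _triangle_areas(verts, faces) / 3.0  # (n, F)
    n, V = verts.shape[0], verts.shape[1]
    out = np.zeros((n, V))
    for j in range(3):
        np.add.at(out, (slice(None), faces[:, j]), tri_areas)
    return out[0] if single else out


def vertex_local_area(vertices, faces=None) -> np.ndarray:
    """Local surface area per vertex: one third of each incident triangle.

    Accepts a trimesh.Trimesh or (vertices, faces) arrays.  The vertex areas
    sum exactly to the total mesh surface area (barycentric allocation).
    """
    if faces is None:  # trimesh-like object
        faces = np.asarray(vertices.faces)
        vertices = np.asarray(vertices.vertices, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    areas3 = _triangle_areas(vertices, faces)
    bad = np.flatnonzero(areas3 <= 0)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) triangle index {bad[0]}")
    return _vertex_areas_all(vertices, faces)


# --------------------------------------------------------------------------- #
# per-vertex trajectories
# --------------------------------------------------------------------------- #

@dataclass
class VertexTrajectories:
    """Per-vertex growth-trajectory fits sharing one design."""

    engine: PenalizedLMM
    betas: np.ndarray        # (q, V)
    lambdas: np.ndarray      # (V,)
    ratios: np.ndarray       # (V,)
    mask: np.ndarray         # (V,) True where the vertex fit converged
    basis: SplineBasis
    t_null: np.ndarray
    t_range: np.ndarray
    site_levels: list
    site_freqs: np.ndarray
    include_icv: bool
    icv_mean: float
    icv_ref_coef: np.ndarray | None
    subject_table: pd.DataFrame
    rstats: tuple = field(repr=False, default=None)
    icv_engine: PenalizedLMM | None = field(repr=False, default=None)
    icv_rstats: tuple | None = field(repr=False, default=None)
    icv_lambdas: np.ndarray | None = field(repr=False, default=None)
    icv_ratio: float | None = field(repr=False, default=None)

    @property
    def n_vertices(self) -> int:
        return self.betas.shape[1]

    @property
    def icv_col(self) -> int | None:
        if not self.include_icv:
            return None
        return 1 + max(len(self.site_levels) - 1, 0)

    def icv_design(self, ages, deriv=False) -> np.ndarray:
        """Design rows of the ICV reference smooth: [const, null, range]."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        B = self.basis.derivative(ages) if deriv else self.basis.evaluate(ages)
        const = np.zeros(ages.size) if deriv else np.ones(ages.size)
        return np.column_stack([const, B @ self.t_null, B @ self.t_range])

    def design(self, ages, deriv=False) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        n = ages.size
        z = np.zeros(n)
        cols = [z if deriv else np.ones(n)]
        for j in range(1, len(self.site_levels)):
            cols.append(z if deriv else np.full(n, self.site_freqs[j]))
        if self.include_icv:
            ref = self.icv_design(ages, deriv) @ self.icv_ref_coef
            cols.append(ref if deriv else ref - self.icv_mean)
        B = self.basis.derivative(ages) if deriv else self.basis.evaluate(ages)
        cols.append(B @ self.t_null)
        cols.append(B @ self.t_range)
        return np.column_stack(cols)

    def area_curves(self, ages) -> np.ndarray:
        """Fitted population area trajectories, shape (len(ages), V)."""
        return self.design(ages) @ self.betas

    def rate_map(self, month: float) -> np.ndarray:
        """Relative expansion rate (fraction/month) per vertex at ``month``."""
        day = float(month) * DAYS_PER_MONTH
        a = (self.design([day]) @ self.betas)[0]
        da = (self.design([day], deriv=True) @ self.betas)[0] * DAYS_PER_MONTH
        out = np.full(self.n_vertices, np.nan)
        ok = self.mask & (a > 0)
        out[ok] = da[ok] / a[ok]
        return out


def fit_vertex_trajectories(
    series: CorrespondedMeshSeries,
    k: int = 8,
    include_icv: bool = True,
    include_site: bool = True,
    span=None,
) -> VertexTrajectories:
    """Fit the no-sex growth model to every vertex's local-area series.

    All vertices share the basis, knots and design; smoothing parameter and
    variance ratio are selected per vertex by ML.  Vertices whose
    optimization fails are masked and excluded downstream.
    """
    if series.n_scans < 20:
        log.warning(
            "only %d scans; per-vertex fits are unreliable", series.n_scans
        )
    Y = series.vertex_areas()
    meta = series.meta
    t = meta["age_days"].to_numpy(dtype=float)

    if span is not None:
        basis_ages = np.concatenate([[span[0]], t, [span[1]]])
    else:
        basis_ages = t
    basis = build_spline_basis(basis_ages, k=k)
    t_null, t_range = _smooth_transform(basis, t)
    B = basis.evaluate(t)

    cols = [np.ones(len(t))]
    site_levels, site_freqs = ["(none)"], np.array([1.0])
    if include_site and "site" in meta.columns:
        site_levels, inv = np.unique(meta["site"], return_inverse=True)
        site_levels = list(site_levels)
        counts = np.bincount(inv, minlength=len(site_levels))
        site_freqs = counts / counts.sum()
        for j in range(1, len(site_levels)):
            cols.append((inv == j).astype(float))
    icv_mean = 0.0
    icv_ref_coef = None
    icv_engine = icv_rstats = icv_lambdas = icv_ratio = None
    use_icv = include_icv and "icv" in meta.columns
    if use_icv:
        icv = meta["icv"].to_numpy(dtype=float)
        icv_mean = float(icv.mean())
        cols.append(icv - icv_mean)
        icv_ref_coef, icv_engine, icv_rstats, icv_lambdas, icv_ratio = (
            _fit_icv_reference(
                icv, B, t_null, t_range, meta["subject_id"].to_numpy()
            )
        )
    cols.append(B @ t_null)
    X = np.column_stack(cols)

    engine = PenalizedLMM(
        X, [B @ t_range], subject_ids=meta["subject_id"].to_numpy()
    )
    rstats = engine.response_stats(Y)
    hs, ts, yys = rstats

    V = Y.shape[1]
    lambdas = np.empty(V)
    ratios = np.empty(V)
    mask = np.ones(V, dtype=bool)
    for v in range(V):
        rv = (hs[:, :, v], ts[:, v], yys[:, v])

        def obj(theta):
            try:
                return engine.neg2loglik(
                    np.exp(theta[:1]), float(np.exp(theta[1])), rv
                )
            except np.linalg.LinAlgError:
                return np.inf

        res = optimize.minimize(
            obj, np.array([2.0, 0.0]), method="L-BFGS-B",
            bounds=[(-12, 28), (-12, 28)],
            options={"ftol": 1e-9, "maxiter": 200},
        )
        if not np.isfinite(res.fun):
            mask[v] = False
            lambdas[v] = np.nan
            ratios[v] = np.nan
            log.warning("vertex %d: trajectory fit failed; masked", v)
            continue
        lambdas[v] = float(np.exp(res.x[0]))
        ratios[v] = float(np.exp(res.x[1]))

    betas = np.zeros((engine.q, V))
    for v in range(V):
        if not mask[v]:
            continue
        rv = (hs[:, :, v], ts[:, v], yys[:, v])
        beta, _, _, _, _ = engine.solve(lambdas[v], ratios[v], rv)
        betas[:, v] = beta

    subj_tab = (
        meta.groupby("subject_id")
        .agg(
            site=("site", "first") if "site" in meta.columns
            else ("age_days", "size"),
            n_scans=("age_days", "size"),
        )
        .reset_index()
    )
    if "site" not in meta.columns:
        subj_tab["site"] = "(none)"

    return VertexTrajectories(
        engine=engine,
        betas=betas,
        lambdas=lambdas,
        ratios=ratios,
        mask=mask,
        basis=basis,
        t_null=t_null,
        t_range=t_range,
        site_levels=site_levels,
        site_freqs=site_freqs,
        include_icv=use_icv,
        icv_mean=icv_mean,
        icv_ref_coef=icv_ref_coef,
        subject_table=subj_tab,
        rstats=rstats,
        icv_engine=icv_engine,
        icv_rstats=icv_rstats,
        icv_lambdas=icv_lambdas,
        icv_ratio=icv_ratio,
    )


def expansion_rate_map(vtraj: VertexTrajectories, month: float) -> np.ndarray:
    """Monthly relative expansion-rate map at ``month`` (fraction/month)."""
    lo, hi = vtraj.basis.span
    if not (lo <= month * DAYS_PER_MONTH <= hi):
        raise ValueError(f"month {month} outside fitted span")
    return vtraj.rate_map(month)


def bootstrap_rate_maps(
    vtraj: VertexTrajectories,
    months,
    B: int = 200,
    seed: int = 0,
    strata_by=None,
) -> np.ndarray:
    """Stratified subject-bootstrap replicate rate maps.

    Returns an array of shape (B, len(months), V).  Replicates reuse each
    vertex's smoothing parameter and variance ratio; the per-replicate
    refit is a batched weighted least-squares solve over all vertices.
    """
    from .growth import _strata_labels

    eng = vtraj.engine
    hs, ts, yys = vtraj.rstats
    subj_order = pd.DataFrame({"subject_id": eng.subjects}).merge(
        vtraj.subject_table, on="subject_id", how="left", sort=False
    )
    labels = _strata_labels(subj_order, strata_by)
    uniq = np.unique(labels)
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    rng = np.random.default_rng(seed)

    months = np.atleast_1d(np.asarray(months, dtype=float))
    days = months * DAYS_PER_MONTH
    C = vtraj.design(days)                      # (M, q)
    dC = vtraj.design(days, deriv=True) * DAYS_PER_MONTH
    icv_col = vtraj.icv_col
    if icv_col is not None:
        D_icv = vtraj.icv_design(days)
        D_icv_d = vtraj.icv_design(days, deriv=True) * DAYS_PER_MONTH

    V = vtraj.n_vertices
    q = eng.q
    pen = np.zeros((V, q))
    pen_cols = eng.group >= 0
    pen[:, pen_cols] = vtraj.lambdas[:, None]
    ratios = np.where(vtraj.mask, vtraj.ratios, 1.0)

    out = np.full((B, months.size, V), np.nan)
    Gs, gs, Os, ns = eng.Gs, eng.gs, eng.Os, eng.ns
    for b in range(B):
        w = np.zeros(eng.S)
        for u in uniq:
            idx = members[u]
            draws = rng.integers(0, idx.size, idx.size)
            w[idx] += np.bincount(draws, minlength=idx.size)
        cw = w[None, :] / (ns[None, :] + ratios[:, None])   # (V, S)
        M0 = np.tensordot(w, Gs, axes=1)                    # (q, q)
        A = M0[None] - np.einsum("vs,sij->vij", cw, Os)     # (V, q, q)
        A[:, np.arange(q), np.arange(q)] += pen
        rhs = (
            np.tensordot(w, hs, axes=1)                     # (q, V)
            - np.einsum("vs,sq,sv->qv", cw, gs, ts)
        )
        try:
            beta = np.linalg.solve(A, rhs.T[:, :, None])[:, :, 0]  # (V, q)
        except np.linalg.LinAlgError:
            log.warning("bootstrap replicate %d failed; dropped", b)
            continue
        a = beta @ C.T          # (V, M)
        da = beta @ dC.T
        if icv_col is not None:
            # the cohort mean-ICV curve is itself resampled
            icv_coef = vtraj.icv_engine.bootstrap_beta(
                vtraj.icv_lambdas, vtraj.icv_ratio, vtraj.icv_rstats, w
            )
            dcoef = icv_coef - vtraj.icv_ref_coef
            a = a + np.outer(beta[:, icv_col], D_icv @ dcoef)
            da = da + np.outer(beta[:, icv_col], D_icv_d @ dcoef)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(a > 0, da / a, np.nan)
        out[b] = rate.T
    out[:, :, ~vtraj.mask] = np.nan
    return out


# --------------------------------------------------------------------------- #
# high-/low-growth region detection
# --------------------------------------------------------------------------- #

def detect_growth_regions(
    rates: np.ndarray,
    replicate_rates: np.ndarray,
    q: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label high-/low-growth vertices at one month.

    Candidates are the top and bottom ``q`` fraction of vertices by point
    rate (ties broken by vertex index; exactly ceil(q V) each side when
    rates are distinct).  Each candidate's rate is tested against the
    cross-vertex median of point rates with a t-statistic using the
    bootstrap SD of that vertex's rate (d.f. = B - 1); two-sided p-values
    are Benjamini-Hochberg corrected across all tested vertices.

    Returns a per-vertex frame with columns rate, candidate, p, q_value,
    label in {"high", "low", "none"}.
    """
    rates = np.asarray(rates, dtype=float)
    replicate_rates = np.asarray(replicate_rates, dtype=float)
    V = rates.size
    valid = np.isfinite(rates)
    out = pd.DataFrame(
        {
            "vertex": np.arange(V),
            "rate": rates,
            "candidate": "none",
            "p": np.nan,
            "q_value": np.nan,
            "label": "none",
        }
    )
    vr = rates[valid]
    if vr.size == 0 or np.ptp(vr) == 0:
        return out  # all rates identical: no candidates
    med = float(np.median(vr))
    n_cand = int(np.ceil(q * vr.size))
    order = np.flatnonzero(valid)[np.argsort(vr, kind="stable")]
    bottom = order[:n_cand]
    top = order[-n_cand:]
    top = np.setdiff1d(top, bottom)  # no double counting on tiny meshes

    if replicate_rates.shape[0] < 2:
        raise ValueError("need >= 2 replicate rate maps")
    nrep = int(np.isfinite(replicate_rates).any(axis=1).sum())
    sd = np.nanstd(replicate_rates, axis=0, ddof=1)

    tested = np.concatenate([top, bottom])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (rates[tested] - med) / sd[tested]
    df = max(int(nrep) - 1, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    out.loc[tested, "p"] = pvals
    out.loc[tested, "q_value"] = qvals
    out.loc[top, "candidate"] = "high"
    out.loc[bottom, "candidate"] = "low"
    is_top = np.isin(tested, top)
    above = rates[tested] > med
    high_sig = tested[reject & is_top & above]
    low_sig = tested[reject & ~is_top & ~above]
    out.loc[high_sig, "label"] = "high"
    out.loc[low_sig, "label"] = "low"
    return out
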