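"""Penalized linear mixed-model engine.

Fits models of the form

    y = X beta + sum_g B_g gamma_g + Z alpha + e

where X is unpenalized, each block B_g carries an identity penalty scaled by
its own smoothing parameter lambda_g (the natural parametrization of a
penalized spline), Z is a subject-indicator matrix (random intercepts with
variance sigma_a^2) and e is iid Gaussian noise with variance sigma^2.

Smoothing parameters and the variance ratio r = sigma^2 / sigma_a^2 are
chosen by maximizing the exact Gaussian marginal likelihood (ML; REML
optional), with sigma^2 profiled out analytically.

Everything is computed from per-subject sufficient statistics
(W_s'W_s, W_s'1, W_s'y_s, 1'y_s, y_s'y_s), which makes

* a criterion evaluation O(S q^2) for q coefficients and S subjects,
* a subject-bootstrap refit a weighted re-sum of the same statistics, and
* multi-response (per-vertex) fits share one design-side reduction.

Derivation sketch: absorbing the random intercepts via the Schur complement
turns the penalized normal equations into a q x q system
A(r) b = rhs(r) with

    A(r)  = sum_s [G_s - g_s g_s' / (n_s + r)] + diag(penalty)
    rhs(r)= sum_s [h_s - g_s t_s / (n_s + r)]

and the profiled -2 log ML is

    n log(PLS/n) + log|Lambda + U'U| - log|Lambda| + n(1 + log 2 pi)

with PLS the minimized penalized sum of squares and U = [B, Z]; the
determinant reduces to sum_s log(n_s + r) + log|M_pp + Lambda_p| where M_pp
is the penalized block of A before adding the penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["PenalizedLMM", "LMMFit"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMFit:
    """Result of a penalized mixed-model fit."""

    beta: np.ndarray          # all q coefficients (X block first)
    lambdas: np.ndarray       # smoothing parameters, one per penalized block
    ratio: float              # r = sigma^2 / sigma_a^2 (inf if no intercept)
    sigma2: float             # residual variance
    sigma2_subject: float     # random-intercept variance
    loglik: float             # maximized log marginal likelihood
    cov_beta: np.ndarray      # q x q coefficient covariance (Bayesian/GLS)
    alpha: np.ndarray | None  # BLUPs of subject intercepts (point fit only)
    edf: float                # effective degrees of freedom of the mean part
    converged: bool
    method: str               # "ML" or "REML"
    n_obs: int

    @property
    def sd_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


class PenalizedLMM:
    """Design-side container for penalized mixed-model fits.

    Parameters
    ----------
    X : (n, p) unpenalized design columns (must include the intercept).
    blocks : list of (n, k_g) penalized column blocks; each block has an
        identity penalty with its own smoothing parameter.
    subject_ids : length-n labels, or None for no random intercept.
    """

    def __init__(self, X, blocks=(), subject_ids=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        parts = [X] + [np.asarray(b, dtype=float) for b in blocks]
        self.W = np.hstack(parts)
        self.n, self.q = self.W.shape
        self.p = X.shape[1]
        self.block_sizes = [b.shape[1] for b in blocks]
        self.n_groups = len(self.block_sizes)
        # column -> penalty-group map (-1 = unpenalized)
        grp = [-np.ones(self.p, dtype=int)]
        for g, k in enumerate(self.block_sizes):
            grp.append(np.full(k, g, dtype=int))
        self.group = np.concatenate(grp)
        self._pen_cols = self.group >= 0

        self.has_intercept_re = subject_ids is not None
        if self.has_intercept_re:
            subject_ids = np.asarray(subject_ids)
            if subject_ids.shape[0] != self.n:
                raise ValueError("subject_ids length must match design rows")
            self.subjects, inv = np.unique(subject_ids, return_inverse=True)
            self.S = self.subjects.size
            order = np.argsort(inv, kind="stable")
            self._order = order
            self._row_subject = inv
            bounds = np.searchsorted(inv[order], np.arange(self.S + 1))
            Wo = self.W[order]
            self.ns = np.diff(bounds).astype(float)
            self.Gs = np.empty((self.S, self.q, self.q))
            self.gs = np.empty((self.S, self.q))
            for s in range(self.S):
                Ws = Wo[bounds[s]:bounds[s + 1]]
                self.Gs[s] = Ws.T @ Ws
                self.gs[s] = Ws.sum(axis=0)
            self.Os = np.einsum("si,sj->sij", self.gs, self.gs)
            self._bounds = bounds
        else:
            self.S = 0

    # ------------------------------------------------------------------ #
    # response-side sufficient statistics
    # ------------------------------------------------------------------ #

    def response_stats(self, y):
        """Per-subject response statistics for y of shape (n,) or (n, V)."""
        y = np.asarray(y, dtype=float)
        if not self.has_intercept_re:
            return (self.W.T @ y, None, (y * y).sum(axis=0))
        yo = y[self._order]
        Wo = self.W[self._order]
        b = self._bounds
        V = y.shape[1] if y.ndim == 2 else None
        hs = np.empty((self.S, self.q) if V is None else (self.S, self.q, V))
        ts = np.empty((self.S,) if V is None else (self.S, V))
        yys = np.empty_like(ts)
        for s in range(self.S):
            ys = yo[b[s]:b[s + 1]]
            hs[s] = Wo[b[s]:b[s + 1]].T @ ys
            ts[s] = ys.sum(axis=0)
            yys[s] = (ys * ys).sum(axis=0)
        return hs, ts, yys

    # ------------------------------------------------------------------ #
    # core linear algebra
    # ------------------------------------------------------------------ #

    def _penalty_diag(self, lambdas):
        pen = np.zeros(self.q)
        for g, lam in enumerate(np.atleast_1d(lambdas)):
            pen[self.group == g] = lam
        return pen

    def _design_sums(self, ratio, weights=None):
        """A-matrix (without penalty), rhs-reduction coefs c_s, n and S."""
        if not self.has_intercept_re or np.isinf(ratio):
            M = self.W.T @ self.W
            return M, None, float(self.n), 0.0
        cs = 1.0 / (self.ns + ratio)
        if weights is None:
            M = self.Gs.sum(axis=0) - np.tensordot(cs, self.Os, axes=1)
            n_eff = self.ns.sum()
            s_eff = float(self.S)
        else:
            w = np.asarray(weights, dtype=float)
            M = np.tensordot(w, self.Gs, axes=1) - np.tensordot(
                w * cs, self.Os, axes=1
            )
            n_eff = float(w @ self.ns)
            s_eff = float(w.sum())
        return M, cs, n_eff, s_eff

    def solve(self, lambdas, ratio, rstats, weights=None):
        """Penalized GLS solve at fixed (lambdas, ratio).

        Returns (beta, pls, n_eff, M, cho) where M is the unpenalized
        A-matrix and cho the Cholesky factor of A = M + penalty.
        """
        hs, ts, yys = rstats
        M, cs, n_eff, _ = self._design_sums(ratio, weights)
        A = M + np.diag(self._penalty_diag(lambdas))
        if not self.has_intercept_re:
            rhs = hs
            yy_adj = yys
        elif np.isinf(ratio):
            rhs = hs.sum(axis=0)
            yy_adj = yys.sum(axis=0)
        elif weights is None:
            rhs = hs.sum(axis=0) - np.einsum(
                "s,sq,s...->q...", cs, self.gs, ts
            )
            yy_adj = yys.sum(axis=0) - cs @ (ts * ts)
        else:
            w = np.asarray(weights, dtype=float)
            rhs = np.tensordot(w, hs, axes=1) - np.einsum(
                "s,sq,s...->q...", w * cs, self.gs, ts
            )
            yy_adj = w @ yys - (w * cs) @ (ts * ts)
        cho = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cho, np.asarray(rhs))
        if beta.ndim == 1:
            pls = yy_adj - beta @ rhs
        else:
            pls = yy_adj - np.einsum("qv,qv->v", beta, rhs)
        return beta, pls, n_eff, M, cho

    def neg2loglik(self, lambdas, ratio, rstats, weights=None, reml=False):
        """Profiled -2 log (restricted) marginal likelihood."""
        lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
        _, pls, n_eff, M, cho = self.solve(lambdas, ratio, rstats, weights)
        pls = max(float(pls), 1e-300)

        # log|Lambda + U'U| (subjects absorbed) and -log|Lambda|
        logdet_subj = 0.0
        s_eff = 0.0
        if self.has_intercept_re and np.isfinite(ratio):
            if weights is None:
                logdet_subj = float(np.log(self.ns + ratio).sum())
                s_eff = float(self.S)
            else:
                w = np.asarray(weights, dtype=float)
                logdet_subj = float(w @ np.log(self.ns + ratio))
                s_eff = float(w.sum())
        log_lam = float(
            sum(k * np.log(l) for k, l in zip(self.block_sizes, lambdas))
        )
        log_ratio = s_eff * np.log(ratio) if s_eff else 0.0

        if reml:
            # uses |C'C + P| = prod(n_s + r) |A|
            logdet_A = 2.0 * float(np.log(np.diag(cho[0])).sum())
            dof = n_eff - self.p
            return (
                dof * np.log(pls / dof)
                + logdet_subj + logdet_A
                - log_lam - log_ratio
                + dof * (1.0 + _LOG2PI)
            )
        # ML: determinant over penalized + subject blocks only
        pp = self._pen_cols
        if pp.any():
            Ap = M[np.ix_(pp, pp)] + np.diag(self._penalty_diag(lambdas)[pp])
            sign, logdet_p = np.linalg.slogdet(Ap)
            if sign <= 0:
                return np.inf
        else:
            logdet_p = 0.0
        return (
            n_eff * np.log(pls / n_eff)
            + logdet_subj + logdet_p
            - log_lam - log_ratio
            + n_eff * (1.0 + _LOG2PI)
        )

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def fit(
        self,
        y,
        reml=False,
        fixed_lambdas=None,
        fixed_ratio=None,
        n_restarts=3,
        tol=1e-8,
    ) -> LMMFit:
        """Maximize the (restricted) marginal likelihood over (lambdas, r).

        Smoothing parameters / the variance ratio can be pinned with
        ``fixed_lambdas`` / ``fixed_ratio`` (e.g. for bootstrap refits or
        limit checks).
        """
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("fit() takes a single response; see solve()")
        rstats = self.response_stats(y)

        free_lam = fixed_lambdas is None and self.n_groups > 0
        free_ratio = fixed_ratio is None and self.has_intercept_re
        n_free = (self.n_groups if free_lam else 0) + (1 if free_ratio else 0)

        def unpack(theta):
            i = 0
            if free_lam:
                lambdas = np.exp(theta[: self.n_groups])
                i = self.n_groups
            else:
                lambdas = (
                    np.atleast_1d(np.asarray(fixed_lambdas, dtype=float))
                    if self.n_groups
                    else np.empty(0)
                )
            if free_ratio:
                ratio = float(np.exp(theta[i]))
            else:
                ratio = (
                    float(fixed_ratio)
                    if self.has_intercept_re
                    else np.inf
                )
            return lambdas, ratio

        converged = True
        if n_free == 0:
            theta_best = np.empty(0)
        else:
            def objective(theta):
                lam, r = unpack(theta)
                try:
                    return self.neg2loglik(lam, r, rstats, reml=reml)
                except linalg.LinAlgError:
                    return np.inf

            starts = []
            base = []
            if free_lam:
                base += [2.0] * self.n_groups
            if free_ratio:
                base += [0.0]
            starts.append(np.array(base))
            rng = np.random.default_rng(0)
            for _ in range(max(0, n_restarts - 1)):
                starts.append(np.array(base) + rng.uniform(-4, 4, n_free))

            lo = [-12.0] * n_free
            hi = [28.0] * n_free
            best = None
            for x0 in starts:
                res = optimize.minimize(
                    objective,
                    x0,
                    method="L-BFGS-B",
                    bounds=list(zip(lo, hi)),
                    options={"ftol": tol, "gtol": 1e-7, "maxiter": 200},
                )
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun):
                raise RuntimeError(
                    "marginal-likelihood optimization failed to produce a "
                    "finite criterion after restarts"
                )
            if not best.success:
                # a numerically perfect fit (zero-noise data) leaves the
                # criterion unbounded below; any boundary solution is fine
                lam_chk, r_chk = unpack(np.clip(best.x, lo, hi))
                _, pls_chk, _, _, _ = self.solve(lam_chk, r_chk, rstats)
                _, _, yys_chk = rstats
                if float(pls_chk) <= 1e-12 * float(np.sum(yys_chk)):
                    best.success = True
            if not best.success:
                # the criterion is very flat in log-lambda near the optimum;
                # polish with a derivative-free step before judging
                polish = optimize.minimize(
                    objective, np.clip(best.x, lo, hi), method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
                )
                if polish.fun <= best.fun:
                    best = polish
                x = np.clip(best.x, lo, hi)
                g = optimize.approx_fprime(x, objective, 1e-6)
                # projected gradient: solutions at the box edge are
                # legitimate boundary optima (e.g. lambda -> 0 or infinity)
                at_lo = x <= np.asarray(lo) + 1e-8
                at_hi = x >= np.asarray(hi) - 1e-8
                g = np.where((at_lo & (g > 0)) | (at_hi & (g < 0)), 0.0, g)
                gnorm = float(np.linalg.norm(g))
                scale = max(abs(best.fun), 1.0)
                if gnorm > 1e-4 * scale:
                    raise RuntimeError(
                        "marginal-likelihood optimizer did not converge; "
                        f"final projected gradient norm {gnorm:.3g}"
                    )
                converged = bool(best.success) or gnorm < 1e-6 * scale
            theta_best = best.x

        lambdas, ratio = unpack(theta_best)
        beta, pls, n_eff, M, cho = self.solve(lambdas, ratio, rstats)
        pls = float(pls)
        dof = n_eff - self.p if reml else n_eff
        sigma2 = max(pls / dof, 1e-300)
        sigma2_subject = (
            sigma2 / ratio if self.has_intercept_re and np.isfinite(ratio) else 0.0
        )
        cov_beta = sigma2 * linalg.cho_solve(cho, np.eye(self.q))
        # BLUPs and effective dof
        alpha = None
        if self.has_intercept_re and np.isfinite(ratio):
            _, ts, _ = rstats
            alpha = (ts - self.gs @ beta) / (self.ns + ratio)
        edf = float(np.trace(linalg.cho_solve(cho, M)))
        ll = -0.5 * self.neg2loglik(
            lambdas if self.n_groups else np.empty(0), ratio, rstats, reml=reml
        )
        return LMMFit(
            beta=beta,
            lambdas=np.atleast_1d(lambdas),
            ratio=ratio,
            sigma2=sigma2,
            sigma2_subject=sigma2_subject,
            loglik=ll,
            cov_beta=cov_beta,
            alpha=alpha,
            edf=edf,
            converged=converged,
            method="REML" if reml else "ML",
            n_obs=self.n,
        )

    # ------------------------------------------------------------------ #
    # subject bootstrap support
    # ------------------------------------------------------------------ #

    def subject_index(self):
        """Map from row to subject position (0..S-1)."""
        return self._row_subject

    def bootstrap_beta(self, lambdas, ratio, rstats, weights):
        """Coefficients refit under subject multiplicities ``weights``."""
        beta, _, _, _, _ = self.solve(lambdas, ratio, rstats, weights)
        return beta
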