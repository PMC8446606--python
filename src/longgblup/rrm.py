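"""Random regression GBLUP: mixed-model equations and AI-REML.

The model for a record of line *i* at DAP *t* in environment-replication *k*::

    y = env_k + sum_m b_m phi_m(t) + sum_m a_im phi_m(t) + e

with random coefficient vectors ``a_i`` jointly Gaussian,
``var(vec(a)) = G (x) G0`` (line-major Kronecker ordering: the m coefficients
of one line are contiguous), ``G`` the genomic relationship matrix, ``G0`` the
m x m coefficient covariance, and residuals independent with a variance per
DAP class.  Variance components are estimated by restricted maximum
likelihood using average-information (AI) updates with step-halving and an
EM fallback whenever the AI step leaves the parameter space or decreases the
restricted likelihood.

The restricted log-likelihood is evaluated through the mixed-model-equation
factorization (log-determinant identity) rather than by inverting the
record-level covariance, so cost scales with the number of lines times
coefficients, not the number of records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .data import PhenotypeTable
from .grm import GRMResult
from .residuals import ResidualClassMap

logger = logging.getLogger(__name__)

__all__ = ["RandomRegressionGBLUP", "RRMFit", "build_mme", "reml_estimate", "aic_compare"]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

class _Design:
    """Record-level design shared across REML iterations.

    Fixed part: one indicator column per env_rep plus the basis columns with
    the first column dropped (the basis constant/partition-of-unity direction
    is absorbed by the env_rep means, keeping X full rank).
    Random part: per-line blocks of basis rows, line-major ordering.
    """

    def __init__(self, phenotypes: PhenotypeTable, basis, grm: GRMResult,
                 residual_map: ResidualClassMap, merge_classes: bool = True):
        df = phenotypes.df
        line_index = {l: i for i, l in enumerate(grm.line_ids)}
        missing = sorted(set(df["line"]) - set(line_index))
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped line(s) absent from the relationship "
                f"matrix, e.g. {missing[:5]}"
            )
        self.line_ids = list(grm.line_ids)
        self.n = len(self.line_ids)
        self.m = basis.n_coef
        self.basis = basis
        y_raw = df["value"].to_numpy(dtype=float)
        # center once: REML and BLUPs are invariant to a constant shift, and
        # working near zero avoids cancellation in y'Py for large baselines
        self.y_offset = float(np.mean(y_raw)) if np.all(np.isfinite(y_raw)) else 0.0
        self.y = y_raw - self.y_offset
        self.N = self.y.size
        self.line_idx = df["line"].map(line_index).to_numpy(dtype=np.int64)
        daps = df["dap"].to_numpy(dtype=int)
        self.daps = daps
        self.T_rec = basis.design_matrix(daps)              # (N, m)

        env_labels = sorted(df["env_rep"].unique().tolist())
        self.env_labels = env_labels
        env_pos = {e: j for j, e in enumerate(env_labels)}
        env_idx = df["env_rep"].map(env_pos).to_numpy(dtype=np.int64)
        K = len(env_labels)
        X = np.zeros((self.N, K + self.m - 1))
        X[np.arange(self.N), env_idx] = 1.0
        X[:, K:] = self.T_rec[:, 1:]
        self.X = X
        self.fixed_names = [f"env:{e}" for e in env_labels] + [
            f"phi_{j}" for j in range(1, self.m)
        ]
        self._check_rank()

        # classes too thin to estimate a variance are merged; at fixed
        # variance components empty classes are harmless and the map is kept
        self.residual_map = (
            residual_map.merged_for_records(daps) if merge_classes else residual_map
        )
        self.res_class = self.residual_map.class_of(daps)
        self.n_classes = self.residual_map.n_classes
        self.class_counts = np.bincount(self.res_class, minlength=self.n_classes)

        # sparse W = [X | Z]; Z row r has the basis row at line block l_r
        self.p = X.shape[1]
        self.q_u = self.n * self.m
        self.q = self.p + self.q_u
        rows = np.repeat(np.arange(self.N), self.m)
        cols = (self.line_idx[:, None] * self.m + np.arange(self.m)).ravel() + self.p
        Z = sp.csr_matrix(
            (self.T_rec.ravel(), (rows, cols - self.p)), shape=(self.N, self.q_u)
        )
        self.W = sp.hstack([sp.csr_matrix(X), Z], format="csr")

        # per-class cross-products, fixed across iterations
        self.A_k, self.Wty_k, self.yty_k = [], [], []
        for k in range(self.n_classes):
            rows_k = np.flatnonzero(self.res_class == k)
            Wk = self.W[rows_k]
            self.A_k.append((Wk.T @ Wk).tocoo())
            self.Wty_k.append(np.asarray(Wk.T @ self.y[rows_k]).ravel())
            self.yty_k.append(float(self.y[rows_k] @ self.y[rows_k]))

        self.Ginv = grm.G_inv()
        sign, self.logdetG = np.linalg.slogdet(
            grm.G + 1e-8 * np.eye(self.n)
        )
        if sign <= 0:
            raise ValueError("relationship matrix is not positive definite after lift")

    def _check_rank(self):
        R = np.linalg.qr(self.X, mode="r")
        d = np.abs(np.diag(R))
        tol = max(self.X.shape) * np.finfo(float).eps * (d.max() if d.size else 1.0)
        if np.any(d < tol):
            bad = [self.fixed_names[j] for j in np.flatnonzero(d < tol)]
            raise ValueError(f"fixed-effect design is rank deficient; confounded columns: {bad}")

    # -- per-varcomp evaluation ---------------------------------------------

    def assemble(self, G0: np.ndarray, sigma2: np.ndarray):
        """Coefficient matrix C, its Cholesky factor, solutions and logL."""
        inv_s2 = 1.0 / sigma2
        A = self.A_k[0] * inv_s2[0]
        for k in range(1, self.n_classes):
            A = A + self.A_k[k] * inv_s2[k]
        C = np.asarray(A.todense())
        G0inv = np.linalg.inv(G0)
        C[self.p:, self.p:] += np.kron(self.Ginv, G0inv)

        rhs = np.zeros(self.q)
        yRy = 0.0
        for k in range(self.n_classes):
            rhs += self.Wty_k[k] * inv_s2[k]
            yRy += self.yty_k[k] * inv_s2[k]

        cf = sla.cho_factor(C, lower=True, check_finite=False)
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        yPy = yRy - rhs @ theta
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sign0, logdetG0 = np.linalg.slogdet(G0)
        if sign0 <= 0:
            raise np.linalg.LinAlgError("G0 not positive definite")
        logdetR = float(np.sum(self.class_counts * np.log(sigma2)))
        logL = -0.5 * (
            logdetR
            + self.m * self.logdetG
            + self.n * logdetG0
            + logdetC
            + yPy
            + (self.N - self.p) * _LOG2PI
        )
        return C, cf, theta, float(logL), G0inv

    def residuals(self, theta):
        return self.y - np.asarray(self.W @ theta).ravel()


def _vech_indices(m: int):
    return [(i, j) for i in range(m) for j in range(i, m)]


@dataclass
class RRMFit:
    """Result container for one fitted random regression model."""

    G0_hat: np.ndarray
    residual_variances: np.ndarray
    residual_map: ResidualClassMap
    b_hat: pd.Series
    env_effects: pd.Series
    g_hat: np.ndarray            # (n_lines, m) coefficient BLUPs
    line_ids: list
    basis: object
    logL_reml: float
    n_varcomp_params: int
    AIC: float
    converged: bool
    n_iterations: int
    varcomp_se: np.ndarray | None = None
    label: str | None = None

    def gebv(self, dap_grid) -> np.ndarray:
        """Breeding-value trajectories: rows are lines, columns the grid."""
        T = self.basis.design_matrix(np.asarray(dap_grid))
        return self.g_hat @ T.T


class RandomRegressionGBLUP(BaseEstimator):
    """Random regression GBLUP with AI-REML variance-component estimation.

    Parameters
    ----------
    basis : LegendreBasis or BSplineBasis
        Covariance-function basis defining the regression on DAP.
    residual_mode : {"heterogeneous", "homogeneous"}
        One residual variance per DAP class, or a single variance.
    residual_map : ResidualClassMap, optional
        DAP class map for heterogeneous residuals.  Defaults to the standard
        19-interval map when the basis covers 27-83 DAP, otherwise a single
        class.
    max_iter, tol : int, float
        REML iteration control.  Convergence requires both the relative
        parameter change and the scaled gradient norm to fall below ``tol``.
    varcomps : tuple (G0, sigma2), optional
        Fix the variance components and only solve the mixed-model equations
        (used by cross-validation when re-estimation is switched off).
    g0_floor_ratio : float
        Eigenvalue floor for G0 iterates, relative to the phenotypic
        variance; keeps the coefficient precision matrix finite when the
        genetic variance approaches zero.

    Attributes (after fit)
    ----------------------
    G0_, residual_variances_, residual_map_, beta_, env_effects_,
    coef_blups_, line_ids_, loglik_, aic_, n_varcomp_params_, converged_,
    n_iter_, varcomp_se_, fit_ (the :class:`RRMFit` bundle).
    """

    def __init__(self, basis=None, residual_mode: str = "heterogeneous",
                 residual_map: ResidualClassMap | None = None,
                 max_iter: int = 100, tol: float = 1e-6,
                 varcomps=None, g0_floor_ratio: float = 1e-6, label: str | None = None):
        self.basis = basis
        self.residual_mode = residual_mode
        self.residual_map = residual_map
        self.max_iter = max_iter
        self.tol = tol
        self.varcomps = varcomps
        self.g0_floor_ratio = g0_floor_ratio
        self.label = label

    # -- helpers ------------------------------------------------------------

    def _resolve_map(self) -> ResidualClassMap:
        dap_min, dap_max = int(self.basis.dap_min), int(self.basis.dap_max)
        if self.residual_mode == "homogeneous":
            return ResidualClassMap.homogeneous(dap_min, dap_max)
        if self.residual_mode != "heterogeneous":
            raise ValueError(f"unknown residual_mode: {self.residual_mode!r}")
        if self.residual_map is not None:
            return self.residual_map
        default = ResidualClassMap.default()
        if (dap_min, dap_max) == (default.dap_min, default.dap_max):
            return default
        raise ValueError(
            "heterogeneous residuals on a non-default DAP range require an "
            "explicit residual_map"
        )

    def _floor_g0(self, G0: np.ndarray, floor: float) -> np.ndarray:
        w, V = np.linalg.eigh(0.5 * (G0 + G0.T))
        w = np.maximum(w, floor)
        return (V * w) @ V.T

    # -- estimation ---------------------------------------------------------

    def fit(self, phenotypes: PhenotypeTable, grm: GRMResult):
        if self.basis is None:
            raise ValueError("a basis must be provided")
        if len(phenotypes) == 0:
            raise ValueError("empty phenotype table")
        des = _Design(
            phenotypes, self.basis, grm, self._resolve_map(),
            merge_classes=self.varcomps is None,
        )
        m, n, N = des.m, des.n, des.N
        if n < m + 2:
            raise ValueError(f"need at least m+2={m + 2} lines, got {n}")
        var_p = float(np.var(des.y))
        if not np.isfinite(var_p) or var_p <= 0:
            var_p = 1.0
        g0_floor = self.g0_floor_ratio * var_p
        s2_floor = 1e-8 * var_p

        if self.varcomps is not None:
            G0, sigma2 = self.varcomps
            G0 = np.asarray(G0, dtype=float)
            sigma2 = np.broadcast_to(
                np.atleast_1d(np.asarray(sigma2, float)), (des.n_classes,)
            ).copy()
            _, cf, theta, logL, _ = des.assemble(self._floor_g0(G0, g0_floor), sigma2)
            return self._finalize(des, G0, sigma2, theta, logL, True, 0, None)

        # scale-aware initialization
        G0 = (var_p / (2.0 * m)) * np.eye(m)
        sigma2 = np.empty(des.n_classes)
        for k in range(des.n_classes):
            vk = float(np.var(des.y[des.res_class == k]))
            sigma2[k] = 0.5 * (vk if vk > 0 else var_p)
        sigma2 = np.maximum(sigma2, s2_floor)

        vech = _vech_indices(m)
        n_g0 = len(vech)
        n_par = n_g0 + des.n_classes

        C, cf, theta, logL, G0inv = des.assemble(G0, sigma2)
        if not np.isfinite(logL):
            raise ValueError("non-finite restricted likelihood at initialization")

        converged = False
        n_iter = 0
        AI = None
        loglik_path = [logL]
        for n_iter in range(1, self.max_iter + 1):
            # quantities at the current iterate
            Cinv = sla.cho_solve(cf, np.eye(des.q), check_finite=False)
            ehat = des.residuals(theta)
            Py = ehat / sigma2[des.res_class]
            U_hat = theta[des.p:].reshape(n, m)
            M = U_hat @ G0inv                        # (n, m)
            K = Cinv[des.p:, des.p:].reshape(n, m, n, m)
            S = np.einsum("aibj,ab->ij", K, des.Ginv)
            S = 0.5 * (S + S.T)
            Qt = n * G0inv - G0inv @ S @ G0inv

            # working variates (record space), one per parameter
            Wv = np.empty((N, n_par))
            Ml = M[des.line_idx]                     # (N, m)
            for c, (i, j) in enumerate(vech):
                w = des.T_rec[:, j] * Ml[:, i]
                if i != j:
                    w = w + des.T_rec[:, i] * Ml[:, j]
                Wv[:, c] = w
            for k in range(des.n_classes):
                col = np.zeros(N)
                rows_k = des.res_class == k
                col[rows_k] = Py[rows_k]
                Wv[:, n_g0 + k] = col

            # gradient
            grad = np.empty(n_par)
            yPVPy = Wv.T @ Py
            for c, (i, j) in enumerate(vech):
                tr = Qt[i, i] if i == j else 2.0 * Qt[i, j]
                grad[c] = -0.5 * (tr - yPVPy[c])
            for k in range(des.n_classes):
                Ak = des.A_k[k]
                trCA = float(np.sum(Cinv[Ak.row, Ak.col] * Ak.data))
                trPDk = des.class_counts[k] / sigma2[k] - trCA / sigma2[k] ** 2
                grad[n_g0 + k] = -0.5 * (trPDk - yPVPy[n_g0 + k])

            # average-information matrix: AI_ab = 0.5 * w_a' P w_b
            inv_s2_rec = 1.0 / sigma2[des.res_class]
            V1 = Wv * inv_s2_rec[:, None]
            V2 = des.W.T @ V1
            V3 = sla.cho_solve(cf, V2, check_finite=False)
            PW = V1 - (des.W @ V3) * inv_s2_rec[:, None]
            AI = 0.5 * (Wv.T @ PW)
            AI = 0.5 * (AI + AI.T)

            # proposed AI step with step-halving; EM fallback
            ridge = 1e-8 * (np.trace(AI) / n_par if np.trace(AI) > 0 else 1.0)
            try:
                delta = np.linalg.solve(AI + ridge * np.eye(n_par), grad)
            except np.linalg.LinAlgError:
                delta = grad / (np.diag(AI) + ridge)

            cur = np.concatenate([[G0[i, j] for i, j in vech], sigma2])
            accepted = False
            step = 1.0
            for _ in range(12):
                trial = cur + step * delta
                G0_t = np.empty((m, m))
                for c, (i, j) in enumerate(vech):
                    G0_t[i, j] = G0_t[j, i] = trial[c]
                s2_t = trial[n_g0:]
                if np.any(s2_t < s2_floor) or np.any(
                    np.linalg.eigvalsh(0.5 * (G0_t + G0_t.T)) < g0_floor
                ):
                    step *= 0.5
                    continue
                try:
                    C_t, cf_t, theta_t, logL_t, G0inv_t = des.assemble(G0_t, s2_t)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if logL_t >= logL - 1e-10 * (1.0 + abs(logL)):
                    accepted = True
                    break
                step *= 0.5

            if not accepted:
                # EM step: guaranteed uphill, always inside the cone
                G0_t = (U_hat.T @ des.Ginv @ U_hat + S) / n
                G0_t = self._floor_g0(0.5 * (G0_t + G0_t.T), g0_floor)
                s2_t = np.empty(des.n_classes)
                for k in range(des.n_classes):
                    rows_k = des.res_class == k
                    Ak = des.A_k[k]
                    trCA = float(np.sum(Cinv[Ak.row, Ak.col] * Ak.data))
                    trPDk = des.class_counts[k] / sigma2[k] - trCA / sigma2[k] ** 2
                    s2_t[k] = (
                        float(ehat[rows_k] @ ehat[rows_k])
                        + sigma2[k] * des.class_counts[k]
                        - sigma2[k] ** 2 * trPDk
                    ) / des.class_counts[k]
                s2_t = np.maximum(s2_t, s2_floor)
                C_t, cf_t, theta_t, logL_t, G0inv_t = des.assemble(G0_t, s2_t)
                trial = np.concatenate([[G0_t[i, j] for i, j in vech], s2_t])

            rel_change = np.max(np.abs(trial - cur)) / (np.max(np.abs(cur)) + 1e-30)
            scale = np.abs(cur) + 1e-3 * var_p
            grad_norm = np.max(np.abs(grad * scale)) / N

            G0, sigma2 = G0_t, s2_t
            C, cf, theta, logL, G0inv = C_t, cf_t, theta_t, logL_t, G0inv_t
            loglik_path.append(logL)
            logger.debug(
                "REML iter %d: logL=%.6f relchg=%.2e gradnorm=%.2e",
                n_iter, logL, rel_change, grad_norm,
            )
            if rel_change < self.tol and grad_norm < self.tol:
                converged = True
                break

        se = None
        if AI is not None:
            try:
                se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
            except np.linalg.LinAlgError:
                se = None
        if not converged:
            logger.warning("REML did not converge in %d iteration(s)", n_iter)
        out = self._finalize(des, G0, sigma2, theta, logL, converged, n_iter, se)
        self.loglik_path_ = np.asarray(loglik_path)
        return out

    def _finalize(self, des, G0, sigma2, theta, logL, converged, n_iter, se):
        m = des.m
        K = len(des.env_labels)
        fixed = theta[: des.p].copy()
        fixed[:K] += des.y_offset  # undo the internal centering
        beta = pd.Series(fixed, index=des.fixed_names)
        env_eff = pd.Series(fixed[:K], index=des.env_labels)
        n_varcomp = m * (m + 1) // 2 + des.n_classes
        self.G0_ = 0.5 * (G0 + G0.T)
        self.residual_variances_ = np.asarray(sigma2, float)
        self.residual_map_ = des.residual_map
        self.beta_ = beta
        self.env_effects_ = env_eff
        self.coef_blups_ = theta[des.p:].reshape(des.n, m)
        self.line_ids_ = des.line_ids
        self.loglik_ = float(logL)
        self.n_varcomp_params_ = n_varcomp
        self.aic_ = -2.0 * float(logL) + 2.0 * n_varcomp
        self.converged_ = bool(converged)
        self.n_iter_ = int(n_iter)
        self.varcomp_se_ = se
        self.fit_ = RRMFit(
            G0_hat=self.G0_,
            residual_variances=self.residual_variances_,
            residual_map=des.residual_map,
            b_hat=beta,
            env_effects=env_eff,
            g_hat=self.coef_blups_,
            line_ids=des.line_ids,
            basis=self.basis,
            logL_reml=self.loglik_,
            n_varcomp_params=n_varcomp,
            AIC=self.aic_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            varcomp_se=se,
            label=self.label,
        )
        return self

    def predict(self, dap_grid) -> np.ndarray:
        """GEBV trajectories for all lines on ``dap_grid`` (lines x grid)."""
        if not hasattr(self, "fit_"):
            raise ValueError("model is not fitted")
        return self.fit_.gebv(dap_grid)


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def build_mme(phenotypes: PhenotypeTable, basis, grm: GRMResult,
              residual_map: ResidualClassMap, varcomps) -> RRMFit:
    """Assemble and solve the mixed-model equations at fixed variance
    components ``(G0, sigma2_per_class)``; returns the solved fit."""
    est = RandomRegressionGBLUP(
        basis=basis, residual_map=residual_map, residual_mode="heterogeneous",
        varcomps=varcomps,
    )
    return est.fit(phenotypes, grm).fit_


def reml_estimate(phenotypes: PhenotypeTable, basis, grm: GRMResult,
                  residual_map: ResidualClassMap | None = None,
                  residual_mode: str = "heterogeneous",
                  max_iter: int = 100, tol: float = 1e-6) -> RRMFit:
    """Estimate variance components by AI-REML and return the fitted model."""
    est = RandomRegressionGBLUP(
        basis=basis, residual_mode=residual_mode, residual_map=residual_map,
        max_iter=max_iter, tol=tol,
    )
    return est.fit(phenotypes, grm).fit_


def aic_compare(fits: list) -> pd.DataFrame:
    """Rank fitted models by AIC (converged fits only; others listed last)."""
    if not any(f.converged for f in fits):
        raise ValueError("no converged fit to rank")
    rows = []
    for i, f in enumerate(fits):
        rows.append(
            {
                "model": f.label or f"model_{i}",
                "n_coef": f.G0_hat.shape[0],
                "n_varcomp_params": f.n_varcomp_params,
                "logL": f.logL_reml,
                "AIC": f.AIC,
                "converged": f.converged,
            }
        )
    df = pd.DataFrame(rows)
    conv = df[df["converged"]].sort_values("AIC", kind="mergesort")
    rest = df[~df["converged"]]
    out = pd.concat([conv, rest]).reset_index(drop=True)
    out["rank"] = [i + 1 if c else pd.NA for i, c in enumerate(out["converged"])]
    return out
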