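"""Covariance-function bases for random regression models.

A random regression model describes each line's additive genetic effect as a
regression on functions of time (days after planting, DAP).  The basis maps a
vector of DAP values onto a covariate matrix ``T`` (one row per time point,
one column per regression coefficient); the coefficient covariance ``G0`` then
induces a covariance between any two time points, ``Sigma = T G0 T'``.

Two families are provided:

* :class:`LegendreBasis` — normalized Legendre orthogonal polynomials on the
  time axis standardized to [-1, 1].
* :class:`BSplineBasis` — clamped B-splines of degree 1 or 2 built from the
  Cox–de Boor recursion with user-supplied interior knots.

Both are scikit-learn transformers: ``transform(daps)`` returns ``T``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["standardize_time", "LegendreBasis", "BSplineBasis", "basis_from_config"]


def standardize_time(dap, dap_min: float, dap_max: float):
    """Affinely map DAP values onto [-1, 1].

    ``dap_min`` maps to -1 and ``dap_max`` to +1.  Values outside the range
    raise ``ValueError`` — the basis is only defined on the observed interval.
    """
    if not dap_min < dap_max:
        raise ValueError(f"dap_min ({dap_min}) must be < dap_max ({dap_max})")
    t = np.asarray(dap, dtype=float)
    if np.any(t < dap_min) or np.any(t > dap_max):
        bad = t[(t < dap_min) | (t > dap_max)]
        raise ValueError(
            f"DAP value(s) {np.unique(bad)} outside range [{dap_min}, {dap_max}]"
        )
    return 2.0 * (t - dap_min) / (dap_max - dap_min) - 1.0


class _TimeBasis(BaseEstimator, TransformerMixin):
    """Shared plumbing: stateless transformers, ``fit`` only validates."""

    def fit(self, X, y=None):
        self._validate()
        return self

    def transform(self, X):
        """Evaluate the basis at DAP values ``X`` -> matrix (len(X), m)."""
        self._validate()
        daps = np.atleast_1d(np.asarray(X, dtype=float)).ravel()
        if daps.size == 0:
            raise ValueError("empty DAP vector")
        return self._design(daps)

    # alias used throughout the pipeline code; reads better than transform()
    def design_matrix(self, daps):
        return self.transform(daps)

    @property
    def n_coef(self) -> int:
        self._validate()
        return self._n_coef()

    def to_config(self) -> dict:
        raise NotImplementedError


class LegendreBasis(_TimeBasis):
    """Normalized Legendre orthogonal polynomial basis.

    Column ``k`` (0-based) is ``phi_k(t) = sqrt((2k+1)/2) * P_k(t)`` evaluated
    at standardized time ``t`` in [-1, 1].  The ``sqrt((2k+1)/2)`` factor makes
    the family orthonormal under the L2 inner product on [-1, 1]; any fixed
    scaling is absorbed by the coefficient covariance ``G0``, but it must be
    pinned down for reproducibility.

    Parameters
    ----------
    order : int
        Highest polynomial order; the basis has ``order + 1`` columns
        (a "third-order" basis has 4 coefficients).
    dap_min, dap_max : float
        Time range mapped onto [-1, 1].
    """

    kind = "legendre"

    def __init__(self, order: int = 3, dap_min: float = 27, dap_max: float = 83):
        self.order = order
        self.dap_min = dap_min
        self.dap_max = dap_max

    def _validate(self):
        if int(self.order) < 1 or self.order != int(self.order):
            raise ValueError(f"Legendre order must be an integer >= 1, got {self.order}")
        if not self.dap_min < self.dap_max:
            raise ValueError("dap_min must be < dap_max")

    def _n_coef(self) -> int:
        return int(self.order) + 1

    def _design(self, daps: np.ndarray) -> np.ndarray:
        t = standardize_time(daps, self.dap_min, self.dap_max)
        m = self._n_coef()
        # legvander gives plain P_k(t); scale columns to the orthonormal family
        V = npleg.legvander(t, int(self.order))
        norms = np.sqrt((2.0 * np.arange(m) + 1.0) / 2.0)
        return V * norms

    def to_config(self) -> dict:
        return {
            "kind": "legendre",
            "order": int(self.order),
            "dap_min": float(self.dap_min),
            "dap_max": float(self.dap_max),
        }


class BSplineBasis(_TimeBasis):
    """Clamped B-spline basis of degree 1 or 2 via the Cox–de Boor recursion.

    The degree-0 function for the interval ``[T_m, T_{m+1})`` is the indicator
    of that interval; degree ``p`` functions combine two lower-degree ones with
    the ratios ``(t - T_m)/(T_{m+p} - T_m)`` and
    ``(T_{m+p+1} - t)/(T_{m+p+1} - T_{m+1})``, with 0/0 defined as 0.

    Boundary knots at ``dap_min`` and ``dap_max`` are repeated so each end has
    multiplicity ``p + 1`` (the clamped convention), giving
    ``len(knots) + p + 1`` basis functions whose sum is 1 everywhere on the
    range.  The last basis function is extended to include the right endpoint
    so the design matrix has no zero rows at ``dap_max``.

    Parameters
    ----------
    degree : int
        Spline degree, 1 (linear) or 2 (quadratic).
    knots : sequence of float
        Interior knots, strictly increasing, strictly inside
        ``(dap_min, dap_max)``.
    """

    kind = "bspline"

    def __init__(self, degree: int = 1, knots=(44, 66), dap_min: float = 27, dap_max: float = 83):
        self.degree = degree
        self.knots = tuple(knots)
        self.dap_min = dap_min
        self.dap_max = dap_max

    def _validate(self):
        if self.degree not in (1, 2):
            raise ValueError(f"B-spline degree must be 1 or 2, got {self.degree}")
        if not self.dap_min < self.dap_max:
            raise ValueError("dap_min must be < dap_max")
        kn = np.asarray(self.knots, dtype=float)
        if kn.size and np.any(np.diff(kn) <= 0):
            raise ValueError(f"interior knots must be strictly increasing: {self.knots}")
        if kn.size and (kn[0] <= self.dap_min or kn[-1] >= self.dap_max):
            raise ValueError(
                f"interior knots {self.knots} must lie strictly inside "
                f"({self.dap_min}, {self.dap_max})"
            )

    def _n_coef(self) -> int:
        return len(self.knots) + self.degree + 1

    def full_knots(self) -> np.ndarray:
        """Full knot vector with clamped (multiplicity p+1) boundary knots."""
        p = int(self.degree)
        return np.concatenate(
            [[self.dap_min] * (p + 1), np.asarray(self.knots, float), [self.dap_max] * (p + 1)]
        )

    def _design(self, daps: np.ndarray) -> np.ndarray:
        standardize_time(daps, self.dap_min, self.dap_max)  # range check only
        tau = self.full_knots()
        p = int(self.degree)
        n_fun = self._n_coef()
        n_knot_fun0 = len(tau) - 1  # number of degree-0 indicator functions

        # degree 0: indicator of [tau_m, tau_{m+1}); the final nonempty
        # interval is closed on the right so dap_max is covered
        B = np.zeros((daps.size, n_knot_fun0))
        last = np.max(np.nonzero(np.diff(tau) > 0)[0])
        for m in range(n_knot_fun0):
            if m == last:
                B[:, m] = (daps >= tau[m]) & (daps <= tau[m + 1])
            else:
                B[:, m] = (daps >= tau[m]) & (daps < tau[m + 1])

        for d in range(1, p + 1):
            nb = n_knot_fun0 - d
            Bn = np.zeros((daps.size, nb))
            for m in range(nb):
                left_den = tau[m + d] - tau[m]
                right_den = tau[m + d + 1] - tau[m + 1]
                term = 0.0
                if left_den > 0:
                    term = (daps - tau[m]) / left_den * B[:, m]
                if right_den > 0:
                    term = term + (tau[m + d + 1] - daps) / right_den * B[:, m + 1]
                Bn[:, m] = term
            B = Bn
        assert B.shape[1] == n_fun
        return B

    def to_config(self) -> dict:
        return {
            "kind": "bspline",
            "degree": int(self.degree),
            "knots": [float(k) for k in self.knots],
            "dap_min": float(self.dap_min),
            "dap_max": float(self.dap_max),
        }


def basis_from_config(cfg: dict):
    """Rebuild a basis from its ``to_config()`` dictionary."""
    kind = cfg.get("kind")
    if kind == "legendre":
        return LegendreBasis(order=cfg["order"], dap_min=cfg["dap_min"], dap_max=cfg["dap_max"])
    if kind == "bspline":
        return BSplineBasis(
            degree=cfg["degree"], knots=cfg["knots"],
            dap_min=cfg["dap_min"], dap_max=cfg["dap_max"],
        )
    raise ValueError(f"unknown basis kind: {kind!r}")
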