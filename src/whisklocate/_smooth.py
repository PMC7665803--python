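"""Penalized cubic B-spline smoothing with GCV-selected penalty.

Stand-in for adaptive spline smoothers of firing-rate curves: a cubic
B-spline basis with a knot near every data point and a second-difference
penalty on the coefficients, the penalty weight chosen per curve by
generalized cross-validation over a fixed log-spaced grid.  Factorizations
are cached per x-grid, so smoothing many curves sampled on the same support
(e.g. Monte-Carlo nulls of a PSTH) costs a few small matrix products each.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

_LAM_GRID = np.logspace(-4, 6, 21)
_CACHE: dict[bytes, "GCVSpline"] = {}
_CACHE_MAX = 32


class GCVSpline:
    """Penalized-spline smoother bound to a fixed x grid."""

    def __init__(self, x: np.ndarray, max_basis: int = 100):
        x = np.asarray(x, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        self.x = x
        n = len(x)
        k = 3
        n_basis = min(max_basis, n)
        # knots spread over quantiles of x so uneven grids are handled
        n_inner = max(n_basis - k - 1, 0)
        if n_inner > 0:
            qs = np.linspace(0, 1, n_inner + 2)[1:-1]
            inner = np.quantile(x, qs)
        else:
            inner = np.empty(0)
        self.t = np.concatenate([np.repeat(x[0], k + 1), inner,
                                 np.repeat(x[-1], k + 1)])
        m = len(self.t) - k - 1
        self.k = k
        self.B = BSpline.design_matrix(x, self.t, k).toarray()
        D = np.diff(np.eye(m), n=2, axis=0)
        P = D.T @ D
        BtB = self.B.T @ self.B
        self._Bt = self.B.T
        self._factors = []
        self._edf = []
        for lam in _LAM_GRID:
            A = BtB + lam * P
            A[np.diag_indices_from(A)] += 1e-10
            c, low = cho_factor(A)
            self._factors.append((c, low))
            # effective degrees of freedom = tr(B A^-1 B')
            Ainv_Bt = cho_solve((c, low), self._Bt)
            self._edf.append(float(np.sum(self.B * Ainv_Bt.T)))

    def fit_coefficients(self, y: np.ndarray) -> np.ndarray:
        """GCV-best spline coefficients for one curve."""
        y = np.asarray(y, dtype=float)
        n = len(y)
        Bty = self._Bt @ y
        best, best_gcv = None, np.inf
        for (fac, edf) in zip(self._factors, self._edf):
            coef = cho_solve(fac, Bty)
            resid = y - self.B @ coef
            denom = max(1.0 - edf / n, 1e-8)
            gcv = (resid @ resid / n) / denom**2
            if gcv < best_gcv:
                best_gcv, best = gcv, coef
        return best

    def smooth(self, y: np.ndarray) -> np.ndarray:
        return self.B @ self.fit_coefficients(y)

    def smooth_many(self, Y: np.ndarray) -> np.ndarray:
        """Smooth rows of Y (each a curve on this x grid), GCV per row."""
        Y = np.asarray(Y, dtype=float)
        n = Y.shape[1]
        BtY = self._Bt @ Y.T                       # (m, rows)
        fits = np.empty((len(self._factors), *Y.shape))
        gcvs = np.empty((len(self._factors), Y.shape[0]))
        for i, (fac, edf) in enumerate(zip(self._factors, self._edf)):
            coef = cho_solve(fac, BtY)             # (m, rows)
            fit = (self.B @ coef).T                # (rows, n)
            resid = Y - fit
            denom = max(1.0 - edf / n, 1e-8)
            gcvs[i] = (resid**2).sum(axis=1) / n / denom**2
            fits[i] = fit
        pick = np.argmin(gcvs, axis=0)
        return fits[pick, np.arange(Y.shape[0])]

    def predict(self, y: np.ndarray, x_new: np.ndarray) -> np.ndarray:
        """Smooth y on the training grid, evaluate on x_new."""
        coef = self.fit_coefficients(y)
        return BSpline(self.t, coef, self.k)(np.asarray(x_new, float))


def get_spline(x: np.ndarray) -> GCVSpline:
    """Cached smoother for this x grid."""
    key = np.asarray(x, float).tobytes()
    sp = _CACHE.get(key)
    if sp is None:
        if len(_CACHE) >= _CACHE_MAX:
            _CACHE.clear()
        sp = GCVSpline(np.asarray(x, float))
        _CACHE[key] = sp
    return sp


def gcv_smooth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth y sampled at x; penalty chosen by GCV."""
    return get_spline(x).smooth(y)
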