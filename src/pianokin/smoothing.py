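"""Penalized B-spline smoothing of marker trajectories.

Discrete fingertip height samples are converted into smooth functions whose
velocity (first derivative) and acceleration (second derivative) can be
evaluated anywhere in the sampled interval.  The smoother is a classical
roughness-penalized least-squares spline: order-6 B-splines with knots at
every sample time and a penalty on the integrated squared second derivative,
so that the acceleration curve — the quantity two derivatives away from the
data — is what gets smoothed.  The penalty weight ``lam`` (lambda) is either
supplied or chosen by generalized cross-validation (GCV).

Internally the fit is carried out with time in seconds (heights stay in mm):
at 120 Hz the second-derivative Gram matrix then has O(1e6) entries and tiny
lambdas remain numerically meaningful.  The public API speaks milliseconds;
``evaluate`` returns mm, mm/s and mm/s^2 for derivative orders 0, 1, 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.sparse.linalg import splu

__all__ = ["SmoothedCurve", "fit_smooth", "fit_smooth_multi", "select_lambda_gcv"]

#: default GCV candidate grid for the roughness-penalty weight
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-13.0, -12.0, 5))


@dataclass
class SmoothedCurve:
    """A fitted spline curve h(t) with evaluable derivatives.

    Attributes
    ----------
    order : int
        Spline order (degree + 1); order 6 supports smooth second derivatives.
    knots_s : ndarray
        Full (clamped) knot vector, in seconds.
    coef : ndarray
        B-spline coefficients, mm.
    lam : float
        Roughness-penalty weight used in the fit.
    domain_ms : tuple of float
        Closed interval [start, end] (ms) on which the curve is defined.
    """

    order: int
    knots_s: np.ndarray
    coef: np.ndarray
    lam: float
    domain_ms: tuple[float, float]
    _bspline: BSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._bspline = BSpline(self.knots_s, self.coef, self.order - 1)

    def __call__(self, times_ms, deriv: int = 0):
        return evaluate(self, times_ms, deriv)


def _design_matrix(t_s: np.ndarray, order: int) -> tuple[sparse.csr_matrix, np.ndarray]:
    """B-spline design matrix with knots at every sample time (clamped ends)."""
    k = order - 1
    knots = np.concatenate([np.full(k, t_s[0]), t_s, np.full(k, t_s[-1])])
    X = BSpline.design_matrix(t_s, knots, k)
    return X.tocsr(), knots


def _derivative_operator(knots: np.ndarray, k: int) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Matrix D with (Dc) the coefficients of the derivative spline.

    Maps coefficients of a degree-k spline on ``knots`` to coefficients of
    its degree-(k-1) derivative on ``knots[1:-1]``.
    """
    n = len(knots) - k - 1
    denom = knots[1 + k : n + k] - knots[1:n]  # t[i+k] - t[i], i=1..n-1
    w = k / denom
    rows = np.arange(n - 1)
    D = sparse.csr_matrix(
        (np.concatenate([-w, w]),
         (np.concatenate([rows, rows]), np.concatenate([rows, rows + 1]))),
        shape=(n - 1, n),
    )
    return D, knots[1:-1]


def _penalty_matrix(knots: np.ndarray, order: int) -> sparse.csr_matrix:
    """Gram matrix of second derivatives: P_ij = integral B_i'' B_j'' dt."""
    k = order - 1
    D1, knots1 = _derivative_operator(knots, k)
    D2, knots2 = _derivative_operator(knots1, k - 1)
    D = D2 @ D1
    k2 = k - 2
    # Gauss-Legendre quadrature per knot span; integrand is piecewise
    # polynomial of degree 2*k2, exact with ceil((2*k2+1)/2) points.
    npts = k2 + 1
    gx, gw = np.polynomial.legendre.leggauss(npts)
    breaks = np.unique(knots2)
    lo, hi = breaks[:-1], breaks[1:]
    keep = hi > lo
    lo, hi = lo[keep], hi[keep]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    pts = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    wts = (half[:, None] * gw[None, :]).ravel()
    B2 = BSpline.design_matrix(pts, knots2, k2).tocsr()
    G = (B2.multiply(wts[:, None])).T @ B2
    P = D.T @ G @ D
    return P.tocsc()


def _prepare(times_ms: np.ndarray, order: int):
    t_ms = np.asarray(times_ms, dtype=float)
    if t_ms.ndim != 1 or len(t_ms) < order + 1:
        raise ValueError(f"need at least {order + 1} samples to fit an order-{order} spline")
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("sample times must be strictly increasing")
    t_s = t_ms / 1000.0
    X, knots = _design_matrix(t_s, order)
    P = _penalty_matrix(knots, order)
    return t_s, X, knots, P


def _solve(X, P, lam, Y):
    """Solve the penalized normal equations for one or more columns of data."""
    XtX = (X.T @ X).tocsc()
    if lam > 0:
        A = XtX + lam * P
        lu = splu(A.tocsc())
        coef = lu.solve(X.T @ Y)
    else:
        # unpenalized: with knots at every sample the system is rank deficient;
        # fall back to the minimum-norm least-squares solution
        coef, *_ = np.linalg.lstsq(X.toarray(), Y, rcond=None)
        lu = None
    return coef, XtX, lu


def fit_smooth(samples, order: int = 6, lam: float = 1e-12) -> SmoothedCurve:
    """Fit a roughness-penalized spline to (time_ms, height_mm) samples.

    Parameters
    ----------
    samples : tuple of arrays or (n, 2) array
        Sample times in ms and heights in mm.
    order : int
        Spline order (default 6).
    lam : float
        Penalty weight on the integrated squared second derivative
        (time in seconds); ``lam >= 0``.
    """
    t_ms, y = _unpack_samples(samples)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not np.all(np.isfinite(y)):
        raise ValueError("heights must be finite")
    t_s, X, knots, P = _prepare(t_ms, order)
    coef, _, _ = _solve(X, P, lam, y)
    return SmoothedCurve(order=order, knots_s=knots, coef=coef, lam=lam,
                         domain_ms=(float(t_ms[0]), float(t_ms[-1])))


def fit_smooth_multi(times_ms, Y, order: int = 6, lam: float = 1e-12) -> list[SmoothedCurve]:
    """Fit several series sharing one time grid (one factorization for all)."""
    t_ms = np.asarray(times_ms, float)
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[0] != len(t_ms):
        raise ValueError("Y must be (n_samples, n_series)")
    t_s, X, knots, P = _prepare(t_ms, order)
    coef, _, _ = _solve(X, P, lam, Y)
    dom = (float(t_ms[0]), float(t_ms[-1]))
    return [SmoothedCurve(order=order, knots_s=knots, coef=coef[:, j], lam=lam, domain_ms=dom)
            for j in range(Y.shape[1])]


def _unpack_samples(samples):
    if isinstance(samples, (tuple, list)) and len(samples) == 2:
        t, y = samples
    else:
        arr = np.asarray(samples, float)
        t, y = arr[:, 0], arr[:, 1]
    return np.asarray(t, float), np.asarray(y, float)


def select_lambda_gcv(samples, candidates=None, order: int = 6, full: bool = False):
    """Choose the penalty weight minimizing generalized cross-validation.

    GCV(lam) = n * RSS / (n - tr(H))^2, with H the hat matrix.  For
    multi-column data sharing one grid the per-column GCV scores are averaged
    (the trace depends only on the grid).  Ties within 1e-12 relative score
    break toward the *larger* lambda (the smoother fit).

    Parameters
    ----------
    samples : (times_ms, heights) with heights of shape (n,) or (n, m)
    candidates : iterable of positive floats, default spans 1e-13..1e-12
    full : if True, also return the GCV profile as an array aligned with
        the (sorted ascending) candidate grid.
    """
    t_ms, Y = _unpack_samples(samples)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    if candidates is None:
        candidates = DEFAULT_LAMBDA_GRID
    cands = np.sort(np.asarray(list(candidates), float))
    if len(cands) == 0 or np.any(cands <= 0):
        raise ValueError("candidates must be nonempty and positive")
    t_s, X, knots, P = _prepare(t_ms, order)
    n = len(t_s)
    XtX = (X.T @ X).tocsc()
    XtY = X.T @ Y2
    M = XtX.toarray()
    scores = np.empty(len(cands))
    for i, lam in enumerate(cands):
        A = (XtX + lam * P).tocsc()
        try:
            lu = splu(A)
        except RuntimeError as e:  # pragma: no cover - singular design
            raise ValueError(f"degenerate design at lambda={lam}: {e}") from e
        coef = lu.solve(XtY)
        resid = Y2 - X @ coef
        rss = np.sum(resid**2, axis=0)
        tr_H = float(np.trace(lu.solve(M)))
        denom = n - tr_H
        if denom <= 0:
            scores[i] = np.inf
        else:
            scores[i] = float(np.mean(n * rss / denom**2))
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("degenerate design: GCV undefined for every candidate "
                         "(effective degrees of freedom exhaust the sample)")
    best = np.min(scores[finite])
    # ties toward larger lambda
    ok = finite & (scores <= best * (1 + 1e-12) + 1e-300)
    lam_hat = float(cands[np.nonzero(ok)[0][-1]])
    if full:
        return lam_hat, np.rec.fromarrays([cands, scores], names=["lam", "gcv"])
    return lam_hat


def evaluate(curve: SmoothedCurve, times_ms, deriv: int = 0):
    """Evaluate a smoothed curve or one of its first two derivatives.

    Returns mm for ``deriv=0``, mm/s for 1 and mm/s^2 for 2.  Times outside
    the fitted domain raise ``ValueError`` (no extrapolation).
    """
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    t = np.asarray(times_ms, dtype=float)
    lo, hi = curve.domain_ms
    tol = 1e-9 * max(1.0, abs(hi))
    if np.any(t < lo - tol) or np.any(t > hi + tol):
        raise ValueError(f"evaluation time outside curve domain [{lo}, {hi}] ms")
    t_s = np.clip(t, lo, hi) / 1000.0
    b = curve._bspline if deriv == 0 else curve._bspline.derivative(deriv)
    return b(t_s)
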