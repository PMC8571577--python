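"""Trajectory smoothing, breakpoint detection, and gradient correlation.

Metric trajectories live on an evenly spaced grid of years since
disturbance (5, 7, ..., 29 by default). Three analyses apply to them:

* presentation smoothing with a penalized B-spline (P-spline) whose
  smoothing parameter is chosen by restricted maximum likelihood (REML),
* piecewise-linear breakpoint detection: the series is partitioned into
  up to three segments, each fit by ordinary least squares; for every
  candidate break count the split minimizing the total sum of squared
  errors is found by exhaustive search over the grid, and the break
  count is selected by BIC (pure SSE cannot compare counts — more breaks
  always fit at least as well),
* Spearman rank correlation of per-plot trajectory summaries against
  the disturbance-intensity gradient, with an exact permutation p-value
  for small plot numbers and the t approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline


@dataclass
class TrajectorySeries:
    """One metric's values on the observation grid for one plot."""

    plot_id: str
    times: np.ndarray
    values: np.ndarray
    metric: str = "metric"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        steps = np.diff(self.times)
        if len(steps) and (steps <= 0).any():
            raise ValueError("times must be strictly increasing")
        if len(steps) > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("times must be evenly spaced")
        if np.isnan(self.values).any():
            raise ValueError("missing values in trajectory")


@dataclass
class BreakpointModel:
    """Selected piecewise-linear fit plus every candidate's score."""

    n_breaks: int
    break_times: list[float]
    segments: list[tuple[float, float]]  # (intercept, slope) per segment
    sse: float
    bic: float
    candidates: dict = field(default_factory=dict)  # k -> {sse, bic, break_times}


@dataclass
class SmoothFit:
    """Penalized-spline fit on the observation grid."""

    times: np.ndarray
    fitted: np.ndarray
    lambda_: float
    edf: float


# ---------------------------------------------------------------------------
# P-spline smoothing with REML


def _bspline_design(x: np.ndarray, basis_size: int) -> tuple[np.ndarray, np.ndarray]:
    # uniform (unclamped) cubic B-splines extending past the domain, so the
    # second-difference coefficient penalty leaves exactly the linear functions
    # unpenalized (Eilers-Marx P-spline construction)
    degree = 3
    lo, hi = x.min(), x.max()
    n_intervals = max(basis_size - degree, 1)
    h = (hi - lo) / n_intervals
    knots = lo + h * np.arange(-degree, n_intervals + degree + 1)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return B, knots


def fit_smooth_trajectory(
    s: TrajectorySeries, basis_size: int = 10, criterion: str = "reml"
) -> SmoothFit:
    """Penalized B-spline fit with REML-selected smoothing parameter.

    A cubic B-spline basis with a second-order difference penalty on the
    coefficients leaves straight lines unpenalized, so linear (and
    constant) series are reproduced exactly in the heavy-smoothing
    limit. The smoothing parameter minimizes the Gaussian REML score
    with the residual variance profiled out.
    """
    if criterion.lower() != "reml":
        raise ValueError("only REML selection is implemented")
    t, y = s.times, s.values
    n = len(t)
    if n < 5:
        raise ValueError("need at least 5 points to smooth")
    if basis_size > n:
        warnings.warn(f"basis shrunk from {basis_size} to {n} (too few points)")
        basis_size = n
    basis_size = max(basis_size, 4)
    B, _ = _bspline_design(t, basis_size)
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    eigvals = np.linalg.eigvalsh(P)
    pos = eigvals[eigvals > 1e-10 * eigvals.max()]
    p0 = k - len(pos)  # penalty nullspace dimension (2)
    BtB, Bty = B.T @ B, B.T @ y

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        A = BtB + lam * P
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, Bty)
        rss_pen = float(np.sum((y - B @ beta) ** 2) + lam * beta @ P @ beta)
        sigma2 = max(rss_pen / (n - p0), 1e-300)
        return (n - p0) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_A - np.sum(
            np.log(lam * pos)
        )

    res = optimize.minimize_scalar(neg2_reml, bounds=(-10.0, 20.0), method="bounded")
    lam = float(np.exp(res.x))
    beta = np.linalg.solve(BtB + lam * P, Bty)
    # degenerate data (exactly linear/constant) leave REML flat in the
    # smoothing parameter; prefer the smoothest fit when it loses nothing
    lam_big = np.exp(20.0)
    beta_big = np.linalg.solve(BtB + lam_big * P, Bty)
    rss = float(np.sum((y - B @ beta) ** 2))
    rss_big = float(np.sum((y - B @ beta_big) ** 2))
    if rss_big <= rss + 1e-10 * (1.0 + float(y @ y)):
        lam, beta = lam_big, beta_big
    A = BtB + lam * P
    hat_trace = float(np.trace(np.linalg.solve(A, BtB)))
    return SmoothFit(times=t, fitted=B @ beta, lambda_=lam, edf=hat_trace)


# ---------------------------------------------------------------------------
# Breakpoint detection


def _segment_sse(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line fit of one segment; returns (sse, intercept, slope)."""
    n = len(t)
    if n == 1:
        return 0.0, float(y[0]), 0.0
    tm, ym = t.mean(), y.mean()
    stt = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (y - ym)) / stt) if stt > 0 else 0.0
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    return float(resid @ resid), intercept, slope


def detect_breakpoints(
    s: TrajectorySeries, max_breaks: int = 2, min_seg: int = 3
) -> BreakpointModel:
    """Piecewise-linear breakpoint model by exhaustive SSE minimization.

    For each break count k in {0, ..., max_breaks}, every admissible
    placement (segments of at least ``min_seg`` observations) is scored
    by the summed OLS SSE of its segments; the minimizing placement is
    kept, with ties resolved toward the earliest break times. The break
    count is then chosen by BIC on the segment-wise Gaussian likelihood.
    Break times are reported as the first observation of each new
    segment and lie strictly inside the window by construction.
    """
    t, y = s.times, s.values
    n = len(t)
    if n < (max_breaks + 1) * min_seg:
        raise ValueError(
            f"series of length {n} too short for {max_breaks} breaks with min_seg={min_seg}"
        )
    sse_cache: dict[tuple[int, int], tuple[float, float, float]] = {}

    def seg(i: int, j: int):
        if (i, j) not in sse_cache:
            sse_cache[(i, j)] = _segment_sse(t[i:j], y[i:j])
        return sse_cache[(i, j)]

    candidates = {}
    for k in range(max_breaks + 1):
        best = None
        positions = range(min_seg, n - min_seg + 1)
        for bounds in itertools.combinations(positions, k):
            cuts = (0,) + bounds + (n,)
            if any(b - a < min_seg for a, b in zip(cuts, cuts[1:])):
                continue
            total = sum(seg(a, b)[0] for a, b in zip(cuts, cuts[1:]))
            key = (total, bounds)
            if best is None or total < best[0] - 1e-12 or (
                abs(total - best[0]) <= 1e-12 and bounds < best[1]
            ):
                best = key
        assert best is not None
        sse_k, bounds = best
        n_params = 2 * (k + 1) + k
        bic = n * np.log(max(sse_k, 1e-12) / n) + n_params * np.log(n)
        candidates[k] = {
            "sse": sse_k,
            "bic": float(bic),
            "break_times": [float(t[b]) for b in bounds],
            "bounds": bounds,
        }

    k_best = min(candidates, key=lambda k: (candidates[k]["bic"], k))
    chosen = candidates[k_best]
    cuts = (0,) + chosen["bounds"] + (n,)
    segments = [seg(a, b)[1:] for a, b in zip(cuts, cuts[1:])]
    return BreakpointModel(
        n_breaks=k_best,
        break_times=chosen["break_times"],
        segments=[(float(b0), float(b1)) for b0, b1 in segments],
        sse=chosen["sse"],
        bic=chosen["bic"],
        candidates={
            k: {kk: vv for kk, vv in v.items() if kk != "bounds"} for k, v in candidates.items()
        },
    )


# ---------------------------------------------------------------------------
# Trajectory summaries and gradient correlation


def max_deviation(
    observed: TrajectorySeries, reference
) -> tuple[float, float]:
    """Signed difference of maximal magnitude and the time it occurs.

    ``reference`` is either a TrajectorySeries on the same grid or a
    scalar baseline (e.g. the predisturbance value). Ties are broken
    toward the earliest time.
    """
    if isinstance(reference, TrajectorySeries):
        if not np.array_equal(observed.times, reference.times):
            raise ValueError("time grids differ")
        diff = observed.values - reference.values
    else:
        diff = observed.values - float(reference)
    idx = int(np.argmax(np.abs(diff)))
    return float(diff[idx]), float(observed.times[idx])


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    Mid-ranks handle ties. For fewer than 10 pairs the two-sided p-value
    is computed by full enumeration of permutations of y; from 10 pairs
    on, the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 plots")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if n >= 10:
        return rho, float(p_t)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    sx = np.sqrt(np.sum(rx_c**2))
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.sum(pc[0] ** 2))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate ranks")
    rhos = pc @ rx_c / (sx * sy)
    p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p_exact
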