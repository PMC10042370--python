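"""Local dynamic stability via the local divergence exponent (LDE).

The three lumbar angle channels, time-normalized to 300 samples per cycle, are
delay-embedded into a 6-dimensional state space (one 30-sample delayed copy,
i.e. 10% of the samples per cycle).  For each state, divergence from its 15
nearest neighbors (Euclidean metric, excluding temporally adjacent points
within a Theiler window) is tracked forward in time; the log distances are
averaged over neighbors per reference point and then over reference points.
The LDE is the least-squares slope of that mean log-divergence curve over the
first 0.25 cycle, expressed per cycle (slope per sample x 300).  Higher LDE
means faster divergence, i.e. lower local dynamic stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingConfig",
    "StateSpace",
    "DivergenceCurve",
    "LdsError",
    "resample_for_lde",
    "embed",
    "nearest_neighbors",
    "divergence_curve",
    "fit_divergence_slope",
    "lde",
    "compute_lde",
]

logger = logging.getLogger(__name__)

DISTANCE_FLOOR = 1e-12  # avoid log(0) on coincident states


class LdsError(ValueError):
    """Local-dynamic-stability computation failed."""


@dataclass
class EmbeddingConfig:
    """State-space reconstruction and divergence-tracking parameters.

    Defaults follow the analysis this package implements: 300 samples/cycle,
    delay 30 samples (10% of a cycle), one delayed copy of the 3 channels
    (dimension 6), 15 nearest neighbors, fit over the first 0.25 cycle.
    The Theiler window (half a cycle) and the divergence horizon (one cycle)
    are standard practice for periodic movement data and configurable.
    """

    samples_per_cycle: int = 300
    delay: int = 30
    n_delayed_copies: int = 1
    n_neighbors: int = 15
    fit_fraction: float = 0.25
    theiler_window: int = 150
    horizon: int = 300

    def validate(self) -> None:
        if self.delay < 1:
            raise LdsError("delay must be >= 1")
        if self.n_delayed_copies != 1:
            raise LdsError("only one delayed copy (dimension 6) is supported")
        if self.n_neighbors < 1:
            raise LdsError("n_neighbors must be >= 1")
        if not 0 < self.fit_fraction <= 1:
            raise LdsError("fit_fraction must be in (0, 1]")
        if self.samples_per_cycle < 2 or self.horizon < 1 or self.theiler_window < 0:
            raise LdsError("invalid embedding configuration")

    @property
    def dimension(self) -> int:
        return 3 * (1 + self.n_delayed_copies)


@dataclass
class StateSpace:
    """Reconstructed state space with provenance."""

    points: np.ndarray          # (N, 6)
    source_length: int
    config: EmbeddingConfig


@dataclass
class DivergenceCurve:
    """Mean log divergence at lags 0..horizon."""

    mean_log_divergence: np.ndarray
    n_pairs_per_lag: np.ndarray


def resample_for_lde(angles: np.ndarray, n_cycles: int, samples_per_cycle: int = 300) -> np.ndarray:
    """Cubic-spline resample a (n, 3) angle series to exactly 300 x n_cycles samples.

    Fixing the number of samples removes the dependence of the LDE on trial
    duration and movement speed.
    """
    from scipy.interpolate import CubicSpline

    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 3:
        raise LdsError(f"expected (n, 3) angle series, got {angles.shape}")
    if n_cycles < 1:
        raise LdsError("n_cycles must be >= 1")
    if angles.shape[0] < 4:
        raise LdsError("series too short to resample")
    n_out = samples_per_cycle * n_cycles
    src = np.linspace(0.0, 1.0, angles.shape[0])
    dst = np.linspace(0.0, 1.0, n_out)
    out = np.empty((n_out, 3))
    for axis in range(3):
        out[:, axis] = CubicSpline(src, angles[:, axis])(dst)
    return out


def embed(series: np.ndarray, config: EmbeddingConfig) -> StateSpace:
    """Delay-embed the 3-channel series: row t = (x_t, x_{t+delay})."""
    config.validate()
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise LdsError(f"expected (n, 3) series, got {series.shape}")
    d = config.delay
    if series.shape[0] <= d:
        raise LdsError(f"series length {series.shape[0]} <= delay {d}")
    points = np.hstack([series[:-d], series[d:]])
    return StateSpace(points=points, source_length=series.shape[0], config=config)


def nearest_neighbors(space: StateSpace, config: EmbeddingConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """For each reference point, its ``n_neighbors`` nearest neighbors.

    Euclidean distance, excluding candidates within ``theiler_window`` samples
    in time; ties broken by (distance, index) so results are deterministic and
    reproducible by an exhaustive search.  Reference points with too few
    admissible neighbors are skipped (logged).  Returns (reference indices,
    neighbor index array of shape (n_ref, n_neighbors)).
    """
    config = config or space.config
    X = space.points
    N = X.shape[0]
    k = config.n_neighbors
    w = config.theiler_window
    # enough candidates to survive the Theiler exclusion
    k_query = min(N, k + 2 * w + 1 + k)
    nn = NearestNeighbors(n_neighbors=k_query).fit(X)
    dist, idx = nn.kneighbors(X)
    rows = np.arange(N)[:, None]
    admissible = np.abs(idx - rows) > w
    rank = admissible.cumsum(axis=1)
    take = admissible & (rank <= k)
    complete = take.sum(axis=1) == k
    refs_list, neigh_list = [], []
    if complete.any():
        refs_list.append(np.flatnonzero(complete))
        neigh_list.append(idx[complete][take[complete]].reshape(-1, k))
    # rows whose k_query candidates were exhausted by the exclusion zone:
    # fall back to an exhaustive search before skipping
    for i in np.flatnonzero(~complete):
        d_all = np.linalg.norm(X - X[i], axis=1)
        ok = np.flatnonzero(np.abs(np.arange(N) - i) > w)
        if ok.size < k:
            logger.info("reference %d skipped: %d admissible neighbors", i, ok.size)
            continue
        order = ok[np.lexsort((ok, d_all[ok]))]
        refs_list.append(np.array([i]))
        neigh_list.append(order[:k][None, :])
    if not refs_list:
        raise LdsError("no reference point has enough admissible neighbors")
    refs = np.concatenate(refs_list)
    neigh = np.concatenate(neigh_list, axis=0)
    order = np.argsort(refs, kind="stable")
    return refs[order], neigh[order]


def divergence_curve(space: StateSpace, config: EmbeddingConfig | None = None) -> DivergenceCurve:
    """Track mean log divergence of neighbor pairs over lags 0..horizon.

    Pairs whose forward images run past the series end are dropped per lag;
    distances are floored at ``DISTANCE_FLOOR`` before the log.
    """
    config = config or space.config
    config.validate()
    X = space.points
    N = X.shape[0]
    if N <= config.theiler_window + config.horizon:
        raise LdsError(
            f"state space too short ({N}) for Theiler window "
            f"{config.theiler_window} + horizon {config.horizon}"
        )
    refs, neigh = nearest_neighbors(space, config)
    sum_log, n_refs, n_pairs = _divergence_sums(
        np.ascontiguousarray(X), refs.astype(np.int64), neigh.astype(np.int64),
        config.horizon, DISTANCE_FLOOR,
    )
    with np.errstate(invalid="ignore"):
        mean_log = np.where(n_refs > 0, sum_log / np.maximum(n_refs, 1), np.nan)
    return DivergenceCurve(mean_log_divergence=mean_log, n_pairs_per_lag=n_pairs)


def _divergence_sums_py(X, refs, neigh, horizon, floor):
    """Accumulate per-lag log-distance sums (numpy reference path)."""
    N = X.shape[0]
    sum_log = np.zeros(horizon + 1)
    n_refs = np.zeros(horizon + 1, dtype=np.int64)
    n_pairs = np.zeros(horizon + 1, dtype=np.int64)
    for tau in range(horizon + 1):
        valid_ref = refs + tau < N
        pv = valid_ref[:, None] & (neigh + tau < N)
        pv = pv[valid_ref]
        r = refs[valid_ref]
        nb = neigh[valid_ref]
        diff = X[r + tau][:, None, :] - X[np.minimum(nb + tau, N - 1)]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        logs = np.where(pv, np.log(np.maximum(d, floor)), 0.0)
        cnt = pv.sum(axis=1)
        keep = cnt > 0
        sum_log[tau] = (logs.sum(axis=1)[keep] / cnt[keep]).sum()
        n_refs[tau] = int(keep.sum())
        n_pairs[tau] = int(cnt.sum())
    return sum_log, n_refs, n_pairs


def _divergence_sums_impl(X, refs, neigh, horizon, floor):  # pragma: no cover
    N = X.shape[0]
    dim = X.shape[1]
    n_ref = refs.shape[0]
    k = neigh.shape[1]
    sum_log = np.zeros(horizon + 1)
    n_refs = np.zeros(horizon + 1, dtype=np.int64)
    n_pairs = np.zeros(horizon + 1, dtype=np.int64)
    for i in range(n_ref):
        r = refs[i]
        max_tau = min(horizon, N - 1 - r)
        for tau in range(max_tau + 1):
            acc = 0.0
            cnt = 0
            for j in range(k):
                nb = neigh[i, j] + tau
                if nb < N:
                    s = 0.0
                    for l in range(dim):
                        dd = X[r + tau, l] - X[nb, l]
                        s += dd * dd
                    dist = np.sqrt(s)
                    if dist < floor:
                        dist = floor
                    acc += np.log(dist)
                    cnt += 1
            if cnt > 0:
                sum_log[tau] += acc / cnt
                n_refs[tau] += 1
                n_pairs[tau] += cnt
    return sum_log, n_refs, n_pairs


try:  # numba accelerates the O(pairs x lags) divergence tracking ~5-10x
    from numba import njit

    _divergence_sums = njit(cache=True, fastmath=False)(_divergence_sums_impl)
except ImportError:  # pragma: no cover
    _divergence_sums = _divergence_sums_py


def fit_divergence_slope(curve: DivergenceCurve, config: EmbeddingConfig) -> tuple[float, float]:
    """OLS (slope, intercept) of the curve over lags 0..fit_fraction x cycle, inclusive."""
    n_fit = int(round(config.fit_fraction * config.samples_per_cycle))
    y = curve.mean_log_divergence
    if y.size < n_fit + 1 or not np.isfinite(y[: n_fit + 1]).all():
        raise LdsError(f"divergence curve shorter than fit range ({n_fit + 1} lags)")
    lags = np.arange(n_fit + 1)
    slope, intercept = np.polyfit(lags, y[: n_fit + 1], 1)
    return float(slope), float(intercept)


def lde(curve: DivergenceCurve, config: EmbeddingConfig) -> float:
    """Local divergence exponent: fitted slope expressed per cycle."""
    slope, _ = fit_divergence_slope(curve, config)
    return slope * config.samples_per_cycle


def compute_lde(angles: np.ndarray, n_cycles: int, config: EmbeddingConfig | None = None) -> tuple[float, float, DivergenceCurve]:
    """Convenience chain: resample -> embed -> divergence -> LDE.

    ``angles`` must span exactly the analyzed cycles.  Returns
    (lde_per_cycle, slope_per_sample, divergence curve).
    """
    config = config or EmbeddingConfig()
    series = resample_for_lde(angles, n_cycles, config.samples_per_cycle)
    space = embed(series, config)
    curve = divergence_curve(space, config)
    slope, _ = fit_divergence_slope(curve, config)
    return slope * config.samples_per_cycle, slope, curve
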