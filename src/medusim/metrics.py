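"""Swarm statistics: indication numbers, avoidance/crossing fractions,
velocity-flow correlation, hexatic order, spread, and K-run double averages.

All "fraction" statistics compare the active ensemble against its passive
tracer twin: the twin's ensemble mean of the field defines the reference
threshold W_hat, and the indication number N(W) is the fraction of agents
with W > W_hat (ties count as not exceeding).  The double average smooths
each run's time series with a Gaussian kernel (15 s window, interpreted as
4 sigma, truncated at +-2 sigma) and then averages across the K runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

#: Gaussian smoothing window [s]; total width = 4 sigma
KERNEL_WINDOW_S = 15.0


# ---------------------------------------------------------------------------
# indication numbers and fractions
# ---------------------------------------------------------------------------

def indication_number(values: np.ndarray, threshold: float) -> float:
    """Fraction of agents with W strictly above the threshold W_hat."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty ensemble")
    return float(np.mean(values > threshold))


def turbulence_fraction(active_absC: np.ndarray, passive_absC: np.ndarray) -> float:
    """P(|C|) = N(|C|) / N(|C|_passive), threshold = passive-twin mean |C|.

    Returns NaN (flagged undefined) when no passive tracer exceeds the
    threshold; 0 when all active agents avoid turbulent regions.
    """
    threshold = float(np.mean(passive_absC))
    denom = indication_number(passive_absC, threshold)
    if denom == 0.0:
        return float("nan")
    return indication_number(active_absC, threshold) / denom


def crossing_fraction(active_x: np.ndarray, passive_x: np.ndarray, boundary: float = 0.0) -> float:
    """P(x) = N_0(x) / N_0(x_passive): agents remaining at x > boundary.

    1 when active and passive both remain fully right of the barrier, 0 when
    every active agent crossed; NaN when no passive tracer is right of it.
    """
    denom = indication_number(np.asarray(passive_x), boundary)
    if denom == 0.0:
        return float("nan")
    return indication_number(np.asarray(active_x), boundary) / denom


def baseline_fraction(series: np.ndarray, times: np.ndarray, burn_in: float = 50.0) -> float:
    """Spike-filtered baseline P_min of a fraction time series.

    Discards the first ``burn_in`` seconds, computes the max P_hat and min
    P_tilde of the remainder, and averages only samples with
    P < 0.9 P_tilde + 0.1 P_hat (intermittent spikes are excluded).  Falls
    back to P_tilde when no sample qualifies.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = times >= burn_in
    if not keep.any():
        raise ValueError("series shorter than the burn-in window")
    tail = series[keep]
    tail = tail[np.isfinite(tail)]
    p_hat = tail.max()
    p_tilde = tail.min()
    cutoff = 0.9 * p_tilde + 0.1 * p_hat
    qualifying = tail[tail < cutoff]
    if qualifying.size == 0:
        import warnings

        warnings.warn("no samples below the spike threshold; returning the minimum")
        return float(p_tilde)
    return float(qualifying.mean())


# ---------------------------------------------------------------------------
# correlation, order, spread
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def velocity_correlation(vx, vy, ux, uy) -> float:
    """Corr_V,U = [Corr(vx, Ux) + Corr(vy, Uy)] / 2 across the ensemble.

    NaN (flagged undefined) when any component has zero variance.
    """
    vx, vy, ux, uy = (np.asarray(a, dtype=float) for a in (vx, vy, ux, uy))
    if vx.size < 3:
        raise ValueError("need at least 3 agents")
    return 0.5 * (_pearson(vx, ux) + _pearson(vy, uy))


def hex_order(x: np.ndarray, y: np.ndarray, n_neighbors: int = 6,
              per_agent: bool = False):
    """Bond-orientational (hexatic) order parameter Hex_n in [0, 1].

    Per agent, the modulus of the mean of exp(i 6 delta) over its n nearest
    neighbours (delta the full-quadrant bond angle), then the ensemble mean.
    Exactly 1 on a perfect hexagonal lattice for interior agents with n = 6.
    Duplicate positions are pushed to the back of each other's neighbour
    ranking by an index tie-break inside the KD-tree query.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} agents")
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # generous k: self and exact duplicates are dropped from each row
    k_query = min(n, n_neighbors + 1 + 4)
    dist, idx = tree.query(pts, k=k_query)
    neigh = np.empty((n, n_neighbors), dtype=int)
    for j in range(n):
        row = [k for k, d in zip(idx[j], dist[j]) if k != j and d > 0.0][:n_neighbors]
        if len(row) < n_neighbors:  # many coincident points: fall back to full sort
            d_all = np.hypot(x - x[j], y - y[j])
            order = np.argsort(d_all, kind="stable")
            row = [k for k in order if k != j and d_all[k] > 0.0][:n_neighbors]
        if len(row) < n_neighbors:
            raise ValueError("not enough distinct neighbour positions")
        neigh[j] = row
    delta = np.arctan2(y[neigh] - y[:, None], x[neigh] - x[:, None])
    order = np.abs(np.exp(1j * 6.0 * delta).mean(axis=1))
    if per_agent:
        return order
    return float(order.mean())


def spread(x: np.ndarray, y: np.ndarray, x0: np.ndarray, y0: np.ndarray) -> float:
    """Sigma = var_x(t)/(2 var_x(0)) + var_y(t)/(2 var_y(0)); 1 at t = 0."""
    x, y, x0, y0 = (np.asarray(a, dtype=float) for a in (x, y, x0, y0))
    if x.size < 2 or x0.size < 2:
        raise ValueError("need at least two agents")
    vx0, vy0 = x0.var(), y0.var()
    if vx0 == 0.0 or vy0 == 0.0:
        raise ValueError("zero initial positional variance")
    return float(x.var() / (2 * vx0) + y.var() / (2 * vy0))


def left_gyre_spread(record, t_index: int, boundary: float = 0.0) -> float:
    """Sigma_0: spread of the agents at x < boundary at time t.

    The crossed subset's positional variances are normalised by the full
    ensemble's initial variances (the t = 0 swarm, which starts entirely on
    the other side, is the only common reference).  NaN when fewer than two
    agents have crossed.
    """
    x_t = record["x"][t_index]
    y_t = record["y"][t_index]
    mask = x_t < boundary
    if mask.sum() < 2:
        return float("nan")
    return spread(x_t[mask], y_t[mask], record["x"][0], record["y"][0])


# ---------------------------------------------------------------------------
# K-run double averaging
# ---------------------------------------------------------------------------

@dataclass
class MetricSeries:
    """Per-run metric time series plus the K-run smoothed double average."""

    times: np.ndarray
    per_run: np.ndarray        # (K, T)
    double_avg: np.ndarray     # (T,)


def smooth_series(series: np.ndarray, dt: float, window_s: float = KERNEL_WINDOW_S) -> np.ndarray:
    """Gaussian temporal smoothing; window = 4 sigma, truncated at 2 sigma."""
    sigma = (window_s / 4.0) / dt
    return gaussian_filter1d(np.asarray(series, dtype=float), sigma=sigma,
                             truncate=2.0, mode="nearest", axis=-1)


def double_average(times: np.ndarray, per_run: np.ndarray,
                   window_s: float = KERNEL_WINDOW_S) -> MetricSeries:
    """Smooth each run's series with the Gaussian kernel, then average over runs.

    ``per_run`` has shape (K, T) on a shared time grid (mismatched grids are
    rejected upstream).  A constant series passes through unchanged and K
    identical runs equal a single smoothed run.
    """
    times = np.asarray(times, dtype=float)
    per_run = np.atleast_2d(np.asarray(per_run, dtype=float))
    if per_run.shape[1] != times.size:
        raise ValueError("time grid and series length mismatch")
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    smoothed = smooth_series(per_run, dt, window_s)
    return MetricSeries(times, per_run, smoothed.mean(axis=0))


def delta_series(active: np.ndarray, passive: np.ndarray) -> np.ndarray:
    """Active-minus-passive per-run series for the Delta statistics."""
    return np.asarray(active, dtype=float) - np.asarray(passive, dtype=float)
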