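"""Circular statistics over peak phases.

Peak phases live on a circle of circumference ``period`` (hours); all
statistics here are computed on angles ``theta = 2 pi phi / T`` and
mapped back to hours.  The two-cluster decomposition implements k-means
on the circle with seeded antipodal restarts, the natural tool for the
day/night bimodality of peak-phase distributions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "circular_distance",
    "circular_mean",
    "circular_median",
    "circular_dispersion",
    "circular_sd",
    "phase_clusters",
]


def circular_distance(a, b, period: float):
    """Shortest distance on the circle, in [0, period/2]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def circular_mean(phases, period: float) -> tuple[float, float]:
    """Circular mean direction (hours) and resultant length R in [0, 1].

    The mean is NaN when R is numerically zero (perfectly balanced
    antipodal configurations have no mean direction).
    """
    phi = np.asarray(phases, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phase set")
    theta = 2 * np.pi * phi / period
    C, S = np.cos(theta).mean(), np.sin(theta).mean()
    R = float(np.hypot(C, S))
    if R < 1e-9:
        return float("nan"), R
    mean = np.mod(np.arctan2(S, C) * period / (2 * np.pi), period)
    if period - mean < 1e-9:
        mean = 0.0
    return float(mean), R


def circular_median(phases, period: float) -> float:
    """Data phase minimising the summed circular distances (lowest-value
    tie-break)."""
    phi = np.asarray(phases, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phase set")
    cand = np.sort(np.unique(phi))
    costs = np.array([circular_distance(phi, c, period).sum() for c in cand])
    return float(cand[np.argmin(costs)])


def circular_dispersion(phases, period: float) -> float:
    """Mean circular distance of the phases from their circular mean."""
    mean, R = circular_mean(phases, period)
    if not np.isfinite(mean):
        return float("nan")
    return float(circular_distance(np.asarray(phases, dtype=float), mean, period).mean())


def circular_sd(phases, period: float) -> float:
    """Circular standard deviation ``sqrt(-2 ln R) * T / (2 pi)`` in hours."""
    _, R = circular_mean(phases, period)
    if R < 1e-9:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(min(R, 1.0))) * period / (2 * np.pi))


def phase_clusters(phases, period: float, k: int = 2, n_init: int = 10,
                   seed: int = 0, max_iter: int = 100):
    """k-means on the circle.

    Restarts ``n_init`` times from seeded initialisations: a data phase is
    drawn and the ``k`` centroids placed at equal offsets around the
    circle from it (antipodal for ``k=2``).  Assignment is by circular
    distance, the centroid update is the circular mean, and the best
    restart minimises the within-cluster summed circular distance.  An
    empty cluster triggers re-initialisation (at most 20 attempts).

    Returns ``(labels, centroids_h, circular_sd_h, objective)``.
    """
    phi = np.asarray(phases, dtype=float)
    n = phi.size
    if k > n:
        raise ValueError(f"k={k} exceeds {n} phases")
    if k == 1:
        mean, _ = circular_mean(phi, period)
        if not np.isfinite(mean):
            mean = circular_median(phi, period)
        sd = circular_sd(phi, period)
        return np.zeros(n, dtype=int), np.array([mean]), np.array([sd]), \
            float(circular_distance(phi, mean, period).sum())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    best = None
    for _ in range(n_init):
        centroids = None
        for _attempt in range(20):
            start = phi[rng.integers(0, n)]
            offset = rng.uniform(0, period / k)
            cand = np.mod(start + offset + period * np.arange(k) / k, period)
            labels, centroids, ok = _lloyd(phi, cand, period, max_iter)
            if ok:
                break
        if centroids is None or not ok:
            raise RuntimeError("clustering degenerate: could not fill all clusters")
        obj = sum(circular_distance(phi[labels == j], centroids[j], period).sum()
                  for j in range(k))
        if best is None or obj < best[-1] - 1e-12:
            best = (labels, centroids, obj)
    labels, centroids, obj = best
    sds = np.array([circular_sd(phi[labels == j], period) if np.sum(labels == j) else np.nan
                    for j in range(k)])
    return labels, centroids, sds, float(obj)


def _objective(phi, labels, centroids, period):
    return sum(circular_distance(phi[labels == j], centroids[j], period).sum()
               for j in range(centroids.size))


def _lloyd(phi, centroids, period, max_iter):
    k = centroids.size
    labels = None
    prev_obj = np.inf
    for _ in range(max_iter):
        D = np.stack([circular_distance(phi, c, period) for c in centroids])
        new_labels = np.argmin(D, axis=0)
        if np.any(np.bincount(new_labels, minlength=k) == 0):
            return new_labels, centroids, False
        if labels is not None and np.array_equal(new_labels, labels):
            break
        obj = _objective(phi, new_labels, centroids, period)
        if obj > prev_obj + 1e-12:
            # circular-mean updates do not exactly minimise the summed
            # circular distance; stop rather than let the objective rise
            break
        prev_obj = obj
        labels = new_labels
        updated = []
        for j in range(k):
            m, R = circular_mean(phi[labels == j], period)
            if not np.isfinite(m):
                return labels, centroids, False
            updated.append(m)
        centroids = np.asarray(updated)
    if labels is None:
        labels = np.argmin(np.stack([circular_distance(phi, c, period)
                                     for c in centroids]), axis=0)
        if np.any(np.bincount(labels, minlength=k) == 0):
            return labels, centroids, False
    return labels, centroids, True
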