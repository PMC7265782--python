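"""Affinity propagation by responsibility/availability message passing.

Similarities are negative squared Euclidean distances; the shared preference
(self-similarity) defaults to the median off-diagonal similarity. Messages
are damped and iterated until the exemplar set is stable for ``conv_iter``
consecutive rounds or ``max_iter`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SpecValidationError


@dataclass(frozen=True)
class APClustering:
    labels: np.ndarray  # cluster id per point, 0..k-1
    exemplars: np.ndarray  # point indices, one per cluster
    iterations: int
    converged: bool
    preference: float
    damping: float

    @property
    def k(self) -> int:
        return len(self.exemplars)


def _similarities(points: np.ndarray) -> np.ndarray:
    d = points[:, None, :] - points[None, :, :]
    return -(d**2).sum(axis=-1)


def net_similarity(points: np.ndarray, exemplars, preference: float) -> float:
    """Sum of preferences of exemplars plus best similarity of non-exemplars.

    The quantity affinity propagation maximizes; used by tests as the
    brute-force optimality criterion.
    """
    s = _similarities(np.asarray(points, float))
    exemplars = sorted(set(int(e) for e in exemplars))
    total = preference * len(exemplars)
    for i in range(len(points)):
        if i in exemplars:
            continue
        total += max(s[i, e] for e in exemplars)
    return total


def affinity_propagation(
    points,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 100,
    seed: int = 0,
) -> APClustering:
    """Cluster 2-D (or n-D) points; returns labels and exemplar indices.

    ``preference`` is the shared self-similarity: larger values yield more
    clusters (every point an exemplar in the limit), smaller values fewer.
    A tiny seeded jitter is added to the similarities to break the exact
    degeneracies of symmetric inputs, as is conventional.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n == 0:
        raise SpecValidationError("affinity propagation needs at least 1 point")
    if not 0.5 <= damping < 1.0:
        raise SpecValidationError("damping must be in [0.5, 1)")
    if n == 1:
        pref = 0.0 if preference == "median" else float(preference)
        return APClustering(
            labels=np.zeros(1, dtype=int),
            exemplars=np.array([0]),
            iterations=0,
            converged=True,
            preference=pref,
            damping=damping,
        )
    if np.all(points == points[0]):
        # fully degenerate input: one cluster, first point as exemplar
        pref = 0.0 if preference == "median" else float(preference)
        return APClustering(
            labels=np.zeros(n, dtype=int),
            exemplars=np.array([0]),
            iterations=0,
            converged=True,
            preference=pref,
            damping=damping,
        )
    S = _similarities(points)
    off_diag = S[~np.eye(n, dtype=bool)]
    pref = float(np.median(off_diag)) if preference == "median" else float(preference)
    S = S.copy()
    np.fill_diagonal(S, pref)
    rng = np.random.default_rng(seed)
    scale = max(np.abs(S).max(), 1.0)
    S = S + 1e-10 * scale * rng.standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    exemplars_prev: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = S - first_val[:, None]
        Rnew[idx, first] = S[idx, first] - second_val
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = np.minimum(0, col[None, :] - Rp)
        np.fill_diagonal(Anew, col - Rp.diagonal())
        A = damping * A + (1 - damping) * Anew
        exemplars = np.nonzero((A + R).diagonal() > 0)[0]
        if exemplars_prev is not None and np.array_equal(exemplars, exemplars_prev):
            stable += 1
            if stable >= conv_iter and len(exemplars) > 0:
                converged = True
                break
        else:
            stable = 0
        exemplars_prev = exemplars
    if exemplars_prev is None or len(exemplars_prev) == 0:
        # no point elected itself: fall back to the single best medoid
        exemplars_prev = np.array([int(S.sum(axis=0).argmax())])
    exemplars = exemplars_prev
    # assign points to the most similar exemplar; exemplars label themselves
    assign = S[:, exemplars].argmax(axis=1)
    assign[exemplars] = np.arange(len(exemplars))
    return APClustering(
        labels=assign,
        exemplars=exemplars,
        iterations=it,
        converged=converged,
        preference=pref,
        damping=damping,
    )
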