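"""Internal cluster-validity indices computed from points and labels.

The registry holds the standard set of 42 internal criteria (Ball-Hall,
Banfeld-Raftery, the Baker-Hubert Gamma family, the generalized Dunn family
GDI11..GDI53, variance-ratio and determinant criteria, SD/S_Dbw, silhouette,
and friends), following their textbook definitions. Indices that are
undefined for a given clustering (single cluster, zero-scatter cluster,
singular scatter matrix, ...) are reported as NaN rather than fabricated.

All indices are deterministic functions of (points, labels) and invariant
to translation and rotation of the point set (the determinant/variance
criteria additionally assume a fixed feature basis only up to orthogonal
maps, which distance-based tests exercise).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "INDEX_NAMES",
    "concordance_counts",
    "compute_validity_index",
    "compute_all_indices",
]

_GDI_NAMES = [f"gdi{u}{v}" for u in range(1, 6) for v in range(1, 4)]

#: Canonical registry: the 42 internal criteria, in reporting order.
INDEX_NAMES = (
    [
        "ball_hall",
        "banfeld_raftery",
        "c_index",
        "calinski_harabasz",
        "davies_bouldin",
        "det_ratio",
        "dunn",
        "gamma",
        "g_plus",
    ]
    + _GDI_NAMES
    + [
        "ksq_detw",
        "log_det_ratio",
        "log_ss_ratio",
        "mcclain_rao",
        "pbm",
        "point_biserial",
        "ray_turi",
        "ratkowsky_lance",
        "scott_symons",
        "sd_scat",
        "sd_dis",
        "s_dbw",
        "silhouette",
        "tau",
        "trace_w",
        "trace_wib",
        "wemmert_gancarski",
        "xie_beni",
    ]
)
assert len(INDEX_NAMES) == 42


class _Stats:
    """Shared per-clustering statistics, computed once."""

    def __init__(self, X, labels):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        self.X = X
        self.n, self.p = X.shape
        self.k = len(uniq)
        self.members = [np.nonzero(labels == u)[0] for u in uniq]
        self.sizes = np.array([len(m) for m in self.members])
        self.G = X.mean(axis=0)
        self.Gk = np.stack([X[m].mean(axis=0) for m in self.members])
        self.WGk = [
            (X[m] - self.Gk[i]).T @ (X[m] - self.Gk[i])
            for i, m in enumerate(self.members)
        ]
        self.WG = sum(self.WGk)
        Xc = X - self.G
        self.T = Xc.T @ Xc
        self.BG = self.T - self.WG
        self.WGSSk = np.array([np.trace(W) for W in self.WGk])
        self.WGSS = float(self.WGSSk.sum())
        self.BGSS = float(np.trace(self.BG))
        self.D = squareform(pdist(X)) if self.n > 1 else np.zeros((1, 1))
        lab_idx = np.searchsorted(uniq, labels)
        self.labels = lab_idx
        iu, ju = np.triu_indices(self.n, k=1)
        self.pair_d = self.D[iu, ju]
        self.pair_within = lab_idx[iu] == lab_idx[ju]
        self.d_centroid = np.linalg.norm(
            X - self.Gk[lab_idx], axis=1
        )  # each point to its own barycenter
        self.Dk = squareform(pdist(self.Gk)) if self.k > 1 else np.zeros((1, 1))


def concordance_counts(distances, labels):
    """Concordant/discordant counts between within- and between-pair distances.

    ``distances`` is a condensed pairwise distance vector (as from
    ``scipy.spatial.distance.pdist``); ``labels`` assigns each point to a
    cluster. Returns ``(s_plus, s_minus, n_w, n_b)`` where ``s_plus`` counts
    (within, between) distance pairs with d_within < d_between, ``s_minus``
    those with d_within > d_between, and ``n_w``/``n_b`` the numbers of
    within/between pairs. Requires at least two clusters.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("concordance counts need at least 2 clusters")
    distances = np.asarray(distances, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    if len(distances) != len(iu):
        raise ValueError("condensed distance length does not match labels")
    within = labels[iu] == labels[ju]
    dw = np.sort(distances[within])
    db = np.sort(distances[~within])
    n_w, n_b = len(dw), len(db)
    # for each within distance: how many between distances are strictly
    # larger (concordant) / strictly smaller (discordant)
    s_plus = int((n_b - np.searchsorted(db, dw, side="right")).sum())
    s_minus = int(np.searchsorted(db, dw, side="left").sum())
    return s_plus, s_minus, n_w, n_b


# --------------------------------------------------------------------------
# individual index implementations (st: _Stats)
# --------------------------------------------------------------------------


def _ball_hall(st):
    return float(np.mean(st.WGSSk / st.sizes))


def _banfeld_raftery(st):
    ratio = st.WGSSk / st.sizes
    if np.any(ratio <= 0):
        return np.nan
    return float(np.sum(st.sizes * np.log(ratio)))


def _c_index(st):
    if st.k < 2:
        return np.nan
    sw = float(st.pair_d[st.pair_within].sum())
    nw = int(st.pair_within.sum())
    if nw == 0:
        return np.nan
    d_sorted = np.sort(st.pair_d)
    s_min = float(d_sorted[:nw].sum())
    s_max = float(d_sorted[-nw:].sum())
    if s_max == s_min:
        return np.nan
    return (sw - s_min) / (s_max - s_min)


def _calinski_harabasz(st):
    if st.k < 2 or st.WGSS == 0:
        return np.nan
    return (st.n - st.k) / (st.k - 1) * st.BGSS / st.WGSS


def _davies_bouldin(st):
    if st.k < 2:
        return np.nan
    delta = np.array(
        [st.d_centroid[m].mean() for m in st.members]
    )
    total = 0.0
    for a in range(st.k):
        vals = [
            (delta[a] + delta[b]) / st.Dk[a, b]
            for b in range(st.k)
            if b != a and st.Dk[a, b] > 0
        ]
        if not vals:
            return np.nan
        total += max(vals)
    return total / st.k


def _det_ratio(st):
    det_w = np.linalg.det(st.WG)
    if det_w == 0:
        return np.nan
    return float(np.linalg.det(st.T) / det_w)


def _gamma_counts(st):
    if st.k < 2:
        return None
    iu, ju = np.triu_indices(st.n, k=1)
    return concordance_counts(st.pair_d, st.labels)


def _gamma(st):
    counts = _gamma_counts(st)
    if counts is None:
        return np.nan
    s_plus, s_minus, _, _ = counts
    if s_plus + s_minus == 0:
        return 0.0
    return (s_plus - s_minus) / (s_plus + s_minus)


def _g_plus(st):
    counts = _gamma_counts(st)
    if counts is None:
        return np.nan
    _, s_minus, n_w, n_b = counts
    nt = n_w + n_b
    return 2.0 * s_minus / (nt * (nt - 1))


def _tau(st):
    counts = _gamma_counts(st)
    if counts is None:
        return np.nan
    s_plus, s_minus, n_w, n_b = counts
    nt = n_w + n_b
    m = nt * (nt - 1) / 2.0
    ties = n_w * (n_w - 1) / 2.0 + n_b * (n_b - 1) / 2.0
    denom = np.sqrt((m - ties) * m)
    if denom == 0:
        return np.nan
    return (s_plus - s_minus) / denom


def _between_delta(st, u, a, b):
    ma, mb = st.members[a], st.members[b]
    block = st.D[np.ix_(ma, mb)]
    if u == 1:
        return block.min()
    if u == 2:
        return block.max()
    if u == 3:
        return block.mean()
    if u == 4:
        return st.Dk[a, b]
    # u == 5: mean distance of both clusters' members to their barycenters
    return (st.d_centroid[ma].sum() + st.d_centroid[mb].sum()) / (
        len(ma) + len(mb)
    )


def _within_delta(st, v, a):
    m = st.members[a]
    if v in (1, 2):
        if len(m) < 2:
            return 0.0
        block = st.D[np.ix_(m, m)]
        if v == 1:
            return block.max()
        # half the mean pairwise distance (sum over unordered pairs
        # divided by n_k * (n_k - 1)), per the reference criteria set
        iu, ju = np.triu_indices(len(m), k=1)
        return block[iu, ju].sum() / (len(m) * (len(m) - 1))
    # v == 3: twice the mean distance to the barycenter
    return 2.0 * st.d_centroid[m].mean()


def _gdi(st, u, v):
    if st.k < 2:
        return np.nan
    num = min(
        _between_delta(st, u, a, b)
        for a in range(st.k)
        for b in range(a + 1, st.k)
    )
    den = max(_within_delta(st, v, a) for a in range(st.k))
    if den == 0:
        return np.nan
    return num / den


def _ksq_detw(st):
    return float(st.k**2 * np.linalg.det(st.WG))


def _log_det_ratio(st):
    r = _det_ratio(st)
    if not np.isfinite(r) or r <= 0:
        return np.nan
    return float(st.n * np.log(r))


def _log_ss_ratio(st):
    if st.WGSS == 0 or st.BGSS <= 0:
        return np.nan
    return float(np.log(st.BGSS / st.WGSS))


def _mcclain_rao(st):
    if st.k < 2:
        return np.nan
    within = st.pair_within
    nw, nb = int(within.sum()), int((~within).sum())
    if nw == 0 or nb == 0:
        return np.nan
    mean_w = st.pair_d[within].mean()
    mean_b = st.pair_d[~within].mean()
    if mean_b == 0:
        return np.nan
    return float(mean_w / mean_b)


def _pbm(st):
    if st.k < 2:
        return np.nan
    e_t = float(np.linalg.norm(st.X - st.G, axis=1).sum())
    e_w = float(st.d_centroid.sum())
    if e_w == 0:
        return np.nan
    d_b = st.Dk[np.triu_indices(st.k, k=1)].max()
    return float((e_t * d_b / (e_w * st.k)) ** 2)


def _point_biserial(st):
    if st.k < 2:
        return np.nan
    within = st.pair_within
    nw, nb = int(within.sum()), int((~within).sum())
    nt = nw + nb
    if nw == 0 or nb == 0:
        return np.nan
    mean_w = st.pair_d[within].mean()
    mean_b = st.pair_d[~within].mean()
    return float((mean_w - mean_b) * np.sqrt(nw * nb) / nt)


def _ray_turi(st):
    if st.k < 2:
        return np.nan
    min_d2 = (st.Dk[np.triu_indices(st.k, k=1)] ** 2).min()
    if min_d2 == 0:
        return np.nan
    return float(st.WGSS / st.n / min_d2)


def _ratkowsky_lance(st):
    if st.k < 2:
        return np.nan
    bgss_j = np.diag(st.BG)
    tss_j = np.diag(st.T)
    if np.any(tss_j == 0):
        return np.nan
    cbar2 = float(np.mean(bgss_j / tss_j))
    return float(np.sqrt(cbar2 / st.k))


def _scott_symons(st):
    total = 0.0
    for nk, W in zip(st.sizes, st.WGk):
        det = np.linalg.det(W / nk)
        if det <= 0:
            return np.nan
        total += nk * np.log(det)
    return float(total)


def _var_norms(st):
    """Euclidean norm of the per-variable (biased) variance vectors."""
    overall = np.linalg.norm(st.X.var(axis=0))
    per_cluster = np.array(
        [np.linalg.norm(st.X[m].var(axis=0)) for m in st.members]
    )
    return overall, per_cluster


def _sd_scat(st):
    overall, per_cluster = _var_norms(st)
    if overall == 0:
        return np.nan
    return float(per_cluster.mean() / overall)


def _sd_dis(st):
    if st.k < 2:
        return np.nan
    pairs = st.Dk[np.triu_indices(st.k, k=1)]
    d_max, d_min = pairs.max(), pairs.min()
    if d_min == 0:
        return np.nan
    total = 0.0
    for a in range(st.k):
        s = sum(st.Dk[a, b] for b in range(st.k) if b != a)
        if s == 0:
            return np.nan
        total += 1.0 / s
    return float(d_max / d_min * total)


def _s_dbw(st):
    scat = _sd_scat(st)
    if st.k < 2 or not np.isfinite(scat):
        return np.nan
    _overall, per_cluster = _var_norms(st)
    sigma = np.sqrt(per_cluster.sum()) / st.k

    def density(point, members):
        return int(
            (np.linalg.norm(st.X[members] - point, axis=1) < sigma).sum()
        )

    total = 0.0
    for a in range(st.k):
        for b in range(a + 1, st.k):
            members = np.concatenate([st.members[a], st.members[b]])
            mid = (st.Gk[a] + st.Gk[b]) / 2.0
            denom = max(density(st.Gk[a], members), density(st.Gk[b], members))
            if denom == 0:
                return np.nan
            total += density(mid, members) / denom
    return float(scat + total * 2.0 / (st.k * (st.k - 1)))


def _silhouette(st):
    if st.k < 2:
        return np.nan
    sil = np.zeros(st.n)
    for i in range(st.n):
        own = st.members[st.labels[i]]
        if len(own) < 2:
            sil[i] = 0.0
            continue
        a = st.D[i, own].sum() / (len(own) - 1)
        b = min(
            st.D[i, st.members[c]].mean()
            for c in range(st.k)
            if c != st.labels[i]
        )
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def _trace_w(st):
    return float(st.WGSS)


def _trace_wib(st):
    try:
        return float(np.trace(np.linalg.solve(st.WG, st.BG)))
    except np.linalg.LinAlgError:
        return np.nan


def _wemmert_gancarski(st):
    if st.k < 2:
        return np.nan
    total = 0.0
    for c in range(st.k):
        m = st.members[c]
        others = [d for d in range(st.k) if d != c]
        dist_own = st.d_centroid[m]
        dist_other = np.min(
            np.stack(
                [np.linalg.norm(st.X[m] - st.Gk[d], axis=1) for d in others]
            ),
            axis=0,
        )
        if np.any(dist_other == 0):
            return np.nan
        total += max(0.0, len(m) - float((dist_own / dist_other).sum()))
    return float(total / st.n)


def _xie_beni(st):
    if st.k < 2:
        return np.nan
    min_d = min(
        _between_delta(st, 1, a, b)
        for a in range(st.k)
        for b in range(a + 1, st.k)
    )
    if min_d == 0:
        return np.nan
    return float(st.WGSS / st.n / min_d**2)


_DISPATCH = {
    "ball_hall": _ball_hall,
    "banfeld_raftery": _banfeld_raftery,
    "c_index": _c_index,
    "calinski_harabasz": _calinski_harabasz,
    "davies_bouldin": _davies_bouldin,
    "det_ratio": _det_ratio,
    "dunn": lambda st: _gdi(st, 1, 1),
    "gamma": _gamma,
    "g_plus": _g_plus,
    "ksq_detw": _ksq_detw,
    "log_det_ratio": _log_det_ratio,
    "log_ss_ratio": _log_ss_ratio,
    "mcclain_rao": _mcclain_rao,
    "pbm": _pbm,
    "point_biserial": _point_biserial,
    "ray_turi": _ray_turi,
    "ratkowsky_lance": _ratkowsky_lance,
    "scott_symons": _scott_symons,
    "sd_scat": _sd_scat,
    "sd_dis": _sd_dis,
    "s_dbw": _s_dbw,
    "silhouette": _silhouette,
    "tau": _tau,
    "trace_w": _trace_w,
    "trace_wib": _trace_wib,
    "wemmert_gancarski": _wemmert_gancarski,
    "xie_beni": _xie_beni,
}
for _u in range(1, 6):
    for _v in range(1, 4):
        _DISPATCH[f"gdi{_u}{_v}"] = (
            lambda st, u=_u, v=_v: _gdi(st, u, v)
        )


def compute_validity_index(name: str, points, labels) -> float:
    """Compute one registry index for a clustering; NaN when undefined."""
    if name not in _DISPATCH:
        raise KeyError(f"unknown validity index {name!r}")
    st = _Stats(points, labels)
    return _DISPATCH[name](st)


def compute_all_indices(points, labels) -> dict:
    """All 42 registry indices as an ordered name -> value mapping."""
    st = _Stats(points, labels)
    return {name: _DISPATCH[name](st) for name in INDEX_NAMES}
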