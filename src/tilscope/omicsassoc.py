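"""Subtype assignment, expression/mutation association screens, and
survival stratification (log-rank cutoff scan, K-means risk groups,
Lasso-Cox feature selection).

Statistical conventions: Spearman correlations use exact average ranks;
the mutation screen is a two-sided Wilcoxon rank-sum test (exact for small
groups, normal approximation with tie correction otherwise); the log-rank
test uses the standard hypergeometric variance at each event time; Cox ties
are handled by Breslow's method. No multiple-testing correction is applied
in the cutoff scan by design — outputs carry an optional
Benjamini-Hochberg column as a safety rail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecValidationError

logger = logging.getLogger(__name__)

SUBTYPES = ("ER-positive", "ER-negative", "triple-negative")


# ---------------------------------------------------------------------------
# subtypes
# ---------------------------------------------------------------------------


def assign_subtype(er: str, pr: str, her2: str):
    """Subtype membership from marker statuses ('+', '-', or 'unknown').

    ER+ patients belong to the ER-positive group; ER- patients to the
    ER-negative group, and additionally to the triple-negative group when
    PR and HER2 are also negative (triple-negative is a subgroup of
    ER-negative, not a disjoint label). Unknown ER status excludes the
    patient (returns an empty tuple).
    """
    if er == "+":
        return ("ER-positive",)
    if er == "-":
        if pr == "-" and her2 == "-":
            return ("ER-negative", "triple-negative")
        return ("ER-negative",)
    return ()


def subtype_groups(clinical: pd.DataFrame, disjoint: bool = False) -> dict:
    """Patient-id lists per subtype from a clinical table.

    With ``disjoint=True`` triple-negative patients are removed from the
    ER-negative group (non-overlapping mode).
    """
    groups: dict = {s: [] for s in SUBTYPES}
    excluded = []
    for pid, row in clinical.iterrows():
        memberships = assign_subtype(row["er"], row["pr"], row["her2"])
        if not memberships:
            excluded.append(pid)
            continue
        for m in memberships:
            groups[m].append(pid)
    if disjoint:
        tn = set(groups["triple-negative"])
        groups["ER-negative"] = [p for p in groups["ER-negative"] if p not in tn]
    if excluded:
        logger.info("excluded %d patients with unknown ER status", len(excluded))
    return groups


# ---------------------------------------------------------------------------
# expression screen
# ---------------------------------------------------------------------------


def spearman_screen(
    feature: pd.Series, expression: pd.DataFrame, threshold: float = 0.3
) -> pd.DataFrame:
    """Genes whose Spearman correlation with ``feature`` exceeds ``threshold``
    in absolute value, sorted by |rho| descending (ties by gene symbol).

    ``expression`` is genes x patients; only patients present in both inputs
    are used (at least 3 required). Returns a DataFrame with columns
    ``gene`` and ``rho`` (sign retained).
    """
    common = feature.index.intersection(expression.columns)
    if len(common) < 3:
        raise SpecValidationError("need at least 3 paired observations")
    y = feature.loc[common].to_numpy(dtype=float)
    if np.all(y == y[0]):
        logger.warning("constant feature: all correlations undefined")
        return pd.DataFrame(columns=["gene", "rho"])
    X = expression[common].to_numpy(dtype=float)
    yr = stats.rankdata(y)
    Xr = np.apply_along_axis(stats.rankdata, 1, X)
    yc = yr - yr.mean()
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (Xc @ yc) / denom, np.nan)
    out = pd.DataFrame({"gene": expression.index, "rho": rho})
    out = out[np.abs(out["rho"]) > threshold]
    out = out.sort_values(
        by=["rho", "gene"], key=lambda s: -s.abs() if s.name == "rho" else s
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# mutation screen
# ---------------------------------------------------------------------------


def mutation_test(
    til: pd.Series, mutation: pd.DataFrame, min_mutated: int = 10
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of TIL score by mutation status.

    Genes mutated in fewer than ``min_mutated`` patients are excluded, as
    are genes mutated in every patient (no wild-type group). Returns a
    DataFrame with columns ``gene``, ``n_mut``, ``p``.
    """
    if min_mutated < 1:
        raise SpecValidationError("min_mutated must be >= 1")
    common = til.index.intersection(mutation.columns)
    y = til.loc[common].to_numpy(dtype=float)
    rows = []
    for gene in mutation.index:
        status = mutation.loc[gene, common].to_numpy().astype(bool)
        n_mut = int(status.sum())
        if n_mut < min_mutated:
            continue
        if n_mut == len(common):
            logger.info("gene %s mutated in all patients; skipped", gene)
            continue
        a, b = y[status], y[~status]
        # exact null distribution for small groups without ties; normal
        # approximation with tie correction otherwise
        small = max(len(a), len(b)) <= 25
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if small and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"gene": gene, "n_mut": n_mut, "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["gene", "n_mut", "p"])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalStratification:
    """Two-group stratification with its log-rank statistic."""

    labels: pd.Series  # group label per patient (0/1)
    statistic: float
    p: float
    cutoff: float | None = None
    cutoff_percentile: float | None = None
    scan_table: pd.DataFrame | None = None
    selected_features: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)


def logrank_test(times_a, events_a, times_b, events_b):
    """One-degree-of-freedom log-rank test between two groups.

    Returns ``(chi_square, p)``. At each distinct event time the observed
    number of events in group A is compared with its hypergeometric
    expectation given the numbers at risk; the statistic is
    ``(O - E)^2 / V`` summed over event times.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise SpecValidationError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        return np.nan, np.nan
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & (ea == 1)).sum())
        d_b = int(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d_a - e_a
        var += v
    if var == 0:
        return np.nan, np.nan
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def univariate_cutoff_scan(
    feature: pd.Series,
    time: pd.Series,
    event: pd.Series,
    lo: float = 20.0,
    hi: float = 80.0,
    step: float = 1.0,
    add_bh: bool = True,
) -> SurvivalStratification:
    """Scan percentile cutoffs of ``feature`` and pick the best log-rank split.

    For each cutoff from the ``lo`` to the ``hi`` percentile (``step``
    percentile increments, 61 cutoffs with the defaults) patients are split
    into low (feature <= cutoff) vs high groups and a log-rank test is run.
    The stratification with the smallest p is reported along with the full
    scan table; cutoffs producing an empty group are skipped and cutoffs
    collapsing to the same split are flagged as duplicates.

    No multiple-testing correction is applied to the reported minimum p
    (``flags['multiple_testing']`` says so); a Benjamini-Hochberg column is
    appended to the scan table when ``add_bh`` is true.
    """
    x = feature.to_numpy(dtype=float)
    t = time.loc[feature.index].to_numpy(dtype=float)
    e = event.loc[feature.index].to_numpy(dtype=int)
    if np.all(x == x[0]):
        return SurvivalStratification(
            labels=pd.Series(0, index=feature.index),
            statistic=np.nan,
            p=np.nan,
            flags={"constant_feature": True},
        )
    percentiles = np.arange(lo, hi + step / 2, step)
    rows = []
    seen_splits: dict = {}
    for q in percentiles:
        cut = float(np.percentile(x, q))
        low = x <= cut
        key = low.tobytes()
        duplicate = key in seen_splits
        if low.all() or not low.any():
            rows.append(
                {"percentile": q, "cutoff": cut, "n_low": int(low.sum()),
                 "chi2": np.nan, "p": np.nan, "degenerate": True,
                 "duplicate": duplicate}
            )
            continue
        if duplicate:
            chi2, p = seen_splits[key]
        else:
            chi2, p = logrank_test(t[low], e[low], t[~low], e[~low])
            seen_splits[key] = (chi2, p)
        rows.append(
            {"percentile": q, "cutoff": cut, "n_low": int(low.sum()),
             "chi2": chi2, "p": p, "degenerate": False, "duplicate": duplicate}
        )
    scan = pd.DataFrame(rows)
    if add_bh:
        unique = scan[~scan["duplicate"] & ~scan["degenerate"]]
        bh = pd.Series(np.nan, index=scan.index)
        if len(unique):
            bh.loc[unique.index] = _benjamini_hochberg(unique["p"].to_numpy())
        scan["p_bh"] = bh
    valid = scan[~scan["degenerate"] & scan["p"].notna()]
    if valid.empty:
        return SurvivalStratification(
            labels=pd.Series(0, index=feature.index),
            statistic=np.nan, p=np.nan, scan_table=scan,
            flags={"no_valid_cutoff": True},
        )
    best = valid.loc[valid["p"].idxmin()]
    labels = pd.Series((x > best["cutoff"]).astype(int), index=feature.index)
    return SurvivalStratification(
        labels=labels,
        statistic=float(best["chi2"]),
        p=float(best["p"]),
        cutoff=float(best["cutoff"]),
        cutoff_percentile=float(best["percentile"]),
        scan_table=scan,
        flags={"multiple_testing": "uncorrected minimum over scan"},
    )


def _benjamini_hochberg(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def multivariate_risk_groups(
    features: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    max_retries: int = 5,
) -> SurvivalStratification:
    """K-means patient subgroups on standardized features + log-rank test.

    Features are z-scored; K-means is seeded with restarts. If a cluster is
    degenerate (< 2 patients) the clustering is re-run with a new seed, then
    flagged. For ``k == 2`` the log-rank p compares the two clusters; for
    larger ``k`` the two largest clusters are compared and a flag records it.
    """
    from sklearn.cluster import KMeans

    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    flags = {}
    labels = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        cand = km.fit_predict(Xz)
        if np.min(np.bincount(cand, minlength=k)) >= 2:
            labels = cand
            break
    if labels is None:
        labels = cand
        flags["degenerate_cluster"] = True
    t = time.loc[features.index].to_numpy(dtype=float)
    e = event.loc[features.index].to_numpy(dtype=int)
    sizes = np.bincount(labels, minlength=k)
    if k > 2:
        a, b = np.argsort(sizes)[-2:]
        flags["compared_clusters"] = (int(a), int(b))
    else:
        a, b = 0, 1
    in_a, in_b = labels == a, labels == b
    if in_a.any() and in_b.any():
        chi2, p = logrank_test(t[in_a], e[in_a], t[in_b], e[in_b])
    else:
        chi2, p = np.nan, np.nan
        flags["empty_group"] = True
    return SurvivalStratification(
        labels=pd.Series(labels, index=features.index),
        statistic=chi2,
        p=p,
        flags=flags,
    )


def lasso_cox_select(
    features: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    n_folds: int = 5,
    n_alphas: int = 50,
    seed: int = 0,
    rule: str = "best",  # "best" | "1se"
) -> SurvivalStratification:
    """L1-penalized Cox regression with cross-validated penalty choice.

    Fits the Lasso-Cox path (Breslow ties), picks the penalty maximizing the
    mean held-out log partial likelihood over seeded folds ("best"), or the
    sparsest model within one standard error of it ("1se"), and returns the
    features with nonzero coefficients (signs retained).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    t = time.loc[features.index].to_numpy(dtype=float)
    e = event.loc[features.index].to_numpy(dtype=bool)
    if features.shape[1] < 2:
        raise SpecValidationError("need at least 2 candidate features")
    if e.sum() == 0:
        raise SpecValidationError("no events in the cohort")
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    y = np.empty(len(t), dtype=[("event", bool), ("time", float)])
    y["event"], y["time"] = e, t

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01
    )
    path.fit(Xz, y)
    alphas = path.alphas_

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t))
    folds = np.array_split(order, n_folds)
    cv_ll = np.zeros((n_folds, len(alphas)))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        m.fit(Xz[train_idx], y[train_idx])
        for ai, alpha in enumerate(alphas):
            beta = _coef_at(m, alpha)
            full = _cox_log_partial_likelihood(Xz, t, e, beta)
            train = _cox_log_partial_likelihood(
                Xz[train_idx], t[train_idx], e[train_idx], beta
            )
            cv_ll[fi, ai] = full - train  # held-out contribution (V&VH method)
    mean_ll = cv_ll.mean(axis=0)
    se_ll = cv_ll.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best_i = int(mean_ll.argmax())
    if rule == "1se":
        bar = mean_ll[best_i] - se_ll[best_i]
        # largest penalty (sparsest model) still within 1 SE of the best
        candidates = [i for i in range(len(alphas)) if mean_ll[i] >= bar]
        best_i = min(candidates)  # alphas_ are sorted descending
    alpha = alphas[best_i]
    beta = _coef_at(path, alpha)
    coef = beta / sd  # back to the original feature scale
    nz = np.nonzero(beta != 0)[0]
    selected = pd.DataFrame(
        {
            "feature": features.columns[nz],
            "coefficient": coef[nz],
            "sign": np.sign(coef[nz]).astype(int),
        }
    ).sort_values("coefficient", key=np.abs, ascending=False).reset_index(drop=True)
    risk = Xz @ beta
    labels = pd.Series((risk > np.median(risk)).astype(int), index=features.index)
    if labels.nunique() == 2:
        chi2, p = logrank_test(
            t[labels == 0], e[labels == 0].astype(int),
            t[labels == 1], e[labels == 1].astype(int),
        )
    else:
        chi2, p = np.nan, np.nan
    return SurvivalStratification(
        labels=labels,
        statistic=chi2,
        p=p,
        selected_features=selected,
        flags={"alpha": float(alpha), "rule": rule, "ties": "breslow"},
    )


def _coef_at(model, alpha):
    """Coefficients at the path point closest to ``alpha``."""
    alphas = np.asarray(model.alphas_)
    i = int(np.argmin(np.abs(alphas - alpha)))
    return model.coef_[:, i]


def _cox_log_partial_likelihood(X, t, e, beta):
    """Breslow log partial likelihood at coefficients ``beta``."""
    eta = X @ beta
    order = np.argsort(-t)  # descending time
    eta_o = eta[order]
    t_o = t[order]
    e_o = e[order]
    log_cumsum = np.logaddexp.accumulate(eta_o)
    # risk set at time t_i: all with t >= t_i; with descending order this is
    # the prefix. Handle ties by using the last index with the same time.
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_cumsum[j]
        for idx in range(i, j + 1):
            if e_o[idx]:
                ll += eta_o[idx] - denom
        i = j + 1
    return ll
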