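from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tilscope.errors import SpecValidationError
from tilscope.omicsassoc import (
    assign_subtype,
    lasso_cox_select,
    logrank_test,
    multivariate_risk_groups,
    mutation_test,
    spearman_screen,
    subtype_groups,
    univariate_cutoff_scan,
)


class TestAssignSubtype:
    def test_er_positive(self):
        assert assign_subtype("+", "+", "-") == ("ER-positive",)

    def test_triple_negative_dual_membership(self):
        assert assign_subtype("-", "-", "-") == ("ER-negative", "triple-negative")

    def test_er_negative_only(self):
        assert assign_subtype("-", "+", "+") == ("ER-negative",)

    def test_unknown_er_excluded(self):
        assert assign_subtype("unknown", "-", "-") == ()

    def test_groups_overlap_and_disjoint_modes(self):
        clinical = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "er": ["+", "-", "-"],
                "pr": ["-", "-", "+"],
                "her2": ["-", "-", "-"],
            }
        ).set_index("patient_id", drop=False)
        g = subtype_groups(clinical)
        assert g["ER-negative"] == ["b", "c"]
        assert g["triple-negative"] == ["b"]
        gd = subtype_groups(clinical, disjoint=True)
        assert gd["ER-negative"] == ["c"]


class TestSpearmanScreen:
    def _cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        feature = pd.Series(rng.normal(size=n),
                            index=[f"p{i}" for i in range(n)])
        return feature

    def test_identical_gene_rho_one(self):
        f = self._cohort()
        expr = pd.DataFrame([f.to_numpy()], index=["SAME"], columns=f.index)
        out = spearman_screen(f, expr)
        assert out.iloc[0]["gene"] == "SAME"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_negated_gene_rho_minus_one_sign_retained(self):
        f = self._cohort()
        expr = pd.DataFrame([-f.to_numpy()], index=["NEG"], columns=f.index)
        out = spearman_screen(f, expr)
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_matches_scipy_exact_ranks_with_ties(self):
        rng = np.random.default_rng(1)
        f = pd.Series(rng.integers(0, 5, size=30).astype(float),
                      index=[f"p{i}" for i in range(30)])
        expr = pd.DataFrame(
            rng.integers(0, 4, size=(8, 30)).astype(float),
            index=[f"G{i}" for i in range(8)], columns=f.index,
        )
        out = spearman_screen(f, expr, threshold=-1.0)
        for _, row in out.iterrows():
            ref = stats.spearmanr(expr.loc[row["gene"]], f).statistic
            assert row["rho"] == pytest.approx(ref, abs=1e-12)

    def test_constant_feature_warns_empty(self):
        f = pd.Series(np.ones(10), index=[f"p{i}" for i in range(10)])
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)),
                            index=list("ABC"), columns=f.index)
        out = spearman_screen(f, expr)
        assert out.empty

    def test_sorting_by_abs_rho_then_symbol(self):
        f = self._cohort(n=50, seed=2)
        vals = f.to_numpy()
        expr = pd.DataFrame(np.stack([vals, -vals, vals]),
                            index=["B", "A", "C"], columns=f.index)
        out = spearman_screen(f, expr)
        assert list(out["gene"]) == ["A", "B", "C"]  # |rho|=1 ties by symbol

    def test_too_few_observations(self):
        f = pd.Series([1.0, 2.0], index=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["a", "b"])
        with pytest.raises(SpecValidationError):
            spearman_screen(f, expr)


class TestMutationTest:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        til = pd.Series(rng.random(n), index=[f"p{i}" for i in range(n)])
        return rng, til

    def test_filter_excludes_below_min(self):
        rng, til = self._setup()
        status = np.zeros(len(til), dtype=int)
        status[:9] = 1  # 9 mutated patients
        mut = pd.DataFrame([status], index=["G9"], columns=til.index)
        assert mutation_test(til, mut, min_mutated=10).empty

    def test_exact_small_sample_p(self):
        # 10 mutated all greater than 10 wild-type: the most extreme table;
        # two-sided exact p = 2 / C(20, 10)
        til = pd.Series(np.r_[np.arange(10, 20), np.arange(10)].astype(float),
                        index=[f"p{i}" for i in range(20)])
        status = np.r_[np.ones(10, int), np.zeros(10, int)]
        mut = pd.DataFrame([status], index=["G"], columns=til.index)
        out = mutation_test(til, mut, min_mutated=10)
        from math import comb

        assert out.iloc[0]["p"] == pytest.approx(2 / comb(20, 10))

    def test_all_mutated_skipped(self):
        _, til = self._setup(n=15)
        mut = pd.DataFrame([np.ones(15, int)], index=["ALL"], columns=til.index)
        assert mutation_test(til, mut, min_mutated=10).empty

    def test_null_p_uniform(self):
        # permuted labels: p-values should be uniform on (0, 1)
        rng = np.random.default_rng(3)
        n = 60
        til = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        ps = []
        for _ in range(500):
            status = np.zeros(n, int)
            status[rng.choice(n, 15, replace=False)] = 1
            mut = pd.DataFrame([status], index=["G"], columns=til.index)
            ps.append(mutation_test(til, mut, min_mutated=10).iloc[0]["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_min_mutated_validation(self):
        _, til = self._setup()
        with pytest.raises(SpecValidationError):
            mutation_test(til, pd.DataFrame(), min_mutated=0)


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_patients(self):
        # group A: times 1, 2 (events); group B: times 3, 4 (events)
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        # hand computation over event times 1, 2, 3:
        # t=1: nA=2, nB=2, d=1, eA=1/2, v=(1*2*2*3)/(16*3)=1/4
        # t=2: nA=1, nB=2, d=1, eA=1/3, v=2/9
        # t=3: nA=0, nB=2, d=1, eA=0, v=0
        # t=4: single subject left -> variance 0 contribution (n=1 skipped)
        o_minus_e = (1 - 0.5) + (1 - 1 / 3) + (0 - 0)
        var = 0.25 + 2 / 9
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_matches_closed_form_exhaustive_small(self):
        # all instances with <= 6 patients: compare with an independent
        # per-event-time table computed in this test
        rng = np.random.default_rng(0)
        for _ in range(60):
            na = int(rng.integers(1, 4))
            nb = int(rng.integers(1, 4))
            ta = rng.integers(1, 5, na).astype(float)
            tb = rng.integers(1, 5, nb).astype(float)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, _p = logrank_test(ta, ea, tb, eb)
            ref = _oracle_logrank(ta, ea, tb, eb)
            if ref is None:
                assert np.isnan(chi2)
            else:
                assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_no_events_flagged(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(chi2) and np.isnan(p)

    def test_empty_group_rejected(self):
        with pytest.raises(SpecValidationError):
            logrank_test([], [], [1], [1])

    def test_null_type_i_error(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = rng.exponential(10, size=100)
            e = (rng.random(100) < 0.8).astype(int)
            chi2, p = logrank_test(t[:50], e[:50], t[50:], e[50:])
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.03


def _oracle_logrank(ta, ea, tb, eb):
    times = sorted(set(np.concatenate([ta[ea == 1], tb[eb == 1]])))
    o_e, var = 0.0, 0.0
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n, d = na + nb, da + db
        if n < 2:
            continue
        o_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return None
    return o_e**2 / var


class TestCutoffScan:
    def _survival(self, n=200, seed=0, threshold_pct=None, hr=3.0):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        if threshold_pct is None:
            rate = np.full(n, 0.1)
        else:
            cut = np.percentile(x, threshold_pct)
            rate = np.where(x > cut, 0.1 * hr, 0.1)
        t = pd.Series(rng.exponential(1 / rate), index=x.index)
        e = pd.Series(np.ones(n, dtype=int), index=x.index)
        return x, t, e

    def test_scan_has_61_rows(self):
        x, t, e = self._survival()
        strat = univariate_cutoff_scan(x, t, e)
        assert len(strat.scan_table) == 61
        assert strat.flags["multiple_testing"]

    def test_min_p_equals_scan_table_min(self):
        x, t, e = self._survival(seed=3)
        strat = univariate_cutoff_scan(x, t, e)
        valid = strat.scan_table[~strat.scan_table["degenerate"]]
        assert strat.p == pytest.approx(valid["p"].min())

    def test_planted_threshold_recovered(self):
        hits = 0
        for seed in range(6):
            x, t, e = self._survival(seed=seed, threshold_pct=40, hr=3.0)
            strat = univariate_cutoff_scan(x, t, e)
            if abs(strat.cutoff_percentile - 40) <= 5:
                hits += 1
        assert hits >= 5

    def test_small_cohort_duplicates_flagged(self):
        x, t, e = self._survival(n=10, seed=1)
        strat = univariate_cutoff_scan(x, t, e)
        dup = strat.scan_table["duplicate"]
        assert dup.sum() > 0  # 61 cutoffs on 10 points must collapse
        unique_rows = (~dup).sum()
        assert unique_rows <= 10

    def test_constant_feature_flagged(self):
        n = 30
        x = pd.Series(np.ones(n), index=[f"p{i}" for i in range(n)])
        t = pd.Series(np.arange(1, n + 1, dtype=float), index=x.index)
        e = pd.Series(np.ones(n, dtype=int), index=x.index)
        strat = univariate_cutoff_scan(x, t, e)
        assert strat.flags.get("constant_feature")


class TestMultivariate:
    def _blobs(self, n=120, seed=0, separated=True, hr=4.0):
        rng = np.random.default_rng(seed)
        half = n // 2
        if separated:
            X = np.vstack([rng.normal(0, 1, (half, 4)),
                           rng.normal(6, 1, (n - half, 4))])
        else:
            X = rng.normal(size=(n, 4))
        risk = np.r_[np.zeros(half), np.ones(n - half)]
        rate = 0.05 * hr**risk if separated else np.full(n, 0.05)
        t = rng.exponential(1 / rate)
        idx = [f"p{i}" for i in range(n)]
        return (pd.DataFrame(X, index=idx),
                pd.Series(t, index=idx),
                pd.Series(np.ones(n, dtype=int), index=idx))

    def test_separated_blobs_recovered(self):
        X, t, e = self._blobs(separated=True)
        strat = multivariate_risk_groups(X, t, e, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 60 + [1] * 60
        assert adjusted_rand_score(truth, strat.labels) >= 0.9
        assert strat.p < 0.05

    def test_null_features_usually_nonsignificant(self):
        ps = []
        for seed in range(10):
            X, t, e = self._blobs(n=200, seed=seed, separated=False)
            strat = multivariate_risk_groups(X, t, e, seed=seed)
            ps.append(strat.p)
        assert np.median(ps) > 0.05

    def test_duplication_scale_invariance(self):
        X, t, e = self._blobs(n=60, seed=2)
        X2 = pd.concat([X, X])
        X2.index = [f"q{i}" for i in range(len(X2))]
        t2 = pd.Series(np.tile(t.to_numpy(), 2), index=X2.index)
        e2 = pd.Series(np.tile(e.to_numpy(), 2), index=X2.index)
        s1 = multivariate_risk_groups(X, t, e, seed=0)
        s2 = multivariate_risk_groups(X2, t2, e2, seed=0)
        a = s1.labels.to_numpy()
        b = s2.labels.to_numpy()[: len(a)]
        agreement = max((a == b).mean(), (a == 1 - b).mean())
        assert agreement == 1.0


class TestLassoCox:
    def _cohort(self, n=300, seed=0, effect=True):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{j}" for j in range(6)], index=idx)
        if effect:
            rate = 0.05 * np.exp(1.0 * X["f0"])
        else:
            rate = np.full(n, 0.05)
        t = pd.Series(rng.exponential(1 / rate), index=idx)
        e = pd.Series(np.ones(n, dtype=int), index=idx)
        return X, t, e

    def test_planted_feature_selected_with_sign(self):
        X, t, e = self._cohort(seed=1)
        res = lasso_cox_select(X, t, e, seed=0)
        sel = res.selected_features.set_index("feature")
        assert "f0" in sel.index
        assert sel.loc["f0", "sign"] == 1
        assert abs(sel.loc["f0", "coefficient"]) == sel["coefficient"].abs().max()

    def test_null_sparse_at_1se(self):
        n_selected = []
        for seed in range(5):
            X, t, e = self._cohort(seed=seed, effect=False)
            res = lasso_cox_select(X, t, e, seed=seed, rule="1se")
            n_selected.append(len(res.selected_features))
        assert np.median(n_selected) <= 1

    def test_duplicate_column_at_most_one(self):
        X, t, e = self._cohort(seed=3)
        X = X.copy()
        X["f0_dup"] = X["f0"]
        res = lasso_cox_select(X, t, e, seed=0, rule="1se")
        sel = set(res.selected_features["feature"])
        assert not ({"f0", "f0_dup"} <= sel)

    def test_no_events_rejected(self):
        X, t, e = self._cohort(n=50)
        with pytest.raises(SpecValidationError):
            lasso_cox_select(X, t, pd.Series(0, index=e.index), seed=0)
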