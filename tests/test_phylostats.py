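"""Permutation tests, PGLS, and classical statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylometab import divergence as dv
from phylometab import phylostats as ps
from phylometab import synthetic_data as sd
from phylometab import treeio
from phylometab.normalize import ProfileTable, SampleTable
from phylometab.phylostats import MantelResult, PermutationResult


def sym_matrix(rng, labels, low=0.0, high=1.0, kind="divergence"):
    n = len(labels)
    M = np.triu(rng.uniform(low, high, (n, n)), 1)
    return dv.DistanceMatrix(list(labels), M + M.T, kind)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        X = sym_matrix(rng, list("abcde"))
        res = ps.mantel_test(X, X, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_direct_pearson(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = list("abcdef")
            X = sym_matrix(rng, labels)
            Y = sym_matrix(rng, labels)
            res = ps.mantel_test(X, Y, n_permutations=9, seed=0)
            iu = np.triu_indices(6, 1)
            expect = stats.pearsonr(X.values[iu], Y.values[iu]).statistic
            assert res.r == pytest.approx(expect, abs=1e-12)

    def test_exhaustive_null_equivalence_five_labels(self):
        # Monte-Carlo p converges to the full 5! = 120 permutation enumeration
        rng = np.random.default_rng(2)
        labels = list("abcde")
        X = sym_matrix(rng, labels)
        Y = sym_matrix(rng, labels)
        iu = np.triu_indices(5, 1)
        x = X.values[iu]
        r_obs = stats.pearsonr(x, Y.values[iu]).statistic
        exceed = 0
        perms = list(itertools.permutations(range(5)))
        for perm in perms:
            perm = np.asarray(perm)
            yp = Y.values[perm[iu[0]], perm[iu[1]]]
            if stats.pearsonr(x, yp).statistic >= r_obs - 1e-15:
                exceed += 1
        p_exact = exceed / len(perms)
        B = 10_000
        res = ps.mantel_test(X, Y, n_permutations=B, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.p_value - p_exact) < 3 * se + 2 / B

    def test_p_floor(self):
        rng = np.random.default_rng(3)
        X = sym_matrix(rng, list("abcdef"))
        res = ps.mantel_test(X, X, n_permutations=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_constant_matrix_rejected(self):
        labels = list("abcd")
        C = dv.DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="constant"):
            ps.mantel_test(C, sym_matrix(rng, labels), n_permutations=9, seed=0)

    def test_phylogenetic_scheme_reproducible_and_tagged(self):
        tree = sd.simulate_tree(6, seed=9)
        labels = tree.tip_labels
        _, P = treeio.patristic_distance_matrix(tree, labels)
        pat = dv.DistanceMatrix(labels, P, "patristic")
        rng = np.random.default_rng(5)
        X = sym_matrix(rng, labels)
        a = ps.mantel_test(X, pat, n_permutations=500, scheme="phylogenetic",
                           tree=tree, seed=11)
        b = ps.mantel_test(X, pat, n_permutations=500, scheme="phylogenetic",
                           tree=tree, seed=11)
        assert a.scheme == "phylogenetic"
        assert a.p_value == b.p_value
        assert a.r == pytest.approx(b.r)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            ps.mantel_test(sym_matrix(rng, list("abc")),
                           sym_matrix(rng, list("abd")), n_permutations=9)


class TestGroupRatio:
    def test_equal_divergences_give_p_one(self):
        labels = list("abcdef")
        D = dv.DistanceMatrix(labels, np.ones((6, 6)) - np.eye(6))
        groups = {l: ("g1" if i < 3 else "g2") for i, l in enumerate(labels)}
        res = ps.group_ratio_permutation_test(D, groups, n_permutations=199, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_addone_pvalue_rule(self):
        res = PermutationResult(observed=2.0, n_permutations=99, exceed_count=0,
                                p_value=1 / 100, seed=0)
        assert res.p_value == 0.01
        with pytest.raises(ValueError):
            PermutationResult(observed=2.0, n_permutations=99, exceed_count=0,
                              p_value=0.5, seed=0)

    def test_exhaustive_null_equivalence_six_labels(self):
        # 6 labels split 3+3: only C(6,3) = 20 distinct assignments
        rng = np.random.default_rng(7)
        labels = list("abcdef")
        D = sym_matrix(rng, labels)
        groups = {l: ("g1" if i < 3 else "g2") for i, l in enumerate(labels)}

        def folded(members):
            m = np.array([l in members for l in labels])
            iu = np.triu_indices(6, 1)
            within1 = D.values[iu][(m[iu[0]]) & (m[iu[1]])].mean()
            within2 = D.values[iu][(~m[iu[0]]) & (~m[iu[1]])].mean()
            return max(within1 / within2, within2 / within1)

        obs = folded(set("abc"))
        all_assignments = list(itertools.combinations(labels, 3))
        p_exact = np.mean([folded(set(c)) >= obs - 1e-15 for c in all_assignments])
        B = 10_000
        res = ps.group_ratio_permutation_test(D, groups, n_permutations=B, seed=8)
        assert res.observed == pytest.approx(obs)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.p_value - p_exact) < 3 * se + 2 / B

    def test_pair_filter_restricts_and_resamples(self):
        rng = np.random.default_rng(9)
        labels = [f"p{i}" for i in range(8)]
        D = sym_matrix(rng, labels)
        groups = {l: ("g1" if i < 4 else "g2") for i, l in enumerate(labels)}
        eligible = [("p0", "p1"), ("p2", "p3"), ("p4", "p5"), ("p6", "p7")]
        res = ps.group_ratio_permutation_test(
            D, groups, n_permutations=999, seed=10, eligible_pairs=eligible)
        assert res.p_value >= 1 / 1000
        # observed statistic uses only the eligible pairs
        m1 = np.mean([D.loc("p0", "p1"), D.loc("p2", "p3")])
        m2 = np.mean([D.loc("p4", "p5"), D.loc("p6", "p7")])
        assert res.observed == pytest.approx(max(m1 / m2, m2 / m1))

    def test_requires_two_groups(self):
        rng = np.random.default_rng(11)
        labels = list("abcd")
        D = sym_matrix(rng, labels)
        with pytest.raises(ValueError, match="two groups"):
            ps.group_ratio_permutation_test(D, {l: "g1" for l in labels},
                                            n_permutations=9)


class TestAnovaPerMetabolite:
    def _table(self, rows, pops):
        names = [f"s{i}_r1" for i in range(len(rows))]
        data = pd.DataFrame(np.exp(np.asarray(rows, dtype=float)), index=names)
        data.columns = [f"m{i}" for i in range(data.shape[1])]
        meta = pd.DataFrame(
            {"strain": [f"s{i}" for i in range(len(rows))], "population": pops,
             "species": "sp", "group": "wild", "od_inoc": 0.1, "od_samp": 0.5,
             "od_stat": 1.0, "batch": 1, "is_qc": False}, index=names)
        return SampleTable(data=data, meta=meta)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(12)
        rows = rng.standard_normal((12, 3)).tolist()
        pops = ["A"] * 6 + ["B"] * 6
        table = self._table(rows, pops)
        out = ps.oneway_anova_per_metabolite(table)
        logged = np.log(table.data)
        for m in logged.columns:
            t = stats.ttest_ind(logged[m][:6], logged[m][6:], equal_var=True)
            assert out.loc[m, "F"] == pytest.approx(t.statistic**2, abs=1e-9)
            assert out.loc[m, "p"] == pytest.approx(t.pvalue, abs=1e-9)

    def test_effect_monotonicity(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal(12)
        rows = [[v] for v in base]
        pops = ["A"] * 6 + ["B"] * 6
        f0 = ps.oneway_anova_per_metabolite(self._table(rows, pops)).loc["m0", "F"]
        shifted = [[v + (3.0 if i >= 6 else 0.0)] for i, v in enumerate(base)]
        f1 = ps.oneway_anova_per_metabolite(self._table(shifted, pops)).loc["m0", "F"]
        assert f1 > f0

    def test_null_p_uniformity(self):
        # KS check that null p-values are U(0,1)
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(1000):
            a = rng.standard_normal(5)
            b = rng.standard_normal(5)
            c = rng.standard_normal(5)
            pvals.append(stats.f_oneway(a, b, c).pvalue)
        # sanity of the oracle itself, then of our wrapper on a subsample
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        wrapper_pvals = []
        for i in range(200):
            rows = rng.standard_normal((9, 1)).tolist()
            table = self._table(rows, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
            wrapper_pvals.append(ps.oneway_anova_per_metabolite(table).loc["m0", "p"])
        assert stats.kstest(wrapper_pvals, "uniform").pvalue > 0.01

    def test_flat_metabolite_flagged(self):
        rows = [[0.0, float(i)] for i in range(6)]
        table = self._table(rows, ["A"] * 3 + ["B"] * 3)
        out = ps.oneway_anova_per_metabolite(table)
        assert out.loc["m0", "undefined"]
        assert not out.loc["m1", "undefined"]


class TestBartlett:
    @staticmethod
    def bartlett_oracle(groups):
        # textbook formula: chi2 = [(N-k) ln Sp2 - sum (ni-1) ln Si2] / C
        k = len(groups)
        ni = np.array([len(g) for g in groups])
        N = ni.sum()
        si2 = np.array([np.var(g, ddof=1) for g in groups])
        sp2 = np.sum((ni - 1) * si2) / (N - k)
        C = 1 + (np.sum(1 / (ni - 1)) - 1 / (N - k)) / (3 * (k - 1))
        chi2 = ((N - k) * np.log(sp2) - np.sum((ni - 1) * np.log(si2))) / C
        return chi2, stats.chi2.sf(chi2, k - 1)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(rng.standard_normal((10, 4)) * [1, 2, 0.5, 3],
                             columns=list("wxyz"))
        chi2, p = ps.bartlett_test(table)
        chi2_o, p_o = self.bartlett_oracle([table[c].to_numpy() for c in table])
        assert chi2 == pytest.approx(chi2_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(500):
            table = pd.DataFrame(rng.standard_normal((8, 3)))
            pvals.append(ps.bartlett_test(table)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_hundredfold_variance_ratio(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            table = pd.DataFrame({
                "a": rng.standard_normal(20),
                "b": 10.0 * rng.standard_normal(20),
            })
            hits += ps.bartlett_test(table)[1] < 0.001
        assert hits / n_sim >= 0.99

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            ps.bartlett_test(table)


class TestPGLS:
    def test_star_tree_reduces_to_ols(self):
        rng = np.random.default_rng(18)
        n = 10
        y = pd.Series(rng.standard_normal(n), index=[f"t{i}" for i in range(n)])
        x = pd.DataFrame({"g": rng.integers(0, 2, n).astype(float)}, index=y.index)
        V = 2.5 * np.eye(n)
        fit = ps.pgls_anova(y, x, V)
        X = np.column_stack([np.ones(n), x["g"]])
        beta_ols = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        assert fit.params["estimate"].to_numpy() == pytest.approx(beta_ols, abs=1e-9)

    def test_three_tip_matrix_oracle(self):
        # explicit (X' V^-1 X)^-1 X' V^-1 y on a hand-built case
        y = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        x = pd.DataFrame({"g": [0.0, 0.0, 1.0]}, index=list("abc"))
        V = np.array([[2.0, 1.0, 0.0], [1.0, 3.0, 0.0], [0.0, 0.0, 4.0]])
        fit = ps.pgls_anova(y, x, V)
        X = np.column_stack([np.ones(3), x["g"]])
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y.to_numpy()
        assert fit.params["estimate"].to_numpy() == pytest.approx(beta, abs=1e-9)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(19)
        tree = sd.simulate_tree(12, seed=4)
        labels, V = treeio.brownian_covariance(tree)
        y = pd.Series(rng.standard_normal(12), index=labels)
        x = pd.DataFrame({"g": rng.integers(0, 2, 12).astype(float),
                          "c": rng.standard_normal(12)}, index=labels)
        fit = ps.pgls_anova(y, x, V)
        X = sm.add_constant(x.to_numpy())
        ref = sm.GLS(y.to_numpy(), X, sigma=V).fit()
        assert fit.params["estimate"].to_numpy() == pytest.approx(ref.params, abs=1e-9)
        assert fit.params["se"].to_numpy() == pytest.approx(ref.bse, abs=1e-9)
        assert fit.params["p"].to_numpy() == pytest.approx(ref.pvalues, abs=1e-9)

    def test_confidence_interval_coverage(self):
        # 95% CI for a planted group effect covers it ~95% of the time
        tree = sd.simulate_tree(17, seed=6)
        labels, V = treeio.brownian_covariance(tree)
        delta = 1.0
        x = pd.DataFrame({"g": [float(i < 7) for i in range(17)]}, index=labels)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(20)
        n_sim, covered = 2000, 0
        tcrit = stats.t.ppf(0.975, 15)
        for _ in range(n_sim):
            y = pd.Series(L @ rng.standard_normal(17) + delta * x["g"].to_numpy(),
                          index=labels)
            fit = ps.pgls_anova(y, x, V)
            est, se = fit.coef("g")["estimate"], fit.coef("g")["se"]
            covered += abs(est - delta) <= tcrit * se
        assert 0.93 <= covered / n_sim <= 0.97

    def test_singular_covariance_jitter_warning(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        x = pd.DataFrame({"g": [0.0, 0.0, 1.0, 1.0]}, index=list("abcd"))
        V = np.ones((4, 4))  # rank 1
        with pytest.warns(UserWarning, match="ridge"):
            fit = ps.pgls_anova(y, x, V)
        assert np.isfinite(fit.params["estimate"]).all()

    def test_rank_deficient_design_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        x = pd.DataFrame({"g": [1.0, 1.0, 1.0]}, index=list("abc"))  # = intercept
        with pytest.raises(ValueError, match="rank"):
            ps.pgls_anova(y, x, np.eye(3))


class TestSignatureScan:
    def test_planted_shift_detected_with_sign(self, small_dataset):
        from phylometab import normalize as nz

        prof, _ = nz.normalize_pipeline(small_dataset.targeted, "targeted",
                                        level="population")
        scan = ps.domestication_signature_scan(
            prof, small_dataset.tree, small_dataset.truth.groups)
        planted = {t: s for t, s in small_dataset.truth.shift_traits.items()
                   if t in scan.index}
        detected = scan.index[scan["significant"]]
        hits = [t for t in planted
                if t in detected and np.sign(planted[t]) == scan.loc[t, "sign"]]
        assert len(hits) >= 0.5 * len(planted)  # strong signal, loose unit bound

    def test_exclusion_leaves_other_profiles_untouched(self, small_dataset):
        from phylometab import normalize as nz

        prof, _ = nz.normalize_pipeline(small_dataset.targeted, "targeted",
                                        level="population")
        before = prof.levels.copy()
        excluded = prof.labels[0]
        ps.domestication_signature_scan(
            prof, small_dataset.tree, small_dataset.truth.groups,
            exclude=[excluded])
        pd.testing.assert_frame_equal(prof.levels, before)

    def test_covariate_changes_design_not_data(self, small_dataset):
        from phylometab import normalize as nz

        prof, _ = nz.normalize_pipeline(small_dataset.targeted, "targeted",
                                        level="population")
        cov = pd.Series(np.linspace(0, 1, len(prof.labels)), index=prof.labels)
        scan_a = ps.domestication_signature_scan(
            prof, small_dataset.tree, small_dataset.truth.groups)
        scan_b = ps.domestication_signature_scan(
            prof, small_dataset.tree, small_dataset.truth.groups, covariate=cov)
        assert not scan_a["p"].equals(scan_b["p"])


class TestFisherOverlap:
    def test_brute_force_hypergeometric(self):
        universe = set(range(19))
        a = set(range(7))
        b = {0, 1, 2, 8, 9}
        odds, p = ps.fisher_exact_overlap(a, b, universe)
        # enumerate all tables with the same margins
        n, K, k_draw = len(universe), len(a), len(b)
        obs = len(a & b)
        probs = {x: stats.hypergeom.pmf(x, n, K, k_draw)
                 for x in range(max(0, K + k_draw - n), min(K, k_draw) + 1)}
        p_obs = probs[obs]
        p_brute = sum(v for v in probs.values() if v <= p_obs + 1e-12)
        assert p == pytest.approx(p_brute, abs=1e-12)

    def test_symmetry(self):
        universe = set(range(30))
        a = set(range(10))
        b = set(range(5, 20))
        assert ps.fisher_exact_overlap(a, b, universe)[1] == pytest.approx(
            ps.fisher_exact_overlap(b, a, universe)[1], abs=1e-12)

    def test_disjoint_cover_boundary(self):
        universe = {1, 2, 3, 4}
        odds, p = ps.fisher_exact_overlap({1, 2}, {3, 4}, universe)
        assert odds == 0.0
        assert 0 < p <= 1

    def test_stray_elements_rejected(self):
        with pytest.raises(ValueError):
            ps.fisher_exact_overlap({1, 99}, {2}, {1, 2, 3})
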