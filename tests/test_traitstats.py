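"""Community and comparative statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from microdiv import phylo, simdata, traitstats
from microdiv.util import rng_for


def random_dist(n, seed, dim=4):
    rng = rng_for(seed, "dist")
    X = rng.normal(size=(n, dim))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(squareform(pdist(X)), index=labels, columns=labels)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        X = pd.DataFrame([[1, 2, 3], [1, 2, 3], [0, 0, 5]],
                         index=["a", "b", "c"], columns=list("xyz"))
        d, s = traitstats.bray_curtis(X)
        assert d.loc["a", "b"] == 0.0
        assert s.loc["a", "b"] == 1.0
        X2 = pd.DataFrame([[1, 0], [0, 3]], index=["a", "b"], columns=["x", "y"])
        d2, _ = traitstats.bray_curtis(X2)
        assert d2.loc["a", "b"] == 1.0

    def test_hand_computed_case(self):
        X = pd.DataFrame([[1, 2, 0], [0, 2, 4]], index=["a", "b"], columns=list("xyz"))
        d, _ = traitstats.bray_curtis(X)
        assert d.loc["a", "b"] == pytest.approx(5 / 9)

    def test_matches_scipy_and_stays_in_unit_interval(self):
        rng = rng_for(0, "bc")
        X = pd.DataFrame(rng.random((6, 5)) + 0.01)
        d, _ = traitstats.bray_curtis(X)
        ref = squareform(pdist(X.to_numpy(), metric="braycurtis"))
        assert np.allclose(d.to_numpy(), ref, atol=1e-12)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 1).all()

    def test_all_zero_sample_rejected(self):
        X = pd.DataFrame([[1, 1], [0, 0]])
        with pytest.raises(ValueError):
            traitstats.bray_curtis(X)


def one_factor_pseudo_f(D, labels):
    """Independent pseudo-F oracle for a one-factor PERMANOVA."""
    n = D.shape[0]
    G = traitstats._gower(D)
    X = traitstats._effect_code(pd.Series(labels))
    Xf = np.hstack([np.ones((n, 1)), X])
    H = Xf @ np.linalg.pinv(Xf)
    Hr = np.ones((n, n)) / n
    sst = np.trace(G)
    ssm = (G * H).sum() - (G * Hr).sum()
    ssr = sst - (G * H).sum()
    k = X.shape[1]
    return (ssm / k) / (ssr / (n - 1 - k))


class TestPermanova:
    def test_degenerate_zero_distances(self):
        labels = [f"s{i}" for i in range(6)]
        D = pd.DataFrame(np.zeros((6, 6)), index=labels, columns=labels)
        design = pd.DataFrame({"sample_id": labels, "treatment": ["a", "b"] * 3,
                               "date": ["d1"] * 3 + ["d2"] * 3})
        res = traitstats.permanova(D, design, n_perm=19, seed=0)
        assert res.degenerate
        assert (res.table.loc[["treatment", "date"], "p"] == 1.0).all()

    def test_exhaustive_matches_enumeration_oracle(self):
        D = random_dist(6, seed=3)
        labels = ["x"] * 3 + ["y"] * 3
        design = pd.DataFrame({"sample_id": D.index, "g": labels})
        res = traitstats.permanova(D, design, factors=("g",), exhaustive=True)
        F_obs = one_factor_pseudo_f(D.to_numpy(), labels)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            lab = ["y"] * 6
            for i in combo:
                lab[i] = "x"
            total += 1
            if one_factor_pseudo_f(D.to_numpy(), lab) >= F_obs - 1e-12:
                count += 1
        assert res.table.loc["g", "p"] == pytest.approx(count / total, abs=1e-12)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(F_obs)

    def test_ss_decomposition_on_balanced_designs(self):
        rng = rng_for(4, "ssdesign")
        for trial in range(30):
            a_lev = int(rng.integers(2, 4))
            b_lev = int(rng.integers(2, 4))
            reps = int(rng.integers(1, 3))
            n = a_lev * b_lev * reps
            labels = [f"s{i}" for i in range(n)]
            rows = [(f"a{i}", f"b{j}") for i in range(a_lev) for j in range(b_lev)
                    for _ in range(reps)]
            design = pd.DataFrame({"sample_id": labels,
                                   "treatment": [r[0] for r in rows],
                                   "date": [r[1] for r in rows]})
            D = random_dist(n, seed=100 + trial)
            res = traitstats.permanova(D, design, n_perm=9, seed=trial)
            tab = res.table
            total = tab.loc["Total", "SS"]
            parts = tab.loc[["treatment", "date", "Residual"], "SS"].sum()
            assert abs(parts - total) < 1e-9 * max(1.0, total)

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_sims = 100
        for sim in range(n_sims):
            D = random_dist(12, seed=2000 + sim)
            rng = rng_for(sim, "labels")
            labels = rng.permutation(["x"] * 6 + ["y"] * 6)
            design = pd.DataFrame({"sample_id": D.index, "g": labels})
            res = traitstats.permanova(D, design, factors=("g",), n_perm=199,
                                       seed=sim)
            if res.table.loc["g", "p"] <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_sims <= 0.10

    def test_confounded_design_rejected(self):
        D = random_dist(6, seed=5)
        design = pd.DataFrame({"sample_id": D.index,
                               "treatment": ["a", "a", "a", "b", "b", "b"],
                               "date": ["d1", "d1", "d1", "d2", "d2", "d2"]})
        with pytest.raises(ValueError, match="confound|alias"):
            traitstats.permanova(D, design, n_perm=9)

    def test_seed_reproducibility(self):
        D = random_dist(10, seed=6)
        design = pd.DataFrame({"sample_id": D.index, "g": ["x", "y"] * 5})
        p1 = traitstats.permanova(D, design, factors=("g",), seed=42).table.loc["g", "p"]
        p2 = traitstats.permanova(D, design, factors=("g",), seed=42).table.loc["g", "p"]
        assert p1 == p2


class TestMantel:
    def test_identity_gives_rho_one_minimal_p(self):
        D = random_dist(7, seed=7)
        res = traitstats.mantel_relate(D, D, n_perm=99, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exhaustive_matches_enumeration_at_n5(self):
        A = random_dist(5, seed=8)
        B = random_dist(5, seed=9)
        res = traitstats.mantel_relate(A, B, exhaustive=True)
        iu = np.triu_indices(5, k=1)
        a = A.to_numpy()[iu]
        rho_obs = stats.spearmanr(a, B.to_numpy()[iu]).statistic
        count = total = 0
        for perm in itertools.permutations(range(5)):
            bp = B.to_numpy()[np.ix_(perm, perm)][iu]
            total += 1
            if stats.spearmanr(a, bp).statistic >= rho_obs - 1e-12:
                count += 1
        assert total == 120
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        D = random_dist(6, seed=10)
        res = traitstats.mantel_relate(D, D ** 2 + 0.3 * D, n_perm=49, seed=2)
        assert res.rho == pytest.approx(1.0)

    def test_constant_matrix_flagged(self):
        other = random_dist(4, seed=11)
        D = pd.DataFrame(1.0 - np.eye(4), index=other.index, columns=other.columns)
        res = traitstats.mantel_relate(D, other, n_perm=9)
        assert not res.defined


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        res = traitstats.anova_tukey([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = rng_for(12, "anova")
        x = rng.normal(size=8)
        g = ["a"] * 4 + ["b"] * 4
        res = traitstats.anova_tukey(x, g)
        t = stats.ttest_ind(x[:4], x[4:]).statistic
        assert res.F == pytest.approx(t ** 2, rel=1e-12)

    def test_cross_implementation_oracle(self):
        rng = rng_for(13, "anova-x")
        x = rng.normal(size=15) + np.repeat([0.0, 1.0, 0.5], 5)
        g = np.repeat(list("abc"), 5)
        res = traitstats.anova_tukey(x, g)
        ref = stats.f_oneway(x[:5], x[5:10], x[10:])
        assert res.F == pytest.approx(ref.statistic, abs=1e-6)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-6)
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        tk = sm.pairwise_tukeyhsd(x, g)
        ours = res.tukey.set_index(["group_a", "group_b"])["p_adj"]
        for (ga, gb), padj in zip(zip(tk.groupsunique[tk._multicomp.pairindices[0]],
                                      tk.groupsunique[tk._multicomp.pairindices[1]]),
                                  tk.pvalues):
            assert ours.loc[(ga, gb)] == pytest.approx(padj, abs=1e-6)

    def test_tukey_never_more_significant_than_t(self):
        rng = rng_for(14, "tukey-mono")
        x = rng.normal(size=12) + np.repeat([0, 0.5, 2.0], 4)
        g = np.repeat(list("abc"), 4)
        res = traitstats.anova_tukey(x, g)
        msw = None
        for row in res.tukey.itertuples():
            xa, xb = x[g == row.group_a], x[g == row.group_b]
            p_t = stats.ttest_ind(xa, xb).pvalue
            assert row.p_adj >= p_t - 1e-9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            traitstats.anova_tukey([1.0, 2.0], ["a", "a"])


class TestPic:
    def test_two_leaf_closed_form(self):
        t = phylo.parse_newick("(A:1,B:1);")
        cs = traitstats.pic(t, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2), abs=1e-12)

    def test_four_leaf_hand_recursion(self):
        # balanced tree, unit branches, traits (4,2,8,6): contrasts
        # +-sqrt(2), +-sqrt(2), +-4/sqrt(3) with variances (2, 2, 3)
        t = phylo.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cs = traitstats.pic(t, {"A": 4.0, "B": 2.0, "C": 8.0, "D": 6.0})
        got = sorted(np.abs(cs.contrasts))
        want = sorted([np.sqrt(2), np.sqrt(2), 4 / np.sqrt(3)])
        assert np.allclose(got, want, atol=1e-9)
        assert sorted(cs.variances) == pytest.approx([2.0, 2.0, 3.0])

    def test_contrast_count_is_leaves_minus_one(self):
        t = phylo.parse_newick("(((A:1,B:2):1,C:3):1,(D:1,E:1):2);")
        cs = traitstats.pic(t, {k: float(i) for i, k in enumerate("ABCDE")})
        assert len(cs.contrasts) == 4

    def test_polytomy_rejected_with_guidance(self):
        t = phylo.parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytomy"):
            traitstats.pic(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_brownian_contrasts_are_zero_mean(self):
        tree = phylo.parse_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);")
        fails = 0
        for seed in range(200):
            vals = simdata.brownian_on_tree(tree, 1.0, rng_for(seed, "picbm"))
            cs = traitstats.pic(tree, vals)
            if stats.ttest_1samp(cs.contrasts, 0.0).pvalue < 0.01:
                fails += 1
        assert fails / 200 <= 0.05

    def test_regression_through_origin(self):
        rng = rng_for(15, "picreg")
        cx = rng.normal(size=15)
        cy = 2.0 * cx + rng.normal(scale=0.1, size=15)
        slope, F, p = traitstats.pic_regression(cx, cy)
        assert slope == pytest.approx(2.0, abs=0.1)
        assert p < 1e-6
        # F has (1, n-1) df: check against statsmodels no-intercept OLS
        import statsmodels.api as smapi

        fit = smapi.OLS(cy, cx[:, None]).fit()
        assert F == pytest.approx(fit.fvalue, rel=1e-9)


class TestAncovaBackward:
    def _simulate(self, seed, interaction=False):
        rng = rng_for(seed, "ancova")
        rows = []
        clade_eff = {"IA": 0.0, "IB": 2.0, "III": 4.0}
        for clade in clade_eff:
            for temp in ("22", "37"):
                for substrate in ("cellulose", "xylan"):
                    for rep in range(3):
                        mu = 10.0 + clade_eff[clade] + (1.5 if temp == "37" else 0.0)
                        if interaction:
                            # one clade rises sharply at 37, one collapses
                            if clade == "IA" and temp == "37":
                                mu += 6.0
                            if clade == "III" and temp == "37":
                                mu -= 12.0
                        rows.append({"area": float(rng.normal(mu, 1.0)),
                                     "temperature": temp, "clade": clade,
                                     "substrate": substrate})
        return pd.DataFrame(rows)

    def test_no_interaction_data_reduces_to_main_effects(self):
        # under the null each of the 4 interaction terms survives with
        # probability ~alpha, so P(main effects only) ~ 0.95^4 ~ 0.81;
        # require at least the 3-sigma binomial lower bound of that
        n_seeds = 60
        kept_main_only = 0
        for seed in range(n_seeds):
            table = traitstats.ancova_backward(self._simulate(seed))
            inter = [t for t in table.index if ":" in t]
            if not inter:
                kept_main_only += 1
        p = 0.95 ** 4
        lower = n_seeds * p - 3 * np.sqrt(n_seeds * p * (1 - p))
        assert kept_main_only >= lower

    def test_temperature_clade_interaction_detected(self):
        kept = 0
        for seed in range(60):
            table = traitstats.ancova_backward(self._simulate(seed, interaction=True))
            if "C(temperature):C(clade)" in table.index:
                kept += 1
        assert kept >= 0.9 * 60

    def test_single_factor_reduces_to_one_way_anova(self):
        rng = rng_for(16, "ancova-1f")
        df = pd.DataFrame({"area": rng.normal(size=12) + np.repeat([0, 1, 3], 4),
                           "clade": np.repeat(["IA", "IB", "III"], 4)})
        table = traitstats.ancova_backward(df, factors=("clade",))
        ref = traitstats.anova_tukey(df["area"], df["clade"])
        assert table.loc["C(clade)", "F"] == pytest.approx(ref.F, rel=1e-9)
        assert table.loc["C(clade)", "p"] == pytest.approx(ref.p, rel=1e-9)
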