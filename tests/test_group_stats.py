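"""Group statistics: epsilon, split-plot ANCOVA, one-way ANCOVA, moderation, FDR."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from surrsupp.group_stats import (
    ancova_oneway,
    bic_bayes_factor,
    hf_epsilon,
    moderation_test,
    orthonormal_contrasts,
    pairwise_fdr,
    rm_ancova_hf,
)


def long_format(y, groups, z, conditions=None):
    n, k = y.shape
    conditions = conditions or [f"c{j}" for j in range(k)]
    return pd.DataFrame({
        "observer_id": np.repeat([f"s{i}" for i in range(n)], k),
        "group": np.repeat(groups, k),
        "logmar": np.repeat(z, k),
        "condition": np.tile(conditions, n),
        "estimate": y.ravel(),
    })


class TestHfEpsilon:
    def test_compound_symmetry_gives_one(self):
        s = 2.0 * ((1 - 0.3) * np.eye(3) + 0.3 * np.ones((3, 3)))
        assert hf_epsilon(s, n=30, g=1) == 1.0

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        # all variance on a single contrast -> maximal nonsphericity
        c = orthonormal_contrasts(3)[:, [0]]
        s = c @ c.T
        assert hf_epsilon(s, n=30, g=1) == pytest.approx(0.5)

    def test_clipped_to_half_for_three_levels(self, rng):
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            s = a @ a.T
            eps = hf_epsilon(s, n=25, g=5)
            assert 0.5 <= eps <= 1.0

    def test_matches_independent_formula(self, rng):
        for _ in range(20):
            a = rng.normal(size=(4, 4))
            s = a @ a.T
            n, g = 40, 2
            k = 4
            # independent step-by-step evaluation
            c = orthonormal_contrasts(k)
            sc = c.T @ s @ c
            lam = np.linalg.eigvalsh(sc)
            gg = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
            hf = ((n - g + 1) * (k - 1) * gg - 2) / ((k - 1) * (n - g - (k - 1) * gg))
            expected = min(1.0, max(1.0 / (k - 1), hf))
            assert hf_epsilon(s, n=n, g=g) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_single_group(self, rng):
        y = rng.normal(size=(40, 3)) + rng.normal(size=(40, 1))
        s = np.cov(y, rowvar=False)
        ours = hf_epsilon(s, n=40, g=1)
        theirs = float(pg.epsilon(pd.DataFrame(y), correction="hf"))
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            hf_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]), n=10)


class TestRmAncova:
    def test_matches_pingouin_mixed_anova_without_covariate(self, rng):
        n, k = 40, 3
        groups = np.repeat(["A", "B", "C", "D"], 10)
        y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 0.8
        long = long_format(y, groups, np.zeros(n))
        ours = rm_ancova_hf(long, covariate=None)
        theirs = pg.mixed_anova(data=long, dv="estimate", within="condition",
                                subject="observer_id", between="group")
        for effect, src in [("group", "group"), ("condition", "condition"),
                            ("group:condition", "Interaction")]:
            f_ours = ours.row(effect)["F"]
            f_theirs = float(theirs.loc[theirs["Source"] == src, "F"].iloc[0])
            assert f_ours == pytest.approx(f_theirs, rel=1e-8)

    def test_covariate_df_accounting(self, rng):
        # one covariate costs one between-subjects error df
        n, k = 30, 3
        groups = np.repeat(["A", "B", "C"], 10)
        y = rng.normal(size=(n, k))
        z = rng.normal(size=n)
        with_cov = rm_ancova_hf(long_format(y, groups, z))
        without = rm_ancova_hf(long_format(y, groups, z), covariate=None)
        assert with_cov.row("group")["df2"] == without.row("group")["df2"] - 1

    def test_epsilon_in_bounds(self, rng):
        n, k = 24, 3
        groups = np.repeat(["A", "B"], 12)
        y = rng.normal(size=(n, k)) * np.array([3.0, 1.0, 0.2])
        res = rm_ancova_hf(long_format(y, groups, rng.normal(size=n)))
        assert 0.5 <= res.epsilon <= 1.0

    def test_condition_effect_power(self, rng):
        # a -15 pp shift of one condition, noise sd 5: condition effect should
        # be overwhelming in nearly every replicate
        hits = 0
        for _ in range(100):
            n = 40
            groups = np.repeat(["A", "B"], 20)
            y = rng.normal(0, 5, size=(n, 3))
            y[:, 0] -= 15.0
            res = rm_ancova_hf(long_format(y, groups, rng.normal(size=n)))
            hits += res.row("condition")["p"] < 0.001
        assert hits > 95

    def test_single_group_rejected(self, rng):
        y = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            rm_ancova_hf(long_format(y, ["A"] * 10, np.zeros(10)))


class TestAncovaOneway:
    def test_matches_pingouin(self, rng):
        y = rng.normal(size=50)
        groups = list(np.repeat(["A", "B", "C", "D", "E"], 10))
        z = rng.normal(size=50) + 0.3 * y
        ours = ancova_oneway(y, groups, z)
        theirs = pg.ancova(data=pd.DataFrame({"y": y, "g": groups, "z": z}),
                           dv="y", between="g", covar="z")
        f_theirs = float(theirs.loc[theirs["Source"] == "g", "F"].iloc[0])
        np2 = float(theirs.loc[theirs["Source"] == "g", "np2"].iloc[0])
        assert ours.row("group")["F"] == pytest.approx(f_theirs, rel=1e-8)
        assert ours.row("group")["partial_eta_sq"] == pytest.approx(np2, rel=1e-6)

    def test_translation_invariance(self, rng):
        y = rng.normal(size=40)
        groups = list(np.repeat(["A", "B", "C", "D"], 10))
        z = rng.normal(size=40)
        a = ancova_oneway(y, groups, z)
        b = ancova_oneway(y + 100.0, groups, z)
        assert a.row("group")["F"] == pytest.approx(b.row("group")["F"], rel=1e-9)

    def test_covariate_absorption_null_calibration(self):
        # y is a pure function of the covariate; group labels random:
        # group p-values should be uniform
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            z = rng.normal(size=40)
            y = 2.0 * z
            groups = list(rng.choice(["A", "B", "C", "D"], size=40))
            if min(groups.count(g) for g in set(groups)) < 2:
                continue
            pvals.append(ancova_oneway(y + rng.normal(0, 0.5, 40), groups, z)
                         .row("group")["p"])
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_group_shift_detected_at_study_sizes(self):
        # +5 pp offset in one of five groups, noise sd 3, cohort sizes as in
        # the study: detection in > 80% of replicates
        rng = np.random.default_rng(17)
        sizes = {"PSZ": 31, "PBD": 29, "HC": 29, "PSZrel": 28, "PBDrel": 21}
        groups = [g for g, s in sizes.items() for _ in range(s)]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0, 3, size=len(groups))
            y[:31] += 5.0  # PSZ shift
            z = rng.normal(0.1, 0.12, size=len(groups))
            hits += ancova_oneway(y, groups, z).row("group")["p"] < 0.05
        assert hits / n_rep > 0.8

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            ancova_oneway(rng.normal(size=10), ["A"] * 10, None)
        with pytest.raises(ValueError):
            ancova_oneway(np.array([1.0, 2.0, 3.0]), ["A", "A", "B"], None)


class TestModeration:
    def test_interaction_df_is_groups_minus_one(self, rng):
        n = 50
        groups = list(np.repeat(["a", "b", "c", "d", "e"], 10))
        res = moderation_test(rng.normal(size=n), groups, rng.normal(size=n))
        assert res.table["df1"].iloc[0] == 4.0
        assert res.table["df2"].iloc[0] == n - 10  # 2g parameters

    def test_single_group_slope_detected(self):
        # acuity slope of 30 pp per logMAR unit confined to one group
        rng = np.random.default_rng(23)
        n_rep, hits = 200, 0
        groups = list(np.repeat(["a", "b", "c", "d", "e"], 20))
        for _ in range(n_rep):
            z = rng.normal(0.1, 0.12, size=100)
            y = rng.normal(0, 3, size=100)
            y[:20] += 30.0 * z[:20]
            res = moderation_test(y, groups, z)
            hits += res.table["p"].iloc[0] < 0.05
        assert hits / n_rep > 0.8

    def test_subgroup_split_reported(self, rng):
        n = 40
        groups = list(np.repeat(["a", "b"], 20))
        z = np.concatenate([np.full(10, 0.0), np.full(10, 0.3)] * 2)
        z = z + rng.normal(0, 0.01, n)
        res = moderation_test(rng.normal(size=n), groups, z)
        assert set(res.subgroup_means["acuity"]) == {"good", "poor"}
        assert res.subgroup_means["count"].sum() == n

    def test_no_acuity_variance_rejected(self, rng):
        groups = ["a"] * 10 + ["b"] * 10
        z = np.concatenate([np.zeros(10), rng.normal(size=10)])
        with pytest.raises(ValueError):
            moderation_test(rng.normal(size=20), groups, z)


class TestPairwiseFdr:
    def test_bh_hand_example(self, rng):
        # raw p {0.01, 0.02, 0.03} -> all adjusted to 0.03
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_all_pairs_present(self, rng):
        y = rng.normal(size=50)
        groups = list(np.repeat(["A", "B", "C", "D", "E"], 10))
        out = pairwise_fdr(y, groups, rng.normal(size=50))
        assert len(out) == 10
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()

    def test_single_comparison_unchanged(self, rng):
        y = rng.normal(size=20)
        groups = list(np.repeat(["A", "B"], 10))
        out = pairwise_fdr(y, groups)
        assert len(out) == 1
        assert out["p_fdr"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_adjustment_monotone_in_rank(self, rng):
        y = rng.normal(size=60)
        y[:12] += 2.0
        groups = list(np.repeat(["A", "B", "C", "D", "E"], 12))
        out = pairwise_fdr(y, groups).sort_values("p")
        assert (np.diff(out["p_fdr"]) >= -1e-12).all()

    def test_true_difference_survives_adjustment(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20),
                            rng.normal(0, 1, 20)])
        groups = list(np.repeat(["A", "B", "C"], 20))
        out = pairwise_fdr(y, groups)
        ab = out[(out["group1"] == "A") & (out["group2"] == "B")]
        assert ab["p_fdr"].iloc[0] < 0.01


class TestBicBayesFactor:
    def test_direction(self, rng):
        groups = list(np.repeat(["A", "B"], 30))
        y_null = rng.normal(size=60)
        y_alt = y_null + np.repeat([0.0, 3.0], 30)
        z = rng.normal(size=60)
        assert bic_bayes_factor(y_alt, groups, z) > 3.0
        assert bic_bayes_factor(y_null, groups, z) < 1.0
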