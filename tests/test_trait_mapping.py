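"""Phenotype screening, discriminative-locus discovery and Blomberg's K."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from cgrmap.pangenome import PangenomeMatrix
from cgrmap.phylo import read_newick, tree_vcv
from cgrmap.simulate import (PangenomeSimConfig, simulate_presence_absence,
                             simulate_trait_on_tree)
from cgrmap.trait_mapping import (blomberg_k, collapse_features,
                                  exact_discriminators, fisher_exact_p,
                                  percent_conversion, rf_gini_importance,
                                  screen_metabolizers)


def as_matrix(presence: pd.DataFrame) -> PangenomeMatrix:
    n = len(presence)
    counts = presence.sum(axis=0)
    cls = pd.Series(np.where(counts == n, "core",
                             np.where(counts == 1, "singleton", "accessory")),
                    index=presence.columns)
    return PangenomeMatrix(presence=presence.astype(bool),
                           class_per_cluster=cls)


class TestPercentConversion:
    @pytest.mark.parametrize("dig,dhd,expected", [
        (10, 0, 0.0), (0, 10, 100.0), (5, 5, 50.0)])
    def test_values(self, dig, dhd, expected):
        assert percent_conversion(dig, dhd) == expected

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_conversion(0, 0)


class TestScreen:
    def test_null_strains_not_called(self, rng):
        reps = {f"S{i}": rng.normal(0, 1, 3) for i in range(8)}
        called, _ = screen_metabolizers(reps, rng.normal(0, 1, 6))
        assert called == set()

    def test_large_shift_called_alone(self, rng):
        reps = {f"S{i}": rng.normal(0, 1, 3) for i in range(8)}
        reps["HIT"] = rng.normal(20, 1, 3)
        called, table = screen_metabolizers(reps, rng.normal(0, 1, 6))
        assert called == {"HIT"}
        assert table.loc[table.strain_id == "HIT", "dunnett_p"].iloc[0] < 1e-4

    def test_dunnett_p_matches_monte_carlo_oracle(self, rng):
        """Adjusted p for the max statistic agrees with a direct Monte-Carlo
        simulation of the many-to-one null within simulation error."""
        k, n, n_ctrl = 4, 5, 5
        groups = {f"S{i}": rng.normal(0, 1, n) for i in range(k)}
        groups["S0"] = groups["S0"] + 1.8
        ctrl = rng.normal(0, 1, n_ctrl)
        _, table = screen_metabolizers(groups, ctrl)
        p_pkg = table.set_index("strain_id").loc["S0", "dunnett_p"]

        # observed t for S0 with pooled variance
        all_groups = [groups[f"S{i}"] for i in range(k)] + [ctrl]
        df = sum(len(g) - 1 for g in all_groups)
        s2 = sum(((g - g.mean()) ** 2).sum() for g in all_groups) / df
        t_obs = (groups["S0"].mean() - ctrl.mean()) / np.sqrt(s2 * (1 / n + 1 / n_ctrl))

        n_mc = 20000
        rng_mc = np.random.default_rng(123)
        max_abs_t = np.empty(n_mc)
        for b in range(n_mc):
            sims = [rng_mc.normal(0, 1, n) for _ in range(k)]
            c = rng_mc.normal(0, 1, n_ctrl)
            df_b = sum(len(g) - 1 for g in sims) + n_ctrl - 1
            s2_b = (sum(((g - g.mean()) ** 2).sum() for g in sims)
                    + ((c - c.mean()) ** 2).sum()) / df_b
            ts = [(g.mean() - c.mean()) / np.sqrt(s2_b * (1 / n + 1 / n_ctrl))
                  for g in sims]
            max_abs_t[b] = max(abs(t) for t in ts)
        p_mc = float((max_abs_t >= abs(t_obs)).mean())
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(p_pkg - p_mc) < max(5 * se, 0.01)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            screen_metabolizers({"A": [1.0]}, [0.0, 0.1])


class TestCollapse:
    def test_planted_cluster_collapses_to_one_feature(self):
        pres, truth = simulate_presence_absence(
            PangenomeSimConfig(n_genomes=20, n_core=20, n_accessory=50, seed=5))
        collapsed, groups = collapse_features(as_matrix(pres))
        planted_feats = {f for f, members in groups.items()
                         if set(truth.planted_gene_ids) & set(members)}
        assert len(planted_feats) == 1
        feat = planted_feats.pop()
        assert set(truth.planted_gene_ids) <= set(groups[feat])

    def test_no_duplicates_is_identity(self, rng):
        pres = pd.DataFrame(rng.random((10, 6)) < 0.5,
                            index=[f"G{i}" for i in range(10)],
                            columns=[f"c{i}" for i in range(6)])
        pres = pres.loc[:, ~pres.T.duplicated()]
        collapsed, groups = collapse_features(as_matrix(pres))
        assert list(collapsed.columns) == list(pres.columns)
        assert all(v == [k] for k, v in groups.items())

    def test_feature_count_equals_distinct_patterns(self, rng):
        pres = pd.DataFrame(rng.random((12, 40)) < 0.4,
                            index=[f"G{i}" for i in range(12)],
                            columns=[f"c{i}" for i in range(40)])
        collapsed, _ = collapse_features(as_matrix(pres))
        n_distinct = len({tuple(pres[c]) for c in pres.columns})
        assert len(collapsed.columns) == n_distinct


class TestRandomForest:
    def _labels(self, pres, truth):
        return truth.phenotype_labels

    def test_perfect_feature_ranks_first(self):
        hits = 0
        for seed in range(10):
            pres, truth = simulate_presence_absence(PangenomeSimConfig(
                n_genomes=24, n_core=1, n_accessory=50,
                planted_cluster_size=1, seed=seed))
            collapsed, groups = collapse_features(as_matrix(pres))
            table = rf_gini_importance(collapsed, truth.phenotype_labels,
                                       seed=seed, group_map=groups)
            top = table.iloc[0]
            if "PLT001" in top["member_clusters"]:
                hits += 1
        assert hits >= 9

    def test_constant_feature_zero_importance(self):
        pres, truth = simulate_presence_absence(PangenomeSimConfig(
            n_genomes=16, n_core=5, n_accessory=20, seed=3))
        collapsed, _ = collapse_features(as_matrix(pres))
        table = rf_gini_importance(collapsed, truth.phenotype_labels, seed=1)
        core_feature = next(f for f in collapsed.columns
                            if collapsed[f].all())
        gini = table.set_index("feature").loc[core_feature,
                                              "mean_decrease_gini"]
        assert gini == 0.0

    def test_independent_phenotype_importance_within_null(self, rng):
        """With labels independent of all features, the top observed
        importance is not extreme against the permuted-label null."""
        pres = pd.DataFrame(rng.random((20, 40)) < 0.5,
                            index=[f"G{i:02d}" for i in range(20)],
                            columns=[f"c{i}" for i in range(40)])
        pres = pres.loc[:, ~pres.T.duplicated()]
        labels = {g: ("metabolizer" if i < 10 else "non-metabolizer")
                  for i, g in enumerate(pres.index)}
        m = as_matrix(pres)
        collapsed, _ = collapse_features(m)
        obs = rf_gini_importance(collapsed, labels, n_trees=200,
                                 seed=0)["mean_decrease_gini"].max()
        null_max = []
        genomes = list(pres.index)
        for b in range(20):
            perm = rng.permutation(genomes)
            plabels = {g: labels[p] for g, p in zip(genomes, perm)}
            null_max.append(rf_gini_importance(
                collapsed, plabels, n_trees=200,
                seed=b + 1)["mean_decrease_gini"].max())
        assert obs <= np.quantile(null_max, 0.95) * 1.5

    def test_single_class_rejected(self, rng):
        pres = pd.DataFrame(rng.random((6, 5)) < 0.5,
                            index=[f"G{i}" for i in range(6)],
                            columns=[f"c{i}" for i in range(5)])
        labels = {g: "metabolizer" for g in pres.index}
        collapsed, _ = collapse_features(as_matrix(pres))
        with pytest.raises(ValueError, match="single class"):
            rf_gini_importance(collapsed, labels)

    def test_deterministic_given_seed(self):
        pres, truth = simulate_presence_absence(PangenomeSimConfig(
            n_genomes=12, n_core=3, n_accessory=30, seed=4))
        collapsed, _ = collapse_features(as_matrix(pres))
        t1 = rf_gini_importance(collapsed, truth.phenotype_labels, seed=7)
        t2 = rf_gini_importance(collapsed, truth.phenotype_labels, seed=7)
        assert t1.equals(t2)


class TestExactDiscriminators:
    def _setup(self):
        genomes = [f"G{i:02d}" for i in range(25)]
        labels = {g: ("metabolizer" if i < 8 else "non-metabolizer")
                  for i, g in enumerate(genomes)}
        y = np.array([labels[g] == "metabolizer" for g in genomes])
        return genomes, labels, y

    def test_pattern_equal_to_labels_flagged_with_closed_form_p(self):
        genomes, labels, y = self._setup()
        pres = pd.DataFrame({"hit": y, "miss": np.roll(y, 1)}, index=genomes)
        res = exact_discriminators(pres, labels).set_index("feature")
        assert bool(res.loc["hit", "perfect_discriminator"])
        assert res.loc["hit", "fisher_p"] == pytest.approx(
            1.0 / comb(25, 8, exact=True))
        assert not bool(res.loc["miss", "perfect_discriminator"])

    def test_complement_pattern_flagged(self):
        genomes, labels, y = self._setup()
        pres = pd.DataFrame({"absent_in_metabolizers": ~y}, index=genomes)
        res = exact_discriminators(pres, labels)
        assert bool(res["perfect_discriminator"].iloc[0])


class TestFisherClosedForm:
    def test_two_sided_p_equals_hypergeometric_sum(self, rng):
        """Spot-check the two-sided Fisher p against a direct hypergeometric
        enumeration for random margins (the exhaustive sweep lives in the
        acceptance suite)."""
        for _ in range(50):
            n = int(rng.integers(2, 30))
            a = int(rng.integers(0, n + 1)); b = int(rng.integers(0, n + 1))
            c = int(rng.integers(0, n + 1)); d = int(rng.integers(0, n + 1))
            if (a + b) == 0 or (c + d) == 0:
                continue
            p = fisher_exact_p(a, b, c, d)
            expected = hypergeom_two_sided(a, b, c, d)
            assert p == pytest.approx(expected, rel=1e-9), (a, b, c, d)


def hypergeom_two_sided(a, b, c, d):
    """Two-sided Fisher p: sum of probabilities of all tables with the same
    margins whose probability does not exceed the observed table's."""
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestBlombergK:
    def test_matches_direct_linear_algebra_oracle(self):
        """Hand-built V for a 4-taxon tree; every component recomputed with
        plain numpy from the published formulas."""
        tree = read_newick("((A:1.0,B:2.0):0.5,(C:1.5,D:0.5):1.0);",
                           from_string=True)
        trait = {"A": 0.3, "B": -1.2, "C": 2.0, "D": 0.8}
        V = np.array([[1.5, 0.5, 0.0, 0.0],
                      [0.5, 2.5, 0.0, 0.0],
                      [0.0, 0.0, 2.5, 1.0],
                      [0.0, 0.0, 1.0, 1.5]])
        labels, V_pkg = tree_vcv(tree)
        order = [labels.index(t) for t in "ABCD"]
        assert np.allclose(V_pkg[np.ix_(order, order)], V)

        x = np.array([trait[t] for t in "ABCD"])
        Vi = np.linalg.inv(V)
        one = np.ones(4)
        a_hat = (one @ Vi @ x) / (one @ Vi @ one)
        mse0 = ((x - a_hat) ** 2).sum() / 3
        mse = (x - a_hat) @ Vi @ (x - a_hat) / 3
        expected_ratio = (np.trace(V) - 4 / (one @ Vi @ one)) / 3
        k_oracle = (mse0 / mse) / expected_ratio

        res = blomberg_k(tree, trait, n_perm=10, seed=0)
        assert res.K == pytest.approx(k_oracle, abs=1e-10)
        assert res.MSE0 == pytest.approx(mse0, abs=1e-10)
        assert res.MSE == pytest.approx(mse, abs=1e-10)
        assert res.expected_ratio == pytest.approx(expected_ratio, abs=1e-10)

    def test_matches_frozen_r_picante_value(self, small_tree):
        # picante::Kcalc on the same tree and trait gives 0.635302991877
        trait = {"A": 1.2, "B": 0.7, "C": -0.3, "D": -0.9, "E": 2.1, "F": 0.4}
        res = blomberg_k(small_tree, trait, n_perm=10, seed=0)
        assert res.K == pytest.approx(0.635302991877, abs=1e-9)

    def test_affine_invariance(self, small_tree):
        trait = {"A": 1.2, "B": 0.7, "C": -0.3, "D": -0.9, "E": 2.1, "F": 0.4}
        shifted = {t: 3.0 + 2.5 * v for t, v in trait.items()}
        k1 = blomberg_k(small_tree, trait, n_perm=1).K
        k2 = blomberg_k(small_tree, shifted, n_perm=1).K
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_permutation_p_never_zero_and_in_range(self, tree24):
        trait = simulate_trait_on_tree(tree24, "brownian", 1.0, seed=2)
        res = blomberg_k(tree24, trait, n_perm=200, seed=3)
        assert 0 < res.p_perm <= 1
        assert res.p_perm >= 1 / 200

    def test_constant_trait_rejected(self, small_tree):
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(small_tree, {t: 1.0 for t in "ABCDEF"})

    def test_mismatched_tips_rejected(self, small_tree):
        with pytest.raises(ValueError, match="tip"):
            blomberg_k(small_tree, {"A": 1.0, "B": 2.0})

    def test_brownian_trait_has_low_p_white_noise_high_k_near_zero(self, tree24):
        # strong phylogenetic signal -> small permutation p
        ps = [blomberg_k(tree24,
                         simulate_trait_on_tree(tree24, "brownian", 1.0, seed=s),
                         n_perm=200, seed=s).p_perm for s in range(10)]
        assert np.median(ps) < 0.2
        ks = [blomberg_k(tree24,
                         simulate_trait_on_tree(tree24, "white_noise", 1.0,
                                                seed=s), n_perm=1).K
              for s in range(20)]
        assert np.mean(ks) < 0.3
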