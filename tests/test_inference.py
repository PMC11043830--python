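import itertools

import numpy as np
import pandas as pd
import pytest

from mossdiv import (
    CommunityDataset,
    aggregate,
    bray_curtis_matrix,
    growth_form_summary,
    paired_permutation_contrast,
    permanova,
)
from mossdiv.synthetic import SyntheticConfig, simulate_dataset

from conftest import make_records


def separated_groups(rng, n_per_group=5):
    """Two groups of units drawn from well-separated abundance profiles."""
    a = rng.poisson([50, 5, 1, 0.5, 40], size=(n_per_group, 5))
    b = rng.poisson([1, 40, 50, 30, 0.5], size=(n_per_group, 5))
    x = np.vstack([a, b])
    labels = ["a"] * n_per_group + ["b"] * n_per_group
    return bray_curtis_matrix(x), labels


class TestPermanova:
    def test_separated_groups_reach_minimum_p(self):
        # groups of 10: a random permutation re-creates the observed split
        # (tying the observed F) with probability ~1e-5, so the add-one
        # minimum p is attained; at groups of 5 that probability is 2/252
        # and the attainable minimum is ~0.009
        d, labels = separated_groups(np.random.default_rng(0), n_per_group=10)
        res = permanova(d, labels, n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1 / 1000)
        assert res.pseudo_f > 1
        assert (res.df_between, res.df_within) == (1, 18)

    def test_small_separated_groups_bounded_by_self_coincidence(self):
        d, labels = separated_groups(np.random.default_rng(0), n_per_group=5)
        res = permanova(d, labels, n_perm=999, seed=1)
        assert res.p_perm < 0.05

    def test_statistic_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(10, size=(8, 4)).astype(float)
        d = bray_curtis_matrix(x)
        labels = np.array(["a", "a", "b", "b", "a", "b", "a", "b"])
        f1 = permanova(d, labels, n_perm=99, seed=0).pseudo_f
        f2 = permanova(d, np.where(labels == "a", "x", "y"), n_perm=99, seed=0).pseudo_f
        order = rng.permutation(8)
        f3 = permanova(d[np.ix_(order, order)], labels[order], n_perm=99, seed=0).pseudo_f
        assert f1 == pytest.approx(f2) == pytest.approx(f3)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """6 units: the add-one MC p converges to the exact permutation p."""
        rng = np.random.default_rng(4)
        x = rng.poisson([20, 3, 8], size=(6, 3)).astype(float)
        d = bray_curtis_matrix(x)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        f_obs = permanova(d, labels, n_perm=99, seed=0).pseudo_f
        f_all = [
            permanova(d, perm, n_perm=99, seed=0).pseudo_f
            for perm in set(itertools.permutations(labels))
        ]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        mc = permanova(d, labels, n_perm=9999, seed=7)
        assert mc.p_perm == pytest.approx(exact_p, abs=0.02)

    def test_matches_scikit_bio_oracle(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = rng.poisson(8, size=(12, 6)).astype(float)
        d = bray_curtis_matrix(x)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, labels, n_perm=999, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d), grouping=list(labels), permutations=999
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)
        assert mine.p_perm == pytest.approx(theirs["p-value"], abs=0.05)

    def test_strata_restrict_permutations(self):
        d, labels = separated_groups(np.random.default_rng(6))
        strata = [0, 1, 2, 3, 4] * 2  # one unit of each group per block
        res = permanova(d, labels, n_perm=499, seed=2, strata=strata)
        assert 0 < res.p_perm <= 1

    def test_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            permanova(np.zeros((4, 4)), ["a", "a", "b", "b"], n_perm=99, seed=0)

    def test_small_groups_rejected(self):
        d = bray_curtis_matrix(np.random.default_rng(0).poisson(5, (3, 2)).astype(float))
        with pytest.raises(ValueError, match="groups"):
            permanova(d, ["a", "a", "b"], n_perm=99, seed=0)


class TestPairedContrast:
    def test_no_effect_gives_p_one(self):
        values = [1.0, 2.0, 1.0, 2.0]
        treatment = ["absence", "presence", "absence", "presence"]
        pair = ["p1", "p1", "p2", "p2"]
        # identical values in both arms of every block
        res = paired_permutation_contrast([3, 3, 5, 5], treatment, pair, seed=0)
        assert res.effect == 0.0 and res.p_perm == 1.0
        res2 = paired_permutation_contrast(values, treatment, pair, seed=0)
        assert res2.effect == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=10)
        values = np.concatenate([base, base + 1])
        treatment = ["absence"] * 10 + ["presence"] * 10
        pair = [f"p{i}" for i in range(10)] * 2
        res = paired_permutation_contrast(values, treatment, pair, n_perm=999, seed=1)
        assert res.effect == pytest.approx(1.0)
        # every sign flip weakens the all-positive observed effect
        assert res.p_perm < 0.02

    def test_monte_carlo_matches_exhaustive_three_blocks(self):
        values = [1.0, 2.5, 3.0, 3.2, 0.5, 1.5]
        treatment = ["absence", "presence"] * 3
        pair = ["a", "a", "b", "b", "c", "c"]
        exact = paired_permutation_contrast(values, treatment, pair, exact=True)
        mc = paired_permutation_contrast(values, treatment, pair, n_perm=19999, seed=3)
        assert mc.p_perm == pytest.approx(exact.p_perm, abs=0.02)

    def test_incomplete_block_rejected(self):
        with pytest.raises(ValueError, match="both treatments"):
            paired_permutation_contrast(
                [1, 2, 3],
                ["absence", "presence", "absence"],
                ["p1", "p1", "p2"],
                seed=0,
            )

    def test_p_never_zero(self):
        values = list(range(20))
        treatment = ["absence", "presence"] * 10
        pair = [f"p{i // 2}" for i in range(20)]
        res = paired_permutation_contrast(values, treatment, pair, n_perm=999, seed=0)
        assert res.p_perm >= 1 / 1000


class TestGrowthForms:
    def test_relative_abundance_shares(self):
        rows = [
            ("p01", "absence", "pl", 1, 1, "spA", 3),
            ("p01", "absence", "pl", 1, 1, "spB", 1),
        ]
        registry = pd.DataFrame(
            {
                "species": ["spA", "spB"],
                "genus": ["gA", "gB"],
                "growth_form": ["acrocarp", "pleurocarp"],
            }
        )
        ds = CommunityDataset(make_records(rows), registry=registry)
        units = growth_form_summary(ds, "cell").units.set_index("growth_form")
        assert units.loc["acrocarp", "rel_abundance"] == 0.75
        assert units.loc["pleurocarp", "rel_abundance"] == 0.25

    def test_single_form_unit(self):
        rows = [("p01", "absence", "pl", 1, 1, "spA", 4)]
        registry = pd.DataFrame(
            {"species": ["spA"], "genus": ["gA"], "growth_form": ["acrocarp"]}
        )
        ds = CommunityDataset(make_records(rows), registry=registry)
        units = growth_form_summary(ds, "cell").units
        assert units["rel_abundance"].tolist() == [1.0]

    def test_shares_sum_to_one_per_unit(self, default_dataset):
        units = growth_form_summary(default_dataset, "quadrat").units
        sums = units.groupby(["pair_id", "treatment", "plot_id", "quadrat_id"])[
            "rel_abundance"
        ].sum()
        assert np.allclose(sums, 1.0)

    def test_missing_species_listed(self, tiny_dataset):
        ds = CommunityDataset(
            tiny_dataset.records, registry=tiny_dataset.registry.iloc[:1]
        )
        with pytest.raises(ValueError, match="spB"):
            growth_form_summary(ds, "cell")

    def test_larger_acrocarp_pool_yields_higher_acrocarp_richness(self):
        """34 acrocarp vs 16 pleurocarp species at matched per-species
        abundance: the larger pool is richer at every scale."""
        cfg = SyntheticConfig(seed=9, sad_sigma=0.0, richness_effect=0.0,
                              evenness_effect=0.0, homogenization=0.0)
        ds = simulate_dataset(cfg)
        for scale in ("cell", "quadrat", "exclosure"):
            summ = growth_form_summary(ds, scale).summary
            by_form = summ.groupby("growth_form")["richness_mean"].mean()
            assert by_form["acrocarp"] > by_form["pleurocarp"]
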