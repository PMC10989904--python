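"""betaMNTD/betaNTI, Raup-Crick, process partitioning, NST, Sloan model."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from primerbias import assembly, synthgen


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _table(rows: dict, taxa: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa)


class TestPatristic:
    def test_matches_dendropy_oracle(self, small_truth):
        D = assembly.patristic_matrix(small_truth.tree, small_truth.taxon_ids)
        pdm = small_truth.tree.phylogenetic_distance_matrix()
        ns = small_truth.tree.taxon_namespace
        for i in range(0, 60, 7):
            for j in range(0, 60, 11):
                a, b = small_truth.taxon_ids[i], small_truth.taxon_ids[j]
                expected = pdm.patristic_distance(ns.get_taxon(a), ns.get_taxon(b))
                assert D[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_missing_taxon_rejected(self, small_truth):
        with pytest.raises(ValueError, match="not a tip"):
            assembly.patristic_matrix(small_truth.tree, ["nope"])


class TestBetaMNTD:
    def test_identical_communities_have_zero_distance(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        t = _table({"s1": [5, 5, 5, 5], "s2": [5, 5, 5, 5]}, list("abcd"))
        b = assembly.beta_mntd(t, tree)
        assert b.loc["s1", "s2"] == pytest.approx(0.0)

    def test_two_singleton_communities_give_patristic_distance(self):
        tree = _tree("(a:2,b:2);")
        t = _table({"s1": [7, 0], "s2": [0, 3]}, ["a", "b"])
        b = assembly.beta_mntd(t, tree)
        assert b.loc["s1", "s2"] == pytest.approx(4.0)

    def test_mixed_example_matches_brute_force(self):
        """Hand check on a 3-tip tree against exhaustive nearest-taxon search."""
        tree = _tree("((a:1,b:2):1,c:4);")
        t = _table({"s1": [6, 2, 2], "s2": [0, 5, 5]}, ["a", "b", "c"])
        D = assembly.patristic_matrix(tree, ["a", "b", "c"])
        x = t.to_numpy(dtype=float)
        P = x / x.sum(axis=1, keepdims=True)
        expected = 0.0
        pres1 = np.where(x[0] > 0)[0]
        pres2 = np.where(x[1] > 0)[0]
        for i in pres1:
            expected += 0.5 * P[0, i] * min(D[i, j] for j in pres2)
        for j in pres2:
            expected += 0.5 * P[1, j] * min(D[i, j] for i in pres1)
        b = assembly.beta_mntd(t, tree)
        assert b.loc["s1", "s2"] == pytest.approx(expected, abs=1e-12)


class TestBNTI:
    def test_star_tree_null_is_degenerate(self):
        """Equal-branch star phylogeny: every tip shuffle is identical, so the
        z-score is undefined and flagged NaN rather than +-inf."""
        tree = _tree("(a:1,b:1,c:1,d:1);")
        t = _table({"s1": [5, 5, 0, 0], "s2": [0, 0, 5, 5]}, list("abcd"))
        z = assembly.bnti(t, tree, n_null=99, seed=0)
        assert np.isnan(z.loc["s1", "s2"])

    def test_z_matrix_symmetric(self, small_truth):
        primer = synthgen.make_primer_profile(small_truth, "P")
        t, _ = synthgen.apply_primer(small_truth, primer, depth=2000, seed=0)
        z = assembly.bnti(t.iloc[:6], small_truth.tree, n_null=99, seed=1)
        np.testing.assert_allclose(z.to_numpy(), z.to_numpy().T, atol=1e-12)

    def test_habitat_filtering_lowers_within_habitat_bnti(self):
        """Three-point dose check: concentrating each habitat's community in
        one clade (with enough overdispersion for presence turnover among
        clade members) pushes the within-habitat betaNTI median down
        monotonically - the phylogenetic-clustering signature of habitat
        filtering."""

        def median_bnti(strength, seed):
            truth = synthgen.simulate_truth(
                n_taxa=120, habitats={"water": 8}, habitat_specialization=0.95,
                phylo_filtering=strength, seed=seed,
            )
            primer = synthgen.make_primer_profile(truth, "P")
            t, _ = synthgen.apply_primer(
                truth, primer, depth=500, dispersion=1.0, seed=seed + 500
            )
            z = assembly.bnti(t, truth.tree, n_null=199, seed=seed + 900)
            iu = np.triu_indices(len(t), k=1)
            return float(np.nanmedian(z.to_numpy()[iu]))

        doses = [
            np.mean([median_bnti(f, s) for s in (1, 2, 3)]) for f in (0.0, 0.5, 0.9)
        ]
        assert doses[0] > doses[1] > doses[2]
        assert doses[2] < 0


class TestRaupCrick:
    def test_boundary_values(self):
        """Two identical rich samples are far more similar than any null draw
        (RCI -> -1); two fully disjoint blocks are far less similar (+1)."""
        rng = np.random.default_rng(0)
        base = rng.integers(50, 100, size=30)
        same = _table({"s1": base, "s2": base, "s3": base}, [f"t{i}" for i in range(30)])
        rci = assembly.raup_crick_bray(same, n_null=99, seed=1)
        assert rci.loc["s1", "s2"] == pytest.approx(-1.0)
        half = np.zeros(30, dtype=int)
        half[:15] = 100
        other = np.zeros(30, dtype=int)
        other[15:] = 100
        disjoint = _table(
            {"s1": half, "s2": other, "s3": half, "s4": other},
            [f"t{i}" for i in range(30)],
        )
        rci2 = assembly.raup_crick_bray(disjoint, n_null=99, seed=2)
        assert rci2.loc["s1", "s2"] == pytest.approx(1.0)

    def test_two_taxon_toy_matches_enumeration(self):
        """Singleton-richness samples over 2 taxa: the null BC is 1 with
        probability 2q(1-q) (different taxa drawn) and 0 otherwise, so for an
        observed disjoint pair RCI = 2*(P(null=0) + 0.5*P(null=1)) - 1."""
        t = _table({"s1": [3, 0], "s2": [0, 3]}, ["a", "b"])
        rci = assembly.raup_crick_bray(t, n_null=2999, seed=5)
        q = 0.5  # both taxa have occupancy 1/2
        expected = 2 * ((1 - 2 * q * (1 - q)) + 0.5 * (2 * q * (1 - q))) - 1
        assert rci.loc["s1", "s2"] == pytest.approx(expected, abs=0.06)

    def test_values_always_bounded(self, paired_dataset):
        table, _ = paired_dataset
        rci = assembly.raup_crick_bray(table.iloc[:8], n_null=99, seed=0)
        assert (rci.to_numpy() >= -1 - 1e-12).all()
        assert (rci.to_numpy() <= 1 + 1e-12).all()


class TestPartition:
    @pytest.mark.parametrize(
        "bnti,rci,expected",
        [
            (-3.0, 0.0, "homogeneous selection"),
            (3.0, 0.0, "heterogeneous selection"),
            (0.0, 0.0, "undominated"),
            (0.5, 0.99, "dispersal limitation"),
            (0.5, -0.99, "homogenizing dispersal"),
            (np.nan, 0.0, "undetermined"),
        ],
    )
    def test_threshold_rules(self, bnti, rci, expected):
        assert assembly.partition_processes(bnti, rci) == expected

    def test_inverted_convention_swaps_dispersal_labels(self):
        assert (
            assembly.partition_processes(0.0, 0.99, rc_convention="inverted")
            == "homogenizing dispersal"
        )

    def test_fractions_sum_to_one_exactly(self, rng):
        labels = rng.choice(list(assembly.PROCESS_LABELS), size=100)
        frac = assembly.process_fractions(list(labels))
        assert frac.sum() == 1.0
        assert set(frac.index) == set(assembly.PROCESS_LABELS)


class TestNST:
    def test_identical_group_is_fully_deterministic(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 50, size=20)
        t = _table({f"s{i}": base for i in range(4)}, [f"t{i}" for i in range(20)])
        groups = pd.Series("g", index=t.index)
        val = assembly.nst(t, groups, n_null=99, seed=1)
        assert val["g"] == pytest.approx(0.0, abs=0.02)

    def test_neutral_groups_look_stochastic(self):
        """Neutrally assembled samples sit near their null expectation: NST
        above the 50% boundary in most runs."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = rng.lognormal(0, 1.5, 80)
            p /= p.sum()
            t = synthgen.simulate_neutral_pair_data(p, m=0.3, N=800, n_samples=8, seed=seed)
            groups = pd.Series("g", index=t.index)
            val = assembly.nst(t, groups, n_null=199, seed=seed + 100)
            wins += val["g"] > 0.5
        assert wins >= 4

    def test_bounded_on_adversarial_tables(self, rng):
        t = pd.DataFrame(
            rng.integers(0, 5, size=(6, 10)), index=[f"s{i}" for i in range(6)]
        )
        t.iloc[:, 0] += 1
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=t.index)
        vals = assembly.nst(t, groups, n_null=99, seed=0)
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_small_group_rejected(self):
        t = _table({"s1": [1, 2], "s2": [2, 1]}, ["a", "b"])
        with pytest.raises(ValueError, match="fewer than 3"):
            assembly.nst(t, pd.Series("g", index=t.index), n_null=99)


class TestSloan:
    def test_ubiquitous_abundant_taxon_saturates(self):
        rng = np.random.default_rng(0)
        p = rng.lognormal(0, 1, 40)
        p /= p.sum()
        t = synthgen.simulate_neutral_pair_data(p, m=0.3, N=2000, n_samples=30, seed=1)
        fit = assembly.sloan_fit(t)
        top = fit.stats["p"].idxmax()
        assert fit.stats.loc[top, "pred"] > 0.99
        assert abs(fit.stats.loc[top, "freq"] - fit.stats.loc[top, "pred"]) < 0.05

    def test_recovered_m_orders_correctly(self):
        """Fitted m must order true m = 0.02 < 0.1 < 0.5."""
        rng = np.random.default_rng(5)
        p = rng.lognormal(0, 1.5, 300)
        p /= p.sum()
        fits = []
        for i, m in enumerate((0.02, 0.1, 0.5)):
            t = synthgen.simulate_neutral_pair_data(p, m=m, N=1500, n_samples=40, seed=50 + i)
            fits.append(assembly.sloan_fit(t).m)
        assert fits[0] < fits[1] < fits[2]

    def test_non_neutral_data_fit_worse_than_neutral(self):
        rng = np.random.default_rng(2)
        p = rng.lognormal(0, 1.5, 100)
        p /= p.sum()
        neutral = synthgen.simulate_neutral_pair_data(p, m=0.2, N=1000, n_samples=30, seed=3)
        r2_neutral = assembly.sloan_fit(neutral).r2
        # deterministic specialists: two alternating fixed compositions
        comp_a = np.where(np.arange(100) % 2 == 0, p, 0.0)
        comp_b = np.where(np.arange(100) % 2 == 1, p, 0.0)
        rows = {}
        for i in range(30):
            comp = comp_a if i % 2 == 0 else comp_b
            rows[f"s{i}"] = rng.multinomial(1000, comp / comp.sum())
        det = _table(rows, list(neutral.columns))
        r2_det = assembly.sloan_fit(det).r2
        assert r2_det < r2_neutral

    def test_too_few_taxa_rejected(self):
        t = _table({"s1": [5, 5], "s2": [5, 5]}, ["a", "b"])
        with pytest.raises(ValueError, match="at least 10"):
            assembly.sloan_fit(t)


class TestClassifyNeutral:
    def test_observed_equal_predicted_is_neutral(self):
        out = assembly.classify_neutral(np.array([0.5]), np.array([0.5]), 50)
        assert out[0] == "neutral"

    def test_observed_above_band_is_above(self):
        out = assembly.classify_neutral(np.array([1.0]), np.array([0.6]), 50)
        assert out[0] == "above"

    def test_observed_below_band_is_below(self):
        out = assembly.classify_neutral(np.array([0.05]), np.array([0.6]), 50)
        assert out[0] == "below"
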