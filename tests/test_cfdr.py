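import numpy as np
import pandas as pd
import pytest

from crosstrait.cfdr import (ConditionalFDR, build_lookup, condfdr_assign,
                             conjfdr_assign, trio_conjfdr)
from crosstrait.simulate import GenerativeParams, simulate_ld_blocks, simulate_trio
from crosstrait.sumstats import harmonize_pair


def constructed_pair(n=1000, seed=0):
    """Identity-LD pair with controllable p-values."""
    ld = simulate_ld_blocks(n, 1, 0.0, seed=seed)
    rng = np.random.default_rng(seed)
    pair = pd.DataFrame({
        "SNP": ld.snp_id, "CHR": ld.chrom, "BP": ld.pos, "A1": "A", "A2": "G",
        "Z_A": 1.0, "Z_B": 1.0, "N_A": 1e4, "N_B": 1e4,
        "P_A": rng.uniform(size=n), "P_B": rng.uniform(size=n),
    })
    return pair, ld


class TestBuildLookup:
    def test_counting_example(self):
        """100 of 1000 SNPs pass p2 <= 0.1; 20 of those pass p1 <= 0.01:
        the raw cell at (p1=0.01, p2=0.1) is 0.01 * 100 / 20 = 0.05."""
        pair, ld = constructed_pair(1000)
        p1 = np.full(1000, 0.5)
        p2 = np.full(1000, 0.5)
        p2[:100] = 0.05          # pass the p2 <= 0.1 threshold
        p1[:20] = 0.005          # pass p1 <= 0.01, all inside the p2 stratum
        pair["P_A"], pair["P_B"] = p1, p2
        grid = build_lookup(pair, ld, n_prune=3, seed=1)
        i = np.searchsorted(grid.axis1, 2.0)   # -log10 0.01
        j = np.searchsorted(grid.axis2, 1.0)   # -log10 0.1
        assert grid.c2[j] == 100
        assert grid.c12[i, j] == 20
        assert grid.raw_values[i, j] == pytest.approx(0.05)

    def test_p2_threshold_one_column_is_unconditional_fdr(self):
        """The p2 = 1 column reduces exactly to the empirical-Bayes FDR
        p1 * N / C1(p1) wherever it is defined."""
        pair, ld = constructed_pair(1000, seed=5)
        grid = build_lookup(pair, ld, n_prune=2, seed=2)
        p1 = pair["P_A"].to_numpy()
        n = len(pair)
        p1_nodes = 10.0 ** (-grid.axis1)
        c1 = np.array([(p1 <= t).sum() for t in p1_nodes])
        defined = c1 >= 1
        expected = np.minimum(p1_nodes[defined] * n / c1[defined], 1.0)
        np.testing.assert_allclose(grid.raw_values[defined, 0], expected)

    def test_grid_invariants(self, overlap_sim):
        _, pair, ld, _ = overlap_sim
        grid = build_lookup(pair, ld, n_prune=5, seed=3)
        assert np.nanmin(grid.values) >= 0 and np.nanmax(grid.values) <= 1
        np.testing.assert_allclose(grid.values[0, :], 1.0)
        # nonincreasing along increasing -log10 p1 at every p2 stringency
        assert (np.diff(grid.values, axis=0) <= 1e-12).all()

    def test_degenerate_input_rejected(self):
        pair, ld = constructed_pair(100)
        pair["P_A"] = 0.5
        with pytest.raises(ValueError, match="degenerate"):
            build_lookup(pair, ld)

    def test_row_order_invariance_and_determinism(self):
        pair, ld = constructed_pair(500, seed=9)
        g1 = build_lookup(pair, ld, n_prune=4, seed=4)
        shuffled = pair.sample(frac=1.0, random_state=2).reset_index(drop=True)
        g2 = build_lookup(shuffled, ld, n_prune=4, seed=4)
        np.testing.assert_array_equal(g1.values, g2.values)


class TestAssign:
    def test_node_value_exact(self):
        pair, ld = constructed_pair(1000, seed=7)
        grid = build_lookup(pair, ld, n_prune=2, seed=6)
        probe = pair.iloc[:1].copy()
        probe["P_A"] = 10.0 ** -1.5   # exactly on axis nodes
        probe["P_B"] = 10.0 ** -0.3
        i = np.searchsorted(grid.axis1, 1.5)
        j = np.searchsorted(grid.axis2, 0.3)
        val = condfdr_assign(probe, grid)[0]
        assert val == pytest.approx(grid.values[i, j], rel=1e-9)

    def test_between_nodes_bounded_by_corners(self):
        pair, ld = constructed_pair(1000, seed=8)
        grid = build_lookup(pair, ld, n_prune=2, seed=6)
        probe = pair.iloc[:1].copy()
        probe["P_A"] = 10.0 ** -1.55
        probe["P_B"] = 10.0 ** -0.33
        i = np.searchsorted(grid.axis1, 1.5)
        j = np.searchsorted(grid.axis2, 0.3)
        corners = grid.values[i:i + 2, j:j + 2]
        val = condfdr_assign(probe, grid)[0]
        assert corners.min() - 1e-12 <= val <= corners.max() + 1e-12

    def test_monotone_in_p1_at_fixed_p2(self):
        pair, ld = constructed_pair(1000, seed=9)
        grid = build_lookup(pair, ld, n_prune=2, seed=6)
        probe = pair.iloc[:2].copy()
        probe["P_B"] = 0.05
        probe["P_A"] = [1e-4, 1e-2]
        vals = condfdr_assign(probe, grid)
        assert vals[0] <= vals[1]

    def test_out_of_range_clamped_to_edge(self):
        pair, ld = constructed_pair(1000, seed=10)
        grid = build_lookup(pair, ld, n_prune=2, seed=6)
        probe = pair.iloc[:1].copy()
        probe["P_A"] = 1e-30   # beyond the grid maximum of 20
        probe["P_B"] = 1e-30
        val = condfdr_assign(probe, grid)[0]
        assert val == pytest.approx(grid.values[-1, -1])


class TestConjFDR:
    def test_max_identity_and_symmetry(self):
        pair, ld = constructed_pair(800, seed=11)
        gab = build_lookup(pair, ld, primary="A", n_prune=2, seed=5)
        gba = build_lookup(pair, ld, primary="B", n_prune=2, seed=5)
        scored = conjfdr_assign(pair, gab, gba)
        np.testing.assert_array_equal(
            scored["CONJFDR"],
            np.maximum(scored["CONDFDR_A_B"], scored["CONDFDR_B_A"]))
        assert (scored["CONJFDR"] >= scored["CONDFDR_A_B"]).all()
        assert (scored["CONJFDR"] >= scored["CONDFDR_B_A"]).all()
        # swapping the two traits leaves conjFDR unchanged
        swapped = pair.rename(columns={"P_A": "P_B", "P_B": "P_A",
                                       "Z_A": "Z_B", "Z_B": "Z_A",
                                       "N_A": "N_B", "N_B": "N_A"})
        gab2 = build_lookup(swapped, ld, primary="A", n_prune=2, seed=5)
        gba2 = build_lookup(swapped, ld, primary="B", n_prune=2, seed=5)
        scored2 = conjfdr_assign(swapped, gab2, gba2)
        np.testing.assert_allclose(scored2["CONJFDR"], scored["CONJFDR"])

    def test_estimator_interface(self, overlap_sim):
        _, pair, ld, _ = overlap_sim
        scorer = ConditionalFDR(n_prune=5, random_state=1)
        scored = scorer.fit(pair, ld=ld).transform(pair)
        assert len(scored) == len(pair)
        assert scored["CONJFDR"].between(0, 1).all()
        params = scorer.get_params()
        assert params["n_prune"] == 5


class TestTrio:
    def make_scored(self, vals):
        n = len(vals)
        return pd.DataFrame({"SNP": [f"rs{i}" for i in range(n)],
                             "CHR": "1", "BP": np.arange(1, n + 1),
                             "CONJFDR": vals})

    def test_max_of_three(self):
        t = trio_conjfdr(self.make_scored([0.01]), self.make_scored([0.02]),
                         self.make_scored([0.03]))
        assert t["TRIO_CONJFDR"].iloc[0] == pytest.approx(0.03)

    def test_dominance(self):
        t = trio_conjfdr(self.make_scored([0.01, 0.2]),
                         self.make_scored([0.02, 0.01]),
                         self.make_scored([0.03, 0.01]))
        tau = 0.05
        exceeds = t[["CONJFDR_AB", "CONJFDR_AC", "CONJFDR_BC"]].gt(tau).any(axis=1)
        assert ((t["TRIO_CONJFDR"] > tau) == exceeds).all()

    def test_empty_intersection_rejected(self):
        a = self.make_scored([0.1])
        b = self.make_scored([0.1])
        b["SNP"] = ["other"]
        with pytest.raises(ValueError, match="intersection"):
            trio_conjfdr(a, b, self.make_scored([0.1]))

    def test_planted_three_way_component_enriched(self):
        """SNPs causal for all three traits reach trio significance more often
        than SNPs shared by only two traits."""
        gp = GenerativeParams(m=30_000, n_blocks=600, pi_a=0, pi_b=0,
                              pi_ab=0, rho_beta=0.9, sigma_b2_a=4e-4,
                              seed=55)
        stats_list, ld, eff = simulate_trio(
            gp, weights={"a": 5e-4, "b": 5e-4, "c": 5e-4,
                         "ab": 1e-3, "ac": 0.0, "bc": 0.0, "abc": 1e-3})
        pairs = {}
        for tag, (i, j) in {"ab": (0, 1), "ac": (0, 2), "bc": (1, 2)}.items():
            pair = harmonize_pair(stats_list[i], stats_list[j])
            scorer = ConditionalFDR(n_prune=5, random_state=2)
            pairs[tag] = scorer.fit(pair, ld=ld).transform(pair)
        trio = trio_conjfdr(pairs["ab"], pairs["ac"], pairs["bc"])
        trio = trio.merge(pd.DataFrame({"SNP": ld.snp_id,
                                        "component": eff["component"]}), on="SNP")
        sig = trio["TRIO_CONJFDR"] < 0.05
        rate_abc = sig[trio["component"] == "abc"].mean()
        rate_ab = sig[trio["component"] == "ab"].mean()
        assert rate_abc > rate_ab
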