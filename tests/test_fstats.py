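"""f3/f4 statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from steppeadmix import simulate as sim
from steppeadmix.fstats import (
    default_block_ids,
    f3,
    f4,
    group_frequencies,
    outgroup_f3_scan,
    f4_symmetry_scan,
    weighted_block_jackknife,
)
from steppeadmix.genodata import GenotypeDataset, Individual
from steppeadmix.simulate import AdmixtureSpec, SourcePopulation

from helpers import freqs_from_arrays, tiny_panel


def brute_force_fstat(kind, pops_freqs, weights=None):
    """Per-SNP loop oracle for f3/f4 (complete-case, uniform weights)."""
    total = 0.0
    n = 0
    for row in zip(*pops_freqs):
        if any(np.isnan(v) for v in row):
            continue
        if kind == "f4":
            a, b, c, d = row
            total += (a - b) * (c - d)
        else:
            a, b, c = row
            total += (c - a) * (c - b)
        n += 1
    return total / n


class TestGroupFrequencies:
    def test_single_pseudohaploid_alt(self):
        panel = tiny_panel(1)
        ds = GenotypeDataset(panel, [Individual("a", group_label="g")],
                             np.array([[2]], dtype=np.int8))
        gf = group_frequencies(ds)
        assert gf.col("g")[0] == 1.0
        assert gf.count[0, 0] == 1

    def test_two_pseudohaploids_half(self):
        panel = tiny_panel(1)
        ds = GenotypeDataset(
            panel,
            [Individual("a", group_label="g"), Individual("b", group_label="g")],
            np.array([[0, 2]], dtype=np.int8),
        )
        assert group_frequencies(ds).col("g")[0] == 0.5

    def test_diploid_counts_two_draws(self):
        panel = tiny_panel(1)
        ds = GenotypeDataset(panel, [Individual("a", group_label="g")],
                             np.array([[1]], dtype=np.int8), ploidy_mode="diploid")
        gf = group_frequencies(ds)
        assert gf.col("g")[0] == 0.5 and gf.count[0, 0] == 2

    def test_matches_brute_force_recount(self, rng):
        panel = tiny_panel(50)
        calls = rng.choice([0, 2, 9], size=(50, 6)).astype(np.int8)
        labels = ["g1"] * 3 + ["g2"] * 3
        ds = GenotypeDataset(
            panel, [Individual(f"i{k}", group_label=labels[k]) for k in range(6)], calls
        )
        gf = group_frequencies(ds)
        for gi, g in enumerate(["g1", "g2"]):
            cols = [k for k in range(6) if labels[k] == g]
            for i in range(50):
                vals = [calls[i, c] for c in cols if calls[i, c] != 9]
                if vals:
                    assert gf.col(g)[i] == pytest.approx(np.mean(vals) / 2)
                else:
                    assert np.isnan(gf.col(g)[i])

    def test_empty_group_rejected(self):
        panel = tiny_panel(1)
        ds = GenotypeDataset(panel, [Individual("a", group_label="g")],
                             np.array([[0]], dtype=np.int8))
        with pytest.raises(ValueError):
            group_frequencies(ds, {"a": "g", "ghost": "h"})


class TestF4:
    def test_identical_first_pair_is_zero(self, small_panel, rng):
        gf = freqs_from_arrays(
            small_panel,
            {"A": rng.random(len(small_panel)), "C": rng.random(len(small_panel)),
             "D": rng.random(len(small_panel))},
        )
        blocks = default_block_ids(small_panel)
        r = f4("A", "A", "C", "D", gf, blocks)
        assert r.estimate == 0.0 and r.se == 0.0

    def test_hand_computed_two_snp_value(self):
        panel = tiny_panel(2, chroms=["1", "2"])
        gf = freqs_from_arrays(panel, {"A": [1, 0], "B": [0, 0], "C": [1, 1], "D": [0, 1]})
        blocks = default_block_ids(panel)
        r = f4("A", "B", "C", "D", gf, blocks)
        assert r.estimate == pytest.approx(0.5)
        assert r.n_blocks == 2

    def test_sign_antisymmetry(self, small_panel, rng):
        n = len(small_panel)
        gf = freqs_from_arrays(small_panel, {p: rng.random(n) for p in "ABCD"})
        blocks = default_block_ids(small_panel)
        base = f4("A", "B", "C", "D", gf, blocks).estimate
        assert f4("B", "A", "C", "D", gf, blocks).estimate == pytest.approx(-base)
        assert f4("A", "B", "D", "C", gf, blocks).estimate == pytest.approx(-base)

    def test_polarity_flip_invariance(self, small_panel, rng):
        n = len(small_panel)
        groups = {p: rng.random(n) for p in "ABCD"}
        blocks = default_block_ids(small_panel)
        base = f4("A", "B", "C", "D", freqs_from_arrays(small_panel, groups), blocks)
        flip = rng.random(n) < 0.5
        flipped = {p: np.where(flip, 1 - v, v) for p, v in groups.items()}
        alt = f4("A", "B", "C", "D", freqs_from_arrays(small_panel, flipped), blocks)
        assert alt.estimate == pytest.approx(base.estimate)
        assert alt.se == pytest.approx(base.se)

    def test_vectorized_equals_brute_force(self, small_panel, rng):
        n = len(small_panel)
        groups = {p: rng.random(n) for p in "ABCD"}
        groups["A"][rng.random(n) < 0.1] = np.nan  # some missing data
        gf = freqs_from_arrays(small_panel, groups)
        blocks = default_block_ids(small_panel)
        r = f4("A", "B", "C", "D", gf, blocks)
        auto = small_panel.autosomal_mask() & ~np.isnan(groups["A"])
        oracle = brute_force_fstat("f4", [groups[p][auto & (blocks >= 0)] for p in "ABCD"])
        assert r.estimate == pytest.approx(oracle, abs=1e-12)


class TestF3:
    def test_apex_nonnegative_for_equal_pair(self, small_panel, rng):
        n = len(small_panel)
        gf = freqs_from_arrays(small_panel, {"A": rng.random(n), "C": rng.random(n)})
        blocks = default_block_ids(small_panel)
        assert f3("A", "A", "C", gf, blocks).estimate >= 0

    def test_hand_computed_value(self):
        panel = tiny_panel(2, chroms=["1", "2"])
        gf = freqs_from_arrays(panel, {"A": [0.2, 0.2], "B": [0.4, 0.4], "C": [0.8, 0.8]})
        r = f3("A", "B", "C", gf, default_block_ids(panel))
        assert r.estimate == pytest.approx(0.24)

    def test_symmetric_in_first_two(self, small_panel, rng):
        n = len(small_panel)
        gf = freqs_from_arrays(small_panel, {p: rng.random(n) for p in "ABC"})
        blocks = default_block_ids(small_panel)
        assert f3("A", "B", "C", gf, blocks).estimate == pytest.approx(
            f3("B", "A", "C", gf, blocks).estimate
        )


class TestWeightedBlockJackknife:
    def test_equal_delete_one_estimates_zero_se(self):
        _, se = weighted_block_jackknife(1.0, [1.0, 1.0, 1.0], [10, 10, 10])
        assert se == 0.0

    def test_matches_textbook_jackknife_with_equal_weights(self):
        """Delete-one estimates (1,2,3,4), equal weights -> classic formula."""
        loo = np.array([1.0, 2.0, 3.0, 4.0])
        theta = loo.mean()
        est, se = weighted_block_jackknife(theta, loo, np.ones(4))
        g = 4
        var_oracle = (g - 1) / g * np.sum((loo - loo.mean()) ** 2)
        assert se == pytest.approx(np.sqrt(var_oracle))
        assert est == pytest.approx(g * theta - (g - 1) * loo.mean())

    def test_weight_scale_invariance(self):
        loo = np.array([0.3, 0.1, 0.25, 0.4, 0.2])
        w = np.array([5.0, 10.0, 3.0, 8.0, 4.0])
        a = weighted_block_jackknife(0.27, loo, w)
        b = weighted_block_jackknife(0.27, loo, 2 * w)
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            weighted_block_jackknife(1.0, [1.0], [5.0])

    def test_se_close_to_analytic_on_iid_blocks(self, rng):
        """Jackknife SE of a mean over 500 iid blocks tracks sigma/sqrt(n)."""
        vals = rng.standard_normal(500)
        theta = vals.mean()
        loo = (vals.sum() - vals) / 499
        _, se = weighted_block_jackknife(theta, loo, np.ones(500))
        analytic = vals.std(ddof=1) / np.sqrt(500)
        assert abs(se - analytic) / analytic < 0.2


@pytest.fixture(scope="module")
def scan_freqs(small_panel):
    freqs = sim.simulate_graph(small_panel, sim.DEFAULT_GRAPH_EDGES, seed=21)
    rng = np.random.default_rng(22)
    calls, inds = [], []
    for pop in ["WSH", "ANA", "han", "iran", "african", "target"]:
        f = freqs["ANA"] if pop == "target" else freqs[pop]
        d = sim.sample_individuals_from_freqs(f, small_panel, 15, pop, rng)
        ph = sim.pseudohaploid_sample(d, 0.05, rng)
        calls.append(ph.calls)
        inds += ph.individuals
    ds = GenotypeDataset(small_panel, inds, np.concatenate(calls, axis=1))
    return group_frequencies(ds)


class TestScans:
    def test_self_like_candidate_ranks_first(self, scan_freqs, small_panel):
        blocks = default_block_ids(small_panel)
        table = outgroup_f3_scan(
            "target", ["WSH", "ANA", "han", "iran"], "african", scan_freqs, blocks
        )
        assert table.iloc[0].candidate == "ANA"

    def test_ranking_invariant_to_input_order(self, scan_freqs, small_panel):
        blocks = default_block_ids(small_panel)
        a = outgroup_f3_scan("target", ["WSH", "ANA", "han"], "african", scan_freqs, blocks)
        b = outgroup_f3_scan("target", ["han", "WSH", "ANA"], "african", scan_freqs, blocks)
        assert list(a.candidate) == list(b.candidate)

    def test_identical_pair_never_flagged(self, scan_freqs, small_panel):
        blocks = default_block_ids(small_panel)
        table = f4_symmetry_scan("ANA", "ANA", ["WSH", "han"], "african", scan_freqs, blocks)
        assert (table.estimate == 0).all() and not table.flagged.any()


def test_f4_linearity_of_mixtures():
    """f4 responds linearly to mixture proportion — the qpAdm lever."""
    panel = sim.make_panel(20_000, seed=30)
    freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, seed=31)
    rng = np.random.default_rng(32)
    spec = AdmixtureSpec(["WSH", "ANA"], [0.4, 0.6], 10, 20)
    sources = [SourcePopulation(n, freqs[n]) for n in ["WSH", "ANA"]]
    dip, _ = sim.simulate_admixed_individuals(spec, sources, panel, rng)
    calls, inds = [sim.pseudohaploid_sample(dip, 0.1, rng).calls], list(dip.individuals)
    for pop in ["WSH", "ANA", "han", "african"]:
        d = sim.sample_individuals_from_freqs(freqs[pop], panel, 15, pop, rng)
        calls.append(sim.pseudohaploid_sample(d, 0.1, rng).calls)
        inds += d.individuals
    ds = GenotypeDataset(panel, inds, np.concatenate(calls, axis=1))
    gf = group_frequencies(ds)
    blocks = default_block_ids(panel)
    mix = f4("target", "african", "han", "african", gf, blocks)
    s1 = f4("WSH", "african", "han", "african", gf, blocks)
    s2 = f4("ANA", "african", "han", "african", gf, blocks)
    expected = 0.4 * s1.estimate + 0.6 * s2.estimate
    pooled_se = np.sqrt(mix.se**2 + (0.4 * s1.se) ** 2 + (0.6 * s2.se) ** 2)
    assert abs(mix.estimate - expected) < 3 * pooled_se
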