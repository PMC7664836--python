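"""Generator checks against independent statistical oracles."""

import numpy as np
import pytest

from steppeadmix import simulate as sim
from steppeadmix.qc import damage_profile
from steppeadmix.simulate import AdmixtureSpec, SourcePopulation


def hudson_fst(p1, p2):
    """Hudson-style Fst from population frequencies (ratio of averages)."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestSources:
    def test_no_drift_limit(self):
        sources, _ = sim.simulate_sources(2000, 2, [1e-9, 1e-9], seed=0)
        diff = np.abs(sources[0].allele_freqs - sources[1].allele_freqs)
        assert diff.mean() < 0.01

    def test_fst_matches_drift_parameter(self):
        sources, _ = sim.simulate_sources(50_000, 2, [0.2, 0.2], seed=1)
        fst = hudson_fst(sources[0].allele_freqs, sources[1].allele_freqs)
        assert abs(fst - 0.2) < 0.03

    def test_seed_reproducibility(self):
        a, _ = sim.simulate_sources(500, 3, 0.1, seed=9)
        b, _ = sim.simulate_sources(500, 3, 0.1, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.allele_freqs, y.allele_freqs)

    def test_negative_drift_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.drift_frequencies(np.array([0.5]), -0.1, rng)

    def test_graph_unreachable_node(self, small_panel):
        with pytest.raises(ValueError, match="unreachable"):
            sim.simulate_graph(small_panel, [("nowhere", "pop", 0.1)], seed=0)


class TestAdmixedIndividuals:
    def test_degenerate_mixture_is_pure_source(self, small_panel, rng):
        sources, panel = sim.simulate_sources(400, 2, [0.05, 0.05], seed=2)
        spec = AdmixtureSpec(["pop1", "pop2"], [1.0, 0.0], 1, 25)
        ds, truth = sim.simulate_admixed_individuals(spec, sources, panel, rng)
        assert set(truth.tracts["source"]) == {"pop1"}
        # genotype frequencies track source-1 frequencies
        f_obs = (ds.calls / 2).mean(axis=1)
        resid = f_obs - sources[0].allele_freqs
        assert abs(resid.mean()) < 0.01

    def test_ancestry_fraction_recovery(self):
        sources, panel = sim.simulate_sources(200, 2, [0.05, 0.05], seed=3)
        spec = AdmixtureSpec(["pop1", "pop2"], [0.7, 0.3], 10, 100)
        _, truth = sim.simulate_admixed_individuals(spec, sources, panel, seed=4)
        frac = truth.ancestry_fractions()["pop1"].mean()
        assert abs(frac - 0.7) < 0.02

    def test_mean_tract_length_is_inverse_generations(self):
        sources, panel = sim.simulate_sources(200, 2, [0.05, 0.05], seed=5)
        spec = AdmixtureSpec(["pop1", "pop2"], [0.5, 0.5], 10, 50)
        _, truth = sim.simulate_admixed_individuals(spec, sources, panel, seed=6)
        assert truth.mean_tract_length() == pytest.approx(0.1, rel=0.10)

    def test_tracts_tile_chromosomes(self):
        sources, panel = sim.simulate_sources(100, 2, [0.05, 0.05], seed=7)
        spec = AdmixtureSpec(["pop1", "pop2"], [0.5, 0.5], 5, 2)
        _, truth = sim.simulate_admixed_individuals(spec, sources, panel, seed=8)
        one = truth.tracts.query("individual == 'target000' and hap == 0 and chrom == '1'")
        one = one.sort_values("start_m")
        assert one["start_m"].iloc[0] == 0.0
        np.testing.assert_allclose(
            one["end_m"].iloc[:-1].to_numpy(), one["start_m"].iloc[1:].to_numpy()
        )

    def test_unknown_source_rejected(self, rng):
        sources, panel = sim.simulate_sources(50, 2, 0.05, seed=9)
        spec = AdmixtureSpec(["popX", "pop2"], [0.5, 0.5], 5, 1)
        with pytest.raises(KeyError):
            sim.simulate_admixed_individuals(spec, sources, panel, rng)

    def test_proportions_must_be_simplex(self):
        with pytest.raises(ValueError):
            AdmixtureSpec(["a", "b"], [0.6, 0.5], 5, 1)


class TestReads:
    def test_noiseless_majority_recovers_genotype(self, rng):
        sources, panel = sim.simulate_sources(300, 1, 0.05, seed=10)
        ds = sim.sample_individuals_from_freqs(sources[0].allele_freqs, panel, 3, "p", rng)
        obs = sim.simulate_reads(ds, mean_depth=30, seed=11, max_recorded_reads=0)
        covered = obs.depth > 0
        hom_alt = ds.calls == 2
        hom_ref = ds.calls == 0
        assert np.all(obs.n_ref[hom_alt & covered] == 0)
        assert np.all(obs.n_alt[hom_ref & covered] == 0)

    def test_missing_fraction_matches_poisson_zero_class(self, rng):
        sources, panel = sim.simulate_sources(5000, 1, 0.05, seed=12)
        ds = sim.sample_individuals_from_freqs(sources[0].allele_freqs, panel, 4, "p", rng)
        obs = sim.simulate_reads(ds, mean_depth=0.5, seed=13, max_recorded_reads=0)
        missing = (obs.depth == 0).mean()
        assert abs(missing - np.exp(-0.5)) < 0.02

    def test_terminal_damage_rate_round_trip(self, rng):
        sources, panel = sim.simulate_sources(500, 1, 0.05, seed=14)
        ds = sim.sample_individuals_from_freqs(sources[0].allele_freqs, panel, 1, "p", rng)
        obs = sim.simulate_reads(
            ds, mean_depth=10, damage_rate=0.2, seed=15, max_recorded_reads=4000
        )
        profile = damage_profile(obs.reads["p000"])
        assert profile.ct_rate[0] == pytest.approx(0.2, abs=0.03)
        assert profile.ga_rate[0] == pytest.approx(0.2, abs=0.03)

    def test_rate_validation(self, small_panel, rng):
        sources, panel = sim.simulate_sources(50, 1, 0.05, seed=16)
        ds = sim.sample_individuals_from_freqs(sources[0].allele_freqs, panel, 1, "p", rng)
        with pytest.raises(ValueError):
            sim.simulate_reads(ds, mean_depth=0)
        with pytest.raises(ValueError):
            sim.simulate_reads(ds, mean_depth=1, error_rate=1.5)


class TestPedigree:
    def test_identical_pair_is_same_genome(self, graph_freqs, small_panel):
        src = SourcePopulation("ANA", graph_freqs["ANA"])
        ds, truth = sim.simulate_pedigree(src, "identical", small_panel, seed=17)
        np.testing.assert_array_equal(ds.calls[:, 0], ds.calls[:, 1])
        assert truth.info["ibd2"] == pytest.approx(1.0)

    def test_parent_offspring_share_an_allele_everywhere(self, graph_freqs, small_panel):
        src = SourcePopulation("ANA", graph_freqs["ANA"])
        ds, truth = sim.simulate_pedigree(src, "parent-offspring", small_panel, seed=18)
        p, c = ds.calls[:, 0], ds.calls[:, 1]
        # a hom parent and opposite hom child would violate Mendel
        assert not np.any((p == 0) & (c == 2))
        assert not np.any((p == 2) & (c == 0))
        assert truth.info["ibd1"] == pytest.approx(1.0)

    def test_full_sib_ibd2_quarter(self, graph_freqs):
        panel = sim.make_panel(400, seed=19)
        src = SourcePopulation("ANA", graph_freqs["ANA"])
        ibd2 = [
            sim.simulate_pedigree(src, "full-sib", panel, seed=s)[1].info["ibd2"]
            for s in range(8)
        ]
        assert abs(np.mean(ibd2) - 0.25) < 0.05

    def test_unknown_relationship(self, graph_freqs, small_panel):
        src = SourcePopulation("ANA", graph_freqs["ANA"])
        with pytest.raises(ValueError):
            sim.simulate_pedigree(src, "cousin-twice-removed", small_panel, seed=0)


class TestSexCoverage:
    def test_female_full_efficiency(self):
        cov = sim.simulate_sex_coverage("F", 5.0, seed=20, x_efficiency=1.0)
        assert cov["x_ratio"] == pytest.approx(1.0, abs=0.05)
        assert cov["y_ratio"] == 0.0

    def test_male_defaults_near_04(self):
        cov = sim.simulate_sex_coverage("M", 1.0, seed=21)
        assert cov["x_ratio"] == pytest.approx(0.4, abs=0.05)
        assert cov["y_ratio"] == pytest.approx(0.4, abs=0.05)

    def test_female_defaults_near_08(self):
        cov = sim.simulate_sex_coverage("F", 1.0, seed=22)
        assert cov["x_ratio"] == pytest.approx(0.8, abs=0.05)
        assert cov["y_ratio"] == 0.0
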