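"""qpWave rank tests, qpAdm weights, cladality and sex-bias Z."""

import numpy as np
import pytest

from steppeadmix import fstats, qpadm, simulate as sim
from steppeadmix.genodata import GenotypeDataset
from steppeadmix.simulate import AdmixtureSpec, SourcePopulation


@pytest.fixture(scope="module")
def cohort():
    """Mid-size cohort: admixed target + sources + outgroups, pseudo-haploid."""
    panel = sim.make_panel(12_000, seed=40)
    freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, seed=41)
    rng = np.random.default_rng(42)
    spec = AdmixtureSpec(["WSH", "ANA"], [0.3, 0.7], 10, 16)
    sources = [SourcePopulation(n, freqs[n]) for n in ["WSH", "ANA"]]
    dip, _ = sim.simulate_admixed_individuals(spec, sources, panel, rng)
    calls, inds = [sim.pseudohaploid_sample(dip, 0.1, rng).calls], list(dip.individuals)
    for pop in sim.DEFAULT_OUTGROUPS + ["WSH", "ANA", "han"]:
        d = sim.sample_individuals_from_freqs(freqs[pop], panel, 12, pop, rng)
        calls.append(sim.pseudohaploid_sample(d, 0.1, rng).calls)
        inds += d.individuals
    ds = GenotypeDataset(panel, inds, np.concatenate(calls, axis=1))
    return fstats.group_frequencies(ds)


class TestF4Matrix:
    def test_entries_match_independent_f4_calls(self, cohort):
        fm = qpadm.build_f4_matrix("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        blocks = cohort.panel.block_ids(5.0, chroms=tuple(str(i) for i in range(1, 23)))
        # restrict the per-statistic computation to the complete-case SNP set
        pops = fm.left + fm.right
        mask = cohort.defined_mask(pops)
        sub = fstats.GroupFrequencies(
            cohort.panel, cohort.groups,
            np.where(mask[:, None], cohort.freq, np.nan), cohort.count,
        )
        for i, left in enumerate(fm.left[1:]):
            for j, right in enumerate(fm.right[1:]):
                r = fstats.f4(fm.left[0], left, fm.right[0], right, sub, blocks)
                assert fm.X[i, j] == pytest.approx(r.estimate, abs=1e-12)

    def test_too_few_outgroups_rejected(self, cohort):
        with pytest.raises(ValueError, match="outgroups must exceed"):
            qpadm.build_f4_matrix("target", ["WSH", "ANA"], ["african", "onge", "ami"], cohort)

    def test_population_on_both_sides_rejected(self, cohort):
        with pytest.raises(ValueError, match="both sides"):
            qpadm.build_f4_matrix("target", ["WSH"], ["african", "WSH", "onge"], cohort)

    def test_loo_matrices_average_back(self, cohort):
        fm = qpadm.build_f4_matrix("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        weights = fm.block_counts / fm.block_counts.sum()
        total = sum(
            fm.loo(j) * (1 - w) for j, w in enumerate(weights)
        ) / (len(weights) - 1)
        np.testing.assert_allclose(total, fm.X, atol=1e-12)


class TestRankTest:
    def test_saturated_rank_perfect_fit(self, cohort):
        fm = qpadm.build_f4_matrix("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        chisq, dof, p = qpadm.qpwave_rank_test(fm, min(fm.shape))
        assert chisq == pytest.approx(0.0, abs=1e-9)
        assert dof == 0 and p == 1.0

    def test_chisq_decreases_with_rank(self, cohort):
        fm = qpadm.build_f4_matrix("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        chis = [qpadm.qpwave_rank_test(fm, r)[0] for r in range(min(fm.shape) + 1)]
        assert all(a >= b - 1e-9 for a, b in zip(chis, chis[1:]))

    def test_deeply_diverged_pair_rejected_at_rank0(self, cohort):
        fm = qpadm.build_f4_matrix("WSH", ["ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        _, _, p = qpadm.qpwave_rank_test(fm, 0)
        assert p < 0.001

    def test_invalid_rank(self, cohort):
        fm = qpadm.build_f4_matrix("target", ["WSH"], sim.DEFAULT_OUTGROUPS, cohort)
        with pytest.raises(ValueError):
            qpadm.qpwave_rank_test(fm, 5)


class TestQpadmFit:
    def test_pure_source_recovered(self, cohort):
        """A target that IS (drifted from) ANA gets weight ~(0,1) ... here the
        admixed target at 0.3/0.7 must recover its simulated proportions."""
        model = qpadm.qpadm_fit("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert abs(model.weights[0] - 0.3) < 3 * model.se[0] + 0.02
        assert model.feasible

    def test_missing_needed_source_lowers_p(self, cohort):
        good = qpadm.qpadm_fit("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        # han is not a real source of the target; as the only partner of WSH
        # the model cannot match the f4 matrix
        bad = qpadm.qpadm_fit("target", ["WSH", "han"], sim.DEFAULT_OUTGROUPS, cohort)
        assert bad.p_value < good.p_value
        assert bad.p_value < 0.05

    def test_weights_never_clipped(self, cohort):
        # a 2-way model for a pure source population often goes slightly
        # out of [0,1]; weights must still sum to 1 and be reported as-is
        model = qpadm.qpadm_fit("ANA", ["target", "han"], sim.DEFAULT_OUTGROUPS, cohort)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert model.feasible == bool(np.all((model.weights >= 0) & (model.weights <= 1)))


class TestCladality:
    def test_same_population_both_sides_rejected(self, cohort):
        with pytest.raises(ValueError):
            qpadm.test_cladality("WSH", "WSH", sim.DEFAULT_OUTGROUPS, cohort)

    def test_diverged_pair_distinct(self, cohort):
        res = qpadm.test_cladality(
            "WSH", "ANA", sim.DEFAULT_OUTGROUPS, cohort, min_snps=5_000
        )
        assert res.status == "distinct"

    def test_insufficient_overlap_reported(self, cohort):
        res = qpadm.test_cladality(
            "WSH", "ANA", sim.DEFAULT_OUTGROUPS, cohort, min_snps=10**7
        )
        assert res.status == "insufficient-data" and res.p_value is None


class TestSexBias:
    def test_zero_when_proportions_equal(self):
        assert qpadm.sex_bias_z_score(0.5, 0.05, 0.5, 0.04) == 0.0

    def test_stated_arithmetic(self):
        z = qpadm.sex_bias_z_score(0.6, 0.05, 0.4, 0.05)
        assert z == pytest.approx(2.8284, abs=1e-3)

    def test_sign_positive_iff_autosomes_higher(self):
        assert qpadm.sex_bias_z_score(0.7, 0.1, 0.5, 0.1) > 0
        assert qpadm.sex_bias_z_score(0.3, 0.1, 0.5, 0.1) < 0

    def test_full_model_runs_on_both_chromosome_sets(self, cohort):
        res = qpadm.sex_bias_z("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, cohort)
        assert len(res) == 2
        assert res[0].z == pytest.approx(
            qpadm.sex_bias_z_score(
                res[0].p_autosomal, res[0].se_autosomal, res[0].p_x, res[0].se_x
            )
        )


def test_model_search_reports_first_fitting_model(cohort):
    best, table = qpadm.model_search(
        "target",
        [["WSH", "han"], ["WSH", "ANA"]],
        sim.DEFAULT_OUTGROUPS,
        cohort,
    )
    assert len(table) == 2
    assert best is not None and best.sources == ["WSH", "ANA"]
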