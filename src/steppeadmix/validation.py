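"""Recovery and calibration experiments on the synthetic study.

Each function runs a self-contained simulation experiment at the study's
default conditions (50k-SNP panel, 22 autosomes + X, 12 pseudo-haploid
individuals per reference population with 10% missingness, 16-individual
targets) and measures how well the corresponding method recovers the
planted truth.  They power both the validation test suite and the
reproduction script; all randomness is controlled by the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from . import admixdate, fstats, kinship, qc, qpadm
from . import simulate as sim
from .genodata import GenotypeDataset
from .simulate import AdmixtureSpec, SourcePopulation

PANEL_SNPS = 50_000
REF_N = 12
REF_MISSING = 0.10
TARGET_N = 16


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _panel(n_snps: int = PANEL_SNPS):
    return sim.make_panel(n_snps, seed=0)


def _cohort_frequencies(panel, seed, alpha=0.3, G=10, extra_pops=()):
    """Admixed target + sources + outgroups, pseudo-haploid, as GroupFrequencies."""
    rng = np.random.default_rng(seed)
    freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, rng)
    spec = AdmixtureSpec(["WSH", "ANA"], [alpha, 1 - alpha], G, TARGET_N)
    sources = [SourcePopulation(n, freqs[n]) for n in ["WSH", "ANA"]]
    dip, truth = sim.simulate_admixed_individuals(spec, sources, panel, rng)
    calls = [sim.pseudohaploid_sample(dip, REF_MISSING, rng).calls]
    inds = list(dip.individuals)
    for pop in sim.DEFAULT_OUTGROUPS + ["WSH", "ANA", *extra_pops]:
        d = sim.sample_individuals_from_freqs(freqs[pop], panel, REF_N, pop, rng)
        calls.append(sim.pseudohaploid_sample(d, REF_MISSING, rng).calls)
        inds += d.individuals
    ds = GenotypeDataset(panel, inds, np.concatenate(calls, axis=1))
    return fstats.group_frequencies(ds), freqs, dip, truth


# ---------------------------------------------------------------------------
# qpAdm weight recovery
# ---------------------------------------------------------------------------

def qpadm_weight_recovery(
    seed: int = 0,
    alphas=(0.1, 0.3, 0.5, 0.7, 0.9),
    seeds_per_alpha: int = 8,
) -> dict:
    """Two-way mixtures across the alpha grid: error and 2-sigma coverage."""
    panel = _panel()
    errors, covered, pvals = [], [], []
    seeds = iter(_seeds(seed, len(alphas) * seeds_per_alpha))
    for alpha in alphas:
        for _ in range(seeds_per_alpha):
            gf, *_ = _cohort_frequencies(panel, next(seeds), alpha=alpha)
            model = qpadm.qpadm_fit("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, gf)
            errors.append(abs(float(model.weights[0]) - alpha))
            covered.append(abs(float(model.weights[0]) - alpha) <= 2 * float(model.se[0]))
            pvals.append(model.p_value)
    return {
        "mean_abs_error": float(np.mean(errors)),
        "coverage_2se": float(np.mean(covered)),
        "n_fits": len(errors),
        "p_values": pvals,
    }


# ---------------------------------------------------------------------------
# qpWave null calibration
# ---------------------------------------------------------------------------

def qpwave_null_pvalues(seed: int = 0, n_seeds: int = 200, sister_drift: float = 0.02):
    """Rank-0 p-values for truly cladal sister populations."""
    panel = _panel()
    edges = sim.DEFAULT_GRAPH_EDGES + [
        ("ANA", "sister1", sister_drift),
        ("ANA", "sister2", sister_drift),
    ]
    ps = []
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        freqs = sim.simulate_graph(panel, edges, rng)
        calls, inds = [], []
        for pop in ["sister1", "sister2"] + sim.DEFAULT_OUTGROUPS:
            d = sim.sample_individuals_from_freqs(freqs[pop], panel, REF_N, pop, rng)
            calls.append(sim.pseudohaploid_sample(d, REF_MISSING, rng).calls)
            inds += d.individuals
        ds = GenotypeDataset(panel, inds, np.concatenate(calls, axis=1))
        gf = fstats.group_frequencies(ds)
        fm = qpadm.build_f4_matrix("sister1", ["sister2"], sim.DEFAULT_OUTGROUPS, gf)
        ps.append(qpadm.qpwave_rank_test(fm, 0)[2])
    return np.array(ps)


# ---------------------------------------------------------------------------
# Admixture-date recovery
# ---------------------------------------------------------------------------

def dating_recovery(seed: int = 0, generations=(5, 10, 20), n_seeds: int = 20) -> dict:
    """Pulse-age estimates and jackknife-CI coverage per true G."""
    panel = _panel()
    out = {}
    seeds = iter(_seeds(seed, len(generations) * n_seeds))
    for G in generations:
        est, se = [], []
        for _ in range(n_seeds):
            s = next(seeds)
            rng = np.random.default_rng(s)
            freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, rng)
            spec = AdmixtureSpec(["WSH", "ANA"], [0.3, 0.7], G, TARGET_N)
            sources = [SourcePopulation(n, freqs[n]) for n in ["WSH", "ANA"]]
            dip, _ = sim.simulate_admixed_individuals(spec, sources, panel, rng)
            ph = sim.pseudohaploid_sample(dip, REF_MISSING, rng)
            curve = admixdate.ancestry_covariance(ph, freqs["WSH"], freqs["ANA"])
            fit = admixdate.fit_decay(curve)
            if fit.detectable:
                est.append(fit.generations)
                se.append(fit.se_generations)
        est, se = np.array(est), np.array(se)
        out[G] = {
            "mean": float(est.mean()),
            "bias_pct": float(100 * (est.mean() - G) / G),
            "ci_covered": (np.abs(est - G) <= 2 * se).tolist(),
            "n": len(est),
        }
    return out


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_mismatch_linearity(seed: int = 0, n_reps: int = 4) -> dict:
    """Observed vs expected mismatch m0(1 - r/2) on simulated pedigrees."""
    panel = _panel()
    rng = np.random.default_rng(seed)
    freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, rng)
    src = SourcePopulation("ANA", freqs["ANA"])
    relations = {
        "unrelated": 0.0,
        "second-degree": 0.25,
        "parent-offspring": 0.5,
        "identical": 1.0,
    }
    # baseline from independent unrelated pairs
    m0s = []
    for s in _seeds(seed + 1, n_reps):
        dip, _ = sim.simulate_pedigree(src, "unrelated", panel, s)
        ph = sim.pseudohaploid_sample(dip, REF_MISSING, np.random.default_rng(s + 1))
        m0s.append(kinship.pairwise_mismatch(ph)["m"][0])
    m0 = float(np.mean(m0s))
    out = {"m0": m0, "relationships": {}}
    for rel, r in relations.items():
        ms, overlaps = [], []
        for s in _seeds(seed + 2 + int(r * 8), n_reps):
            dip, _ = sim.simulate_pedigree(src, rel, panel, s)
            ph = sim.pseudohaploid_sample(dip, REF_MISSING, np.random.default_rng(s + 1))
            row = kinship.pairwise_mismatch(ph).iloc[0]
            ms.append(row.m)
            overlaps.append(row.n_overlap)
        m_bar = float(np.mean(ms))
        expected = m0 * (1 - r / 2)
        # binomial SE of the mean mismatch over the pooled overlapping sites
        se = float(np.sqrt(expected * (1 - expected) / np.sum(overlaps)))
        out["relationships"][rel] = {
            "r": r, "observed_m": m_bar, "expected_m": expected, "binomial_se": se,
        }
    return out


def kinship_planted_pairs(seed: int = 0, cohort_size: int = 20) -> dict:
    """A cohort with one planted first- and one second-degree pair."""
    panel = _panel()
    rng = np.random.default_rng(seed)
    freqs = sim.simulate_graph(panel, sim.DEFAULT_GRAPH_EDGES, rng)
    src = SourcePopulation("ANA", freqs["ANA"])
    n_unrel = cohort_size - 4
    dip = sim.sample_individuals_from_freqs(freqs["ANA"], panel, n_unrel, "grp", rng)
    ph = sim.pseudohaploid_sample(dip, REF_MISSING, rng)
    s1, s2 = _seeds(seed + 5, 2)
    po = sim.pseudohaploid_sample(
        sim.simulate_pedigree(src, "parent-offspring", panel, s1)[0], REF_MISSING, rng
    )
    sd = sim.pseudohaploid_sample(
        sim.simulate_pedigree(src, "second-degree", panel, s2)[0], REF_MISSING, rng
    )
    from .genodata import Individual

    ids = [f"u{i}" for i in range(n_unrel)] + ["po1", "po2", "sd1", "sd2"]
    ds = GenotypeDataset(
        panel,
        [Individual(i, group_label="grp") for i in ids],
        np.concatenate([ph.calls, po.calls, sd.calls], axis=1),
    )
    table = kinship.kinship_table(ds)
    related = table[table.degree.isin(["identical", "first", "second"])]
    detected = {frozenset((r.id1, r.id2)): r.degree for r in related.itertuples()}
    truth = {frozenset(("po1", "po2")): "first", frozenset(("sd1", "sd2")): "second"}
    return {
        "detected": {tuple(sorted(k)): v for k, v in detected.items()},
        "true_positives": sum(detected.get(k) == v for k, v in truth.items()),
        "false_positives": len([k for k in detected if k not in truth]),
        "n_pairs_tested": len(table),
    }


# ---------------------------------------------------------------------------
# Sex typing and sex bias
# ---------------------------------------------------------------------------

def sex_typing_accuracy(seed: int = 0, n_individuals: int = 40, depth: float = 0.5) -> float:
    """Classification accuracy on simulated coverage at default efficiencies."""
    correct = 0
    for k, s in enumerate(_seeds(seed, n_individuals)):
        truth = "M" if k % 2 == 0 else "F"
        cov = sim.simulate_sex_coverage(truth, depth, seed=s)
        call = qc.assign_genetic_sex(cov["x_ratio"], cov["y_ratio"])
        correct += call.call == truth
    return correct / n_individuals


def sexbias_null_z(seed: int = 0, n_seeds: int = 40, G: int = 40):
    """Sex-bias Z under sex-unbiased admixture.

    The admixture age is set so that ancestry tracts (mean 1/G Morgans) are
    shorter than the 5 cM jackknife blocks, the regime where block
    independence — and hence the Z calibration — holds; see the methods
    note for the recent-admixture caveat.
    """
    panel = _panel()
    zs = []
    for s in _seeds(seed, n_seeds):
        gf, *_ = _cohort_frequencies(panel, s, alpha=0.3, G=G)
        res = qpadm.sex_bias_z("target", ["WSH", "ANA"], sim.DEFAULT_OUTGROUPS, gf)
        zs.append(res[0].z)
    return np.array(zs)


# ---------------------------------------------------------------------------
# Allele-frequency likelihood
# ---------------------------------------------------------------------------

def allele_frequency_interval_coverage(
    seed: int = 0, n_runs: int = 200, n_individuals: int = 20,
    depth: float = 2.0, true_f: float = 0.3,
) -> float:
    """Fraction of runs whose ±1.96 SE interval contains the true frequency."""
    from .snpfreq import likelihood_allele_frequency

    hits, runs = 0, 0
    for s in _seeds(seed, n_runs):
        r = np.random.default_rng(s)
        g = r.binomial(2, true_f, size=n_individuals)
        n = r.poisson(depth, size=n_individuals)
        d = r.binomial(n, g / 2 * 0.999 + (1 - g / 2) * 0.001)
        if n.sum() == 0:
            continue
        est = likelihood_allele_frequency(d, n)
        lo, hi = est.interval()
        hits += lo <= true_f <= hi
        runs += 1
    return hits / runs


# ---------------------------------------------------------------------------
# f-statistic oracle agreement
# ---------------------------------------------------------------------------

def fstat_bruteforce_max_diff(seed: int = 0, n_snps: int = 1_000) -> float:
    """Max |vectorized - per-SNP-loop| over random f3/f4 fixtures."""
    panel = sim.make_panel(n_snps, seed=seed)
    rng = np.random.default_rng(seed + 1)
    groups = {p: rng.random(len(panel)) for p in "ABCD"}
    gf = fstats.GroupFrequencies(
        panel, list(groups),
        np.column_stack(list(groups.values())),
        np.full((len(panel), 4), 10, dtype=np.int32),
    )
    blocks = fstats.default_block_ids(panel)
    auto = blocks >= 0
    a, b, c, d = (groups[p][auto] for p in "ABCD")
    worst = 0.0
    f4_loop = float(np.sum([(ai - bi) * (ci - di) for ai, bi, ci, di in zip(a, b, c, d)]) / len(a))
    worst = max(worst, abs(fstats.f4("A", "B", "C", "D", gf, blocks).estimate - f4_loop))
    f3_loop = float(np.sum([(ci - ai) * (ci - bi) for ai, bi, ci in zip(a, b, c)]) / len(a))
    worst = max(worst, abs(fstats.f3("A", "B", "C", gf, blocks).estimate - f3_loop))
    return worst
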