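"""The bundled synthetic study: one coherent cohort with planted truths.

This builds the default end-to-end dataset the pipeline, the analysis
drivers and the acceptance checks all run on: a ten-population admixture
graph (two source clades, each carrying outgroups that share drift with
its source, plus a deep outgroup), pseudo-haploid reference panels, an
admixed target population with known mixture proportions and admixture
time, planted kin pairs, and per-individual sex/coverage truth.

Default conditions (chosen once as a realistic desk-scale cohort):
50,000 autosomal SNPs on 22 chromosomes of 1 Morgan each plus X; 12
pseudo-haploid individuals per reference population with 10% missingness;
a 16-individual target admixed 30% WSH / 70% ANA ten generations before
sampling; read depth 1x with 15% terminal damage on UDG-half libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import simulate as sim
from .genodata import GenotypeDataset, Individual
from .simulate import (
    DEFAULT_GRAPH_EDGES,
    DEFAULT_OUTGROUPS,
    AdmixtureSpec,
    GroundTruth,
    SourcePopulation,
)

DEFAULT_N_SNPS = 50_000
DEFAULT_REF_N = 12
DEFAULT_REF_MISSING = 0.10
DEFAULT_TARGET = dict(sources=("WSH", "ANA"), proportions=(0.3, 0.7),
                      generations=10, n_individuals=16)


@dataclass
class SyntheticStudy:
    panel: object
    freqs: dict[str, np.ndarray]  # true population frequencies per graph node
    references: GenotypeDataset  # pseudo-haploid reference individuals, labelled
    target: GenotypeDataset  # pseudo-haploid target individuals
    target_truth: GroundTruth
    target_diploid: GenotypeDataset
    outgroups: list[str] = field(default_factory=lambda: list(DEFAULT_OUTGROUPS))
    sources: list[str] = field(default_factory=list)
    proportions: list[float] = field(default_factory=list)
    generations: int = 0

    def combined(self) -> GenotypeDataset:
        """References and targets in one pseudo-haploid dataset."""
        calls = np.concatenate([self.references.calls, self.target.calls], axis=1)
        inds = list(self.references.individuals) + list(self.target.individuals)
        return GenotypeDataset(self.panel, inds, calls, ploidy_mode="pseudo-haploid")

    def source_populations(self) -> list[SourcePopulation]:
        return [SourcePopulation(n, f) for n, f in self.freqs.items()]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """One global seed fans out to named per-stage streams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def make_study(
    seed: int = 0,
    n_snps: int = DEFAULT_N_SNPS,
    ref_n: int = DEFAULT_REF_N,
    ref_missing: float = DEFAULT_REF_MISSING,
    target: dict | None = None,
) -> SyntheticStudy:
    """Build the default synthetic cohort; deterministic given ``seed``."""
    target = dict(DEFAULT_TARGET if target is None else target)
    panel = sim.make_panel(n_snps, _stage_rng(seed, 0))
    freqs = sim.simulate_graph(panel, DEFAULT_GRAPH_EDGES, _stage_rng(seed, 1))

    ref_pops = list(DEFAULT_OUTGROUPS) + list(target["sources"])
    if "han" not in ref_pops:  # alternative-source panel for model comparison
        ref_pops.append("han")
    rng = _stage_rng(seed, 2)
    ref_calls = []
    ref_inds: list[Individual] = []
    for pop in ref_pops:
        dip = sim.sample_individuals_from_freqs(freqs[pop], panel, ref_n, pop, rng)
        ph = sim.pseudohaploid_sample(dip, ref_missing, rng)
        ref_calls.append(ph.calls)
        ref_inds.extend(ph.individuals)
    references = GenotypeDataset(
        panel, ref_inds, np.concatenate(ref_calls, axis=1), ploidy_mode="pseudo-haploid"
    )

    spec = AdmixtureSpec(
        list(target["sources"]),
        list(target["proportions"]),
        int(target["generations"]),
        int(target["n_individuals"]),
    )
    sources = [SourcePopulation(n, freqs[n]) for n in target["sources"]]
    dip, truth = sim.simulate_admixed_individuals(
        spec, sources, panel, _stage_rng(seed, 3)
    )
    ph_target = sim.pseudohaploid_sample(dip, ref_missing, _stage_rng(seed, 4))
    for ind in ph_target.individuals:
        ind.genetic_sex = truth.sex[ind.individual_id]
    return SyntheticStudy(
        panel=panel,
        freqs=freqs,
        references=references,
        target=ph_target,
        target_truth=truth,
        target_diploid=dip,
        sources=list(target["sources"]),
        proportions=list(target["proportions"]),
        generations=int(target["generations"]),
    )
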