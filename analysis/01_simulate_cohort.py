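#!/usr/bin/env python
"""Build the synthetic steppe cohort and export its inputs and ground truth.

Creates the default study: a ten-population admixture graph on a 50k-SNP
panel (22 autosomes + X), pseudo-haploid reference panels, and a
16-individual target admixed 30% WSH / 70% ANA ten generations before
sampling.  Writes the EIGENSTRAT trio the rest of the pipeline consumes
plus the tract/ancestry truth tables used to score recovery.
"""
from pathlib import Path

from steppeadmix.genodata import write_eigenstrat
from steppeadmix.study import make_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

study = make_study(seed=0)
combined = study.combined()
write_eigenstrat(combined, OUT / "cohort")
study.target_truth.tracts.to_csv(OUT / "truth_tracts.tsv", sep="\t", index=False)
study.target_truth.ancestry_fractions().to_csv(OUT / "truth_ancestry.tsv", sep="\t")

frac = study.target_truth.ancestry_fractions().mean()
print(f"cohort: {combined.n_individuals} individuals x {len(study.panel)} SNPs")
print(f"target truth: {study.proportions[0]:.0%} {study.sources[0]} pulse "
      f"{study.generations} generations ago")
print(f"realized mean ancestry: {frac[study.sources[0]]:.3f} {study.sources[0]}")
print(f"wrote {OUT}/cohort.{{geno,snp,ind}} and truth tables")
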