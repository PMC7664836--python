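#!/usr/bin/env python
"""Read-count maximum-likelihood allele frequencies at phenotype loci.

Designates five panel sites as stand-ins for the classic Eurasian
phenotype SNPs (lactase persistence, pigmentation, alcohol metabolism,
EDAR) and estimates each derived-allele frequency per group from raw
read counts at 2x coverage.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from steppeadmix import simulate as sim, snpfreq
from steppeadmix.study import make_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

study = make_study(seed=0)
idx = np.linspace(0, len(study.panel) - 1, 5).astype(int)
loci = pd.DataFrame({
    "snp_id": study.panel.table["snp_id"].iloc[idx].to_list(),
    "rsid": snpfreq.PHENOTYPE_PANEL["rsid"],
    "gene": snpfreq.PHENOTYPE_PANEL["gene"],
    "effect_allele": "alt",
})
obs = sim.simulate_reads(study.target_diploid, mean_depth=2.0, seed=800,
                         max_recorded_reads=0)
table = snpfreq.frequency_table(obs, loci, {i: "target" for i in obs.individual_ids})
table = table.merge(loci[["snp_id", "rsid", "gene"]], on="snp_id")
# true frequency of the mixed gene pool at those sites
p_true = (0.3 * study.freqs["WSH"] + 0.7 * study.freqs["ANA"])[idx]
table["true_f"] = np.round(p_true, 3)
table.to_csv(OUT / "phenotype_frequencies.tsv", sep="\t", index=False)
print(table[["rsid", "gene", "f_hat", "se", "true_f", "n_individuals"]].to_string(index=False))
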