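#!/usr/bin/env python
"""Outgroup-f3 affinity ranking and f4 cladality scan for the target.

f3(target, X; african) ranks candidate populations by shared drift with
the admixed target; f4(target, ANA; X, african) asks which references
break the (target, ANA) cladality - the WSH admixture should flag
western-related populations at |Z| > 3.
"""
from pathlib import Path

from steppeadmix import fstats
from steppeadmix.study import make_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

study = make_study(seed=0)
gf = fstats.group_frequencies(study.combined())
blocks = fstats.default_block_ids(study.panel)
candidates = [g for g in gf.groups if g not in ("target", "african")]

scan = fstats.outgroup_f3_scan("target", candidates, "african", gf, blocks)
scan.to_csv(OUT / "outgroup_f3.tsv", sep="\t", index=False)
print("outgroup-f3 ranking (shared drift with target):")
print(scan.head(4).to_string(index=False))

refs = [g for g in candidates if g not in ("ANA",)]
clad = fstats.f4_symmetry_scan("target", "ANA", refs, "african", gf, blocks)
clad.to_csv(OUT / "f4_cladality_scan.tsv", sep="\t", index=False)
flagged = clad[clad.flagged]
print(f"\nf4(target, ANA; X, african): {len(flagged)}/{len(clad)} references "
      f"flagged at |Z|>3 -> {', '.join(flagged.reference)}")
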