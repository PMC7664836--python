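import numpy as np
import pandas as pd

from steppeadmix.fstats import GroupFrequencies
from steppeadmix.genodata import SnpPanel


def tiny_panel(n, chroms=None, ref="A", alt="G"):
    """Hand-built panel: one SNP per listed chromosome position."""
    chroms = chroms or [str(i % 22 + 1) for i in range(n)]
    rows = []
    counters = {}
    for c in chroms:
        k = counters.get(c, 0)
        counters[c] = k + 1
        rows.append((f"s{c}_{k}", c, 0.1 + 0.2 * k, 1000 * (k + 1), ref, alt))
    order = sorted(range(len(rows)), key=lambda i: (int(rows[i][1]) if rows[i][1].isdigit() else 99, rows[i][3]))
    rows = [rows[i] for i in order]
    return SnpPanel(
        pd.DataFrame(rows, columns=["snp_id", "chrom", "genetic_pos", "physical_pos", "ref", "alt"])
    )


def freqs_from_arrays(panel, groups):
    """GroupFrequencies straight from per-group frequency vectors."""
    names = list(groups)
    freq = np.column_stack([np.asarray(groups[g], dtype=float) for g in names])
    count = np.where(np.isnan(freq), 0, 10).astype(np.int32)
    return GroupFrequencies(panel, names, freq, count)
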