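"""Relatedness from pairwise mismatch rates of pseudo-haploid genotypes.

For a pair of individuals the mismatch rate m is the fraction of
autosomal sites, called in both, where the two sampled alleles differ.
Unrelated individuals from one population share a baseline rate m0; a
pair with relatedness coefficient r has expected mismatch m0 (1 - r/2)
(one quarter of sampled allele pairs land on the shared IBD copy per unit
of kinship), so r is estimated as r_hat = 2 (1 - m/m0).  Degrees are
assigned by midpoint cutoffs on m/m0 between the expected values for
identical/duplicate (0.5), first degree (0.75), second degree (0.875) and
unrelated (1.0) pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset

DEGREE_CUTOFFS = (
    (0.625, "identical"),
    (0.8125, "first"),
    (0.90625, "second"),
)
MIN_OVERLAP = 3000


def pairwise_mismatch(dataset: GenotypeDataset) -> pd.DataFrame:
    """All-pairs mismatch table (id1, id2, n_overlap, n_mismatch, m).

    Uses autosomal pseudo-haploid calls; pairs with no overlap get m NaN.
    Fewer than two individuals yields an empty table.
    """
    if dataset.ploidy_mode != "pseudo-haploid":
        raise ValueError("pairwise mismatch is defined on pseudo-haploid calls")
    auto = dataset.panel.autosomal_mask()
    calls = dataset.calls[auto]
    ids = dataset.individual_ids
    if len(ids) < 2:
        return pd.DataFrame(columns=["id1", "id2", "n_overlap", "n_mismatch", "m"])
    called = (calls != MISSING).astype(np.float32)
    alt = (calls == 2).astype(np.float32)
    ref = called - alt
    overlap = called.T @ called
    mismatch = alt.T @ ref + ref.T @ alt
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            n_ov = int(overlap[i, j])
            n_mm = int(round(mismatch[i, j]))
            rows.append(
                (ids[i], ids[j], n_ov, n_mm, n_mm / n_ov if n_ov > 0 else np.nan)
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "n_overlap", "n_mismatch", "m"])


def estimate_baseline(
    mismatch: pd.DataFrame, group_labels: dict[str, str] | None = None
) -> dict[str, float]:
    """Per-group baseline mismatch m0 among (presumed) unrelated pairs.

    Robust estimator: median of within-group pairwise rates after one
    round of excluding pairs below 0.75x the median (close relatives pull
    the rate down, never up).  Groups with fewer than 3 eligible pairs
    fall back to the global median, with a warning.
    """
    valid = mismatch.dropna(subset=["m"])
    if not len(valid):
        raise ValueError("no pairs with overlapping data; supply m0 externally")

    def robust_median(m: np.ndarray) -> float:
        med = float(np.median(m))
        kept = m[m >= 0.75 * med]
        return float(np.median(kept)) if len(kept) else med

    global_m0 = robust_median(valid["m"].to_numpy())
    if group_labels is None:
        return {"__global__": global_m0}
    out = {"__global__": global_m0}
    groups = set(group_labels.values())
    for g in groups:
        members = {i for i, lab in group_labels.items() if lab == g}
        sub = valid[valid["id1"].isin(members) & valid["id2"].isin(members)]
        if len(sub) >= 3:
            out[g] = robust_median(sub["m"].to_numpy())
        else:
            warnings.warn(
                f"group {g!r} has only {len(sub)} pairs; using global baseline",
                stacklevel=2,
            )
            out[g] = global_m0
    return out


def classify_relationship(
    m: float, m0: float, n_overlap: int, min_overlap: int = MIN_OVERLAP
) -> tuple[float, str]:
    """Relatedness coefficient and degree from a mismatch rate and baseline."""
    if m0 <= 0:
        raise ValueError("baseline m0 must be positive")
    if n_overlap < min_overlap:
        return np.nan, "insufficient"
    r_hat = 2.0 * (1.0 - m / m0)
    if m > 1.2 * m0:
        warnings.warn(
            f"mismatch {m:.3f} far above baseline {m0:.3f}: possible contamination "
            "or ancestry mismatch",
            stacklevel=2,
        )
        return r_hat, "unrelated"
    ratio = m / m0
    for cutoff, degree in DEGREE_CUTOFFS:
        if ratio <= cutoff:
            return r_hat, degree
    return r_hat, "unrelated"


def kinship_table(
    dataset: GenotypeDataset,
    group_labels: dict[str, str] | None = None,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """Full pair table: id1, id2, n_overlap, m, m0, r_hat, degree."""
    mm = pairwise_mismatch(dataset)
    if group_labels is None:
        group_labels = {
            ind.individual_id: ind.group_label for ind in dataset.individuals
        }
    m0 = estimate_baseline(mm, group_labels)
    rows = []
    for rec in mm.itertuples(index=False):
        g1, g2 = group_labels.get(rec.id1), group_labels.get(rec.id2)
        base = m0[g1] if g1 == g2 and g1 in m0 else m0["__global__"]
        if np.isnan(rec.m):
            r_hat, degree = np.nan, "insufficient"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r_hat, degree = classify_relationship(rec.m, base, rec.n_overlap, min_overlap)
        rows.append((rec.id1, rec.id2, rec.n_overlap, rec.m, base, r_hat, degree))
    return pd.DataFrame(
        rows, columns=["id1", "id2", "n_overlap", "m", "m0", "r_hat", "degree"]
    )
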