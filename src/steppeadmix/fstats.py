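"""Allele-frequency based f-statistics with weighted block jackknife.

f4(A, B; C, D) is the average over SNPs of (a-b)(c-d) where lower-case
letters are sample allele frequencies; f3(A, B; C) averages (c-a)(c-b)
with C the apex.  Standard errors come from a delete-one-block weighted
jackknife over contiguous genetic-distance blocks (5 cM by default), with
per-block SNP counts as weights.  Sites are used complete-case per
statistic: a SNP is dropped whenever any involved population lacks data.
No small-sample or inbreeding corrections are applied, matching plain
f4-mode computation on pseudo-haploid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import AUTOSOMES, MISSING, GenotypeDataset, SnpPanel


@dataclass
class GroupFrequencies:
    """Per-(group, SNP) alternate-allele sample frequency and draw count.

    A pseudo-haploid individual contributes one allele draw per called
    site, a diploid individual two.  Frequencies are NaN where a group has
    no data.
    """

    panel: SnpPanel
    groups: list[str]
    freq: np.ndarray  # (n_snps, n_groups), NaN where count == 0
    count: np.ndarray  # (n_snps, n_groups) allele draws

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.groups)}

    def col(self, group: str) -> np.ndarray:
        return self.freq[:, self._index[group]]

    def defined_mask(self, pops) -> np.ndarray:
        m = np.ones(len(self.panel), dtype=bool)
        for p in pops:
            m &= ~np.isnan(self.col(p))
        return m


def group_frequencies(dataset: GenotypeDataset, grouping: dict | None = None) -> GroupFrequencies:
    """Sample allele frequencies per group label.

    ``grouping`` maps individual id -> group label; by default the
    individuals' own ``group_label`` is used.  Empty groups raise.
    """
    if grouping is None:
        grouping = {ind.individual_id: ind.group_label for ind in dataset.individuals}
    groups = list(dict.fromkeys(grouping.values()))
    draws_per_ind = 1 if dataset.ploidy_mode == "pseudo-haploid" else 2
    n = len(dataset.panel)
    freq = np.full((n, len(groups)), np.nan)
    count = np.zeros((n, len(groups)), dtype=np.int32)
    ids = dataset.individual_ids
    for gi, g in enumerate(groups):
        cols = [ids.index(i) for i, lab in grouping.items() if lab == g and i in ids]
        if not cols:
            raise ValueError(f"group {g!r} has no individuals")
        sub = dataset.calls[:, cols]
        called = sub != MISSING
        alt_draws = np.where(called, sub, 0).sum(axis=1) / (2 // draws_per_ind)
        total = called.sum(axis=1) * draws_per_ind
        count[:, gi] = total
        with np.errstate(invalid="ignore"):
            freq[:, gi] = np.where(total > 0, alt_draws / np.maximum(total, 1), np.nan)
    return GroupFrequencies(dataset.panel, groups, freq, count)


@dataclass
class FStatResult:
    statistic: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps_used: int


def weighted_block_jackknife(theta_hat, loo_estimates, block_weights):
    """Combine delete-one-block estimates with the weighted jackknife.

    ``theta_hat`` is the full-data estimate (scalar or vector),
    ``loo_estimates`` the delete-one estimates stacked on axis 0 and
    ``block_weights`` the per-block weights (e.g. SNP counts).  Returns the
    bias-corrected jackknife estimate and its standard error; with equal
    weights this reduces to the textbook delete-one jackknife.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    loo = np.asarray(loo_estimates, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    g = len(w)
    if g < 2:
        raise ValueError("need at least 2 blocks")
    if np.any(w <= 0):
        raise ValueError("block weights must be positive")
    n = w.sum()
    h = n / w
    shape = (g,) + (1,) * theta_hat.ndim
    hb = h.reshape(shape)
    theta_j = g * theta_hat - ((1 - w / n).reshape(shape) * loo).sum(axis=0)
    tau = hb * theta_hat - (hb - 1) * loo
    var = ((tau - theta_j) ** 2 / (hb - 1)).sum(axis=0) / g
    return theta_j, np.sqrt(var)


def jackknife_covariance(theta_hat, loo_estimates, block_weights):
    """Weighted-jackknife covariance matrix of a vector statistic."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    loo = np.asarray(loo_estimates, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    g = len(w)
    h = (w.sum() / w)[:, None]
    theta_j = g * theta_hat - ((1 - w / w.sum())[:, None] * loo).sum(axis=0)
    tau = h * theta_hat - (h - 1) * loo
    d = tau - theta_j
    return (d.T / (h[:, 0] - 1)) @ d / g


def _blocked_mean_stat(products: np.ndarray, block_ids: np.ndarray, mask: np.ndarray):
    """Full and delete-one-block means of a per-SNP product statistic."""
    use = mask & (block_ids >= 0)
    if not use.any():
        raise ValueError("no usable SNPs for this statistic")
    b = block_ids[use]
    uniq, inv = np.unique(b, return_inverse=True)
    sums = np.bincount(inv, weights=products[use])
    counts = np.bincount(inv).astype(float)
    if len(uniq) < 2:
        raise ValueError("need at least 2 jackknife blocks with data")
    S, N = sums.sum(), counts.sum()
    theta = S / N
    loo = (S - sums) / (N - counts)
    return theta, loo, counts, int(N)


def _fstat(name, pops, products, freqs: GroupFrequencies, block_ids, mask) -> FStatResult:
    theta, loo, wts, n_used = _blocked_mean_stat(products, block_ids, mask)
    _, se = weighted_block_jackknife(theta, loo, wts)
    z = theta / se if se > 0 else np.inf * np.sign(theta) if theta != 0 else 0.0
    return FStatResult(name, tuple(pops), float(theta), float(se), float(z),
                       n_blocks=len(wts), n_snps_used=n_used)


def default_block_ids(panel: SnpPanel, block_cm: float = 5.0, chroms=AUTOSOMES) -> np.ndarray:
    return panel.block_ids(block_cm, chroms=chroms)


def f4(A, B, C, D, freqs: GroupFrequencies, block_ids: np.ndarray) -> FStatResult:
    """f4(A, B; C, D) with block-jackknife SE (f4-mode, not D-normalized)."""
    a, b, c, d = (freqs.col(p) for p in (A, B, C, D))
    mask = freqs.defined_mask((A, B, C, D))
    prod = np.where(mask, (a - b) * (c - d), 0.0)
    return _fstat("f4", (A, B, C, D), prod, freqs, block_ids, mask)


def f3(A, B, C, freqs: GroupFrequencies, block_ids: np.ndarray) -> FStatResult:
    """f3(A, B; C) = mean (c-a)(c-b), apex C (outgroup-f3 when C is the outgroup)."""
    a, b, c = (freqs.col(p) for p in (A, B, C))
    mask = freqs.defined_mask((A, B, C))
    prod = np.where(mask, (c - a) * (c - b), 0.0)
    return _fstat("f3", (A, B, C), prod, freqs, block_ids, mask)


def outgroup_f3_scan(
    target: str, candidates, outgroup: str, freqs: GroupFrequencies, block_ids: np.ndarray
) -> pd.DataFrame:
    """Rank candidate populations by shared drift with the target.

    Computes f3(target, X; outgroup) for every candidate and sorts
    descending — the top candidate shares the most drift with the target.
    """
    rows = []
    for cand in candidates:
        r = f3(target, cand, outgroup, freqs, block_ids)
        rows.append((cand, r.estimate, r.se, r.z, r.n_snps_used, r.n_blocks))
    table = pd.DataFrame(
        rows, columns=["candidate", "estimate", "se", "z", "n_snps", "n_blocks"]
    ).sort_values("estimate", ascending=False, kind="stable").reset_index(drop=True)
    return table


def f4_symmetry_scan(
    pop1: str, pop2: str, reference_list, outgroup: str,
    freqs: GroupFrequencies, block_ids: np.ndarray, z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Test (pop1, pop2) cladality against each reference population.

    Rows are f4(pop1, pop2; X, outgroup); |Z| above the threshold flags a
    reference X that is asymmetrically related to the pair, i.e. evidence
    against cladality.
    """
    rows = []
    for ref in reference_list:
        r = f4(pop1, pop2, ref, outgroup, freqs, block_ids)
        rows.append((ref, r.estimate, r.se, r.z, abs(r.z) > z_threshold, r.n_snps_used))
    return pd.DataFrame(
        rows, columns=["reference", "estimate", "se", "z", "flagged", "n_snps"]
    )
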