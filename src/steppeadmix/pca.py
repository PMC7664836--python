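"""PCA of reference individuals with least-squares projection of ancient ones.

Components are computed from (modern, high-quality) reference individuals
only: genotypes are centered per SNP and scaled by sqrt(p(1-p)) with p
the mean allele frequency, then decomposed by SVD.  Ancient individuals,
whose missingness is heavy and non-random, are never used to compute
components and never imputed: each is projected by ordinary least squares
of its observed normalized calls on the SNP loadings, restricted to its
observed sites (the "lsqproject" strategy).  Axis signs are anchored so a
designated reference population has positive mean score on every
component, making output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset

MIN_PROJECTION_SNPS = 5000


@dataclass
class PcaModel:
    mean: np.ndarray  # per-SNP mean genotype (kept SNPs)
    norm: np.ndarray  # per-SNP scale sqrt(p(1-p))
    loadings: np.ndarray  # (n_kept_snps, k)
    reference_scores: pd.DataFrame  # individual x PC
    variance_explained: np.ndarray
    snp_mask: np.ndarray  # kept SNPs within the panel


@dataclass
class Projection:
    individual_id: str
    scores: np.ndarray | None
    n_snps_used: int
    status: str  # ok / insufficient-data


def fit_pca(reference: GenotypeDataset, k: int = 10, anchor_group: str | None = None) -> PcaModel:
    """Fit PCs on reference individuals (missing calls mean-imputed).

    Monomorphic SNPs are dropped.  ``k`` must not exceed the smaller of
    the individual and SNP counts.
    """
    n_ind = reference.n_individuals
    if k > min(n_ind, len(reference.panel)):
        raise ValueError(f"k={k} exceeds min(n_individuals, n_snps)")
    G = reference.calls.astype(float).T  # (n_ind, n_snps)
    G[G == MISSING] = np.nan
    if reference.ploidy_mode == "pseudo-haploid":
        G = G / 1.0  # calls 0/2 keep the same scale as diploid dosage
    mean = np.nanmean(G, axis=0)
    p = mean / 2.0
    norm = np.sqrt(np.clip(p * (1 - p), 0.0, None))
    keep = (norm > 0) & ~np.isnan(mean)
    G = G[:, keep]
    mean_k, norm_k = mean[keep], norm[keep]
    X = (np.where(np.isnan(G), mean_k, G) - mean_k) / norm_k
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    scores = U * s
    loadings = Vt.T
    # deterministic sign: anchor population mean positive on each axis
    if anchor_group is not None:
        anchor_rows = [
            i for i, ind in enumerate(reference.individuals) if ind.group_label == anchor_group
        ]
    else:
        anchor_rows = [0]
    sign = np.sign(scores[anchor_rows].mean(axis=0))
    sign[sign == 0] = 1.0
    scores *= sign
    loadings *= sign
    var = s**2 / (s**2).sum()
    ref_scores = pd.DataFrame(
        scores,
        index=reference.individual_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaModel(mean_k, norm_k, loadings, ref_scores, var, keep)


def project(
    calls: np.ndarray, model: PcaModel, individual_id: str = "",
    min_snps: int = MIN_PROJECTION_SNPS,
) -> Projection:
    """Least-squares projection of one individual's calls onto the model.

    Only the individual's observed SNPs enter the normal equations; below
    ``min_snps`` observed sites an insufficient-data result is returned.
    """
    calls = np.asarray(calls, dtype=float)[model.snp_mask]
    obs = calls != MISSING
    n_obs = int(obs.sum())
    if n_obs < min_snps:
        return Projection(individual_id, None, n_obs, "insufficient-data")
    x = (calls[obs] - model.mean[obs]) / model.norm[obs]
    L = model.loadings[obs]
    scores, *_ = np.linalg.lstsq(L, x, rcond=None)
    return Projection(individual_id, scores, n_obs, "ok")


def project_dataset(
    dataset: GenotypeDataset, model: PcaModel, min_snps: int = MIN_PROJECTION_SNPS
) -> pd.DataFrame:
    """Project every individual; returns a scores table with n_snps_used."""
    rows = []
    k = model.loadings.shape[1]
    for j, ind in enumerate(dataset.individuals):
        pr = project(dataset.calls[:, j], model, ind.individual_id, min_snps)
        scores = pr.scores if pr.scores is not None else [np.nan] * k
        rows.append([ind.individual_id, *scores, pr.n_snps_used, pr.status])
    return pd.DataFrame(
        rows,
        columns=["individual_id", *(f"PC{i + 1}" for i in range(k)), "n_snps_used", "status"],
    )
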