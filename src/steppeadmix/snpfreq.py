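"""Maximum-likelihood allele frequencies for phenotype SNPs from read counts.

Low coverage makes per-individual genotype calls at single loci
unreliable, so the population frequency f of the derived allele is
estimated directly from read counts: with Hardy-Weinberg genotype
probabilities Binom(g; 2, f) and a per-read error rate epsilon,

    L(f) = prod_ind sum_{g in 0,1,2} Binom(g; 2, f) Binom(d; n, p_g),
    p_g = (g/2)(1 - eps) + (1 - g/2) eps,

where d of n reads carry the derived allele.  The MLE is found on a
0.001 grid and refined by golden-section search; the standard error comes
from the curvature of log L at the optimum, replaced at boundary MLEs by
the one-sided distance where log L drops by 0.5.

The default locus panel carries the five classic Eurasian phenotype SNPs
(lactase persistence, skin pigmentation, alcohol metabolism, and the EDAR
epithelial variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import binom

from .genodata import ReadObservations

DEFAULT_ERROR_RATE = 0.001
GRID_STEP = 0.001

# rsid, gene, trait, effect allele relative to the panel (derived)
PHENOTYPE_PANEL = pd.DataFrame(
    [
        ("rs4988235", "LCT/MCM6", "lactase persistence"),
        ("rs3827760", "EDAR", "shovel-shaped incisors / hair thickness"),
        ("rs1800414", "OCA2", "skin pigmentation"),
        ("rs1426654", "SLC24A5", "skin pigmentation"),
        ("rs1229984", "ADH1B", "alcohol metabolism"),
    ],
    columns=["rsid", "gene", "trait"],
)


@dataclass
class FrequencyEstimate:
    snp_id: str
    group: str
    f_hat: float
    se: float  # one-sided interval half-width at boundary MLEs
    loglik: float
    n_individuals: int
    total_reads: int
    boundary: bool

    def interval(self, z: float = 1.96) -> tuple[float, float]:
        lo, hi = self.f_hat - z * self.se, self.f_hat + z * self.se
        return max(lo, 0.0), min(hi, 1.0)


def _loglik_grid(n_der, n_tot, error_rate):
    """Per-individual log P(reads | g) for g = 0, 1, 2 and a grid evaluator."""
    n_der = np.asarray(n_der, dtype=int)
    n_tot = np.asarray(n_tot, dtype=int)
    p_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    # (n_ind, 3): log Binom(d; n, p_g)
    read_ll = binom.logpmf(n_der[:, None], n_tot[:, None], p_g[None, :])

    def loglik(f: np.ndarray) -> np.ndarray:
        f = np.atleast_1d(np.clip(f, 0.0, 1.0))
        prior = np.stack(
            [(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1
        )
        with np.errstate(divide="ignore"):
            lp = np.log(prior)
        total = logsumexp(lp[:, None, :] + read_ll[None, :, :], axis=-1).sum(axis=-1)
        return total

    return loglik


def likelihood_allele_frequency(
    n_derived,
    n_total,
    error_rate: float = DEFAULT_ERROR_RATE,
    snp_id: str = "",
    group: str = "",
) -> FrequencyEstimate:
    """MLE of the derived-allele frequency from per-individual read counts."""
    n_derived = np.asarray(n_derived, dtype=int)
    n_total = np.asarray(n_total, dtype=int)
    has_data = n_total > 0
    if not has_data.any():
        raise ValueError("no individual has any reads at this locus")
    n_derived, n_total = n_derived[has_data], n_total[has_data]
    loglik = _loglik_grid(n_derived, n_total, error_rate)

    grid = np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP)
    ll = loglik(grid)
    i_best = int(np.argmax(ll))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda f: -loglik(f)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    f_hat = float(res.x)
    ll_hat = float(-res.fun)
    # snap to grid best if refinement did not improve (flat likelihood)
    if ll[i_best] > ll_hat:
        f_hat, ll_hat = float(grid[i_best]), float(ll[i_best])

    boundary = f_hat < GRID_STEP or f_hat > 1 - GRID_STEP
    if boundary:
        f_hat = 0.0 if f_hat < 0.5 else 1.0
        ll_hat = float(loglik(f_hat)[0])
        # one-sided: distance to the f where log L drops by 0.5
        drop = ll_hat - 0.5
        direction = 1 if f_hat == 0.0 else -1
        f = f_hat
        step = GRID_STEP
        while 0.0 <= f + direction * step <= 1.0 and loglik(f + direction * step)[0] > drop:
            f += direction * step
        se = abs(f + direction * step - f_hat)
    else:
        h = 1e-4
        d2 = (loglik(f_hat + h)[0] - 2 * ll_hat + loglik(f_hat - h)[0]) / h**2
        se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan
    return FrequencyEstimate(
        snp_id, group, f_hat, float(se), ll_hat,
        n_individuals=int(has_data.sum()), total_reads=int(n_total.sum()),
        boundary=boundary,
    )


def frequency_table(
    obs: ReadObservations,
    loci: pd.DataFrame,
    grouping: dict[str, str],
    error_rate: float = DEFAULT_ERROR_RATE,
) -> pd.DataFrame:
    """One frequency estimate per (locus, group).

    ``loci`` needs columns snp_id and effect_allele ("ref" or "alt" relative
    to the panel); groups without read data produce missing rows.  Counts
    at C/T and G/A loci are assumed to come from end-masked reads (the
    read-count pipeline's convention).
    """
    panel_ids = list(obs.panel.table["snp_id"])
    groups = list(dict.fromkeys(grouping.values()))
    ind_ids = obs.individual_ids
    rows = []
    for locus in loci.itertuples(index=False):
        if locus.snp_id not in panel_ids:
            continue
        i = panel_ids.index(locus.snp_id)
        derived_is_alt = getattr(locus, "effect_allele", "alt") == "alt"
        for g in groups:
            cols = [ind_ids.index(x) for x, lab in grouping.items() if lab == g and x in ind_ids]
            n_tot = obs.depth[i, cols]
            n_der = (obs.n_alt if derived_is_alt else obs.n_ref)[i, cols]
            if n_tot.sum() == 0:
                rows.append((locus.snp_id, g, np.nan, np.nan, 0, 0, False))
                continue
            est = likelihood_allele_frequency(
                n_der, n_tot, error_rate, snp_id=locus.snp_id, group=g
            )
            rows.append(
                (locus.snp_id, g, est.f_hat, est.se, est.n_individuals,
                 est.total_reads, est.boundary)
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "group", "f_hat", "se", "n_individuals", "total_reads", "boundary"],
    )
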