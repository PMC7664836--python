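"""qpWave rank tests and qpAdm admixture-weight estimation.

The engine is the matrix of f4 statistics
``X[i][j] = f4(L0, Li; R0, Rj)`` for left populations L (target first,
then sources) against right populations R (the outgroups).  If the target
is a mixture of the sources with weights w (summing to 1), the linearity
of f4 statistics makes w a left null vector of X, and X has reduced rank.
qpAdm therefore (1) fits a rank-(k-1) approximation of X by generalized
least squares under the block-jackknife covariance of vec(X), reporting
the minimized chi-square as a model fit test with
dof = (|L|-1-r)(|R|-1-r), and (2) reads the weights off the left null
vector of the fitted matrix, normalized to sum to 1.  Weight standard
errors come from re-running the whole fit on each delete-one-block f4
matrix and combining with the weighted jackknife.

Sex-biased admixture is tested by fitting the same model on autosomes and
on the X chromosome and comparing proportions:
``Z = (P_A - P_X) / sqrt(sigma_A^2 + sigma_X^2)``; positive Z means more
of that ancestry on autosomes than on X, i.e. male-driven admixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genodata import AUTOSOMES
from .fstats import GroupFrequencies, jackknife_covariance, weighted_block_jackknife

RIDGE_CONDITION = 1e10
RIDGE_LAMBDA = 1e-4
ALS_TOL = 1e-8
ALS_MAX_ITER = 1000


@dataclass
class F4Matrix:
    left: list[str]  # target first, then sources
    right: list[str]  # outgroups, base first
    X: np.ndarray  # (|L|-1, |R|-1)
    block_sums: np.ndarray  # (n_blocks, |L|-1, |R|-1)
    block_counts: np.ndarray  # SNPs per block
    n_snps: int
    cov: np.ndarray  # covariance of vec(X), possibly ridge-regularized
    ridged: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def loo(self, j: int) -> np.ndarray:
        """Delete-one-block f4 matrix."""
        S = self.block_sums.sum(axis=0) - self.block_sums[j]
        N = self.block_counts.sum() - self.block_counts[j]
        return S / N


def build_f4_matrix(
    target: str,
    sources,
    outgroups,
    freqs: GroupFrequencies,
    block_cm: float = 5.0,
    chroms=AUTOSOMES,
) -> F4Matrix:
    """f4 matrix, per-block sums and jackknife covariance of vec(X).

    Sites are complete-case across the full left-plus-right population set.
    Requires strictly more outgroups than sources + 1 so the rank test has
    degrees of freedom.
    """
    sources = list(sources)
    outgroups = list(outgroups)
    left = [target] + sources
    if len(outgroups) <= len(sources) + 1:
        raise ValueError("outgroups must exceed sources + 1")
    overlap = set(left) & set(outgroups)
    if overlap:
        raise ValueError(f"populations on both sides: {sorted(overlap)}")
    pops = left + outgroups
    mask = freqs.defined_mask(pops)
    block_ids = freqs.panel.block_ids(block_cm, chroms=chroms)
    use = mask & (block_ids >= 0)
    if not use.any():
        raise ValueError("no usable SNPs across all populations")
    l0 = freqs.col(left[0])[use]
    r0 = freqs.col(outgroups[0])[use]
    L = np.column_stack([l0 - freqs.col(p)[use] for p in left[1:]])  # (n, l)
    R = np.column_stack([r0 - freqs.col(p)[use] for p in outgroups[1:]])  # (n, m)
    b = block_ids[use]
    uniq, inv = np.unique(b, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")
    prods = L[:, :, None] * R[:, None, :]  # (n, l, m)
    lm = prods.reshape(len(l0), -1)
    block_sums = np.zeros((g, lm.shape[1]))
    for c in range(lm.shape[1]):
        block_sums[:, c] = np.bincount(inv, weights=lm[:, c], minlength=g)
    counts = np.bincount(inv, minlength=g).astype(float)
    shape = (len(left) - 1, len(outgroups) - 1)
    block_sums = block_sums.reshape((g,) + shape)
    total = block_sums.sum(axis=0)
    N = counts.sum()
    X = total / N
    loo = (total[None] - block_sums) / (N - counts)[:, None, None]
    cov = jackknife_covariance(
        X.ravel(), loo.reshape(g, -1), counts
    )
    ridged = False
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > RIDGE_CONDITION:
        cov = cov + RIDGE_LAMBDA * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
        ridged = True
    return F4Matrix(left, outgroups, X, block_sums, counts, int(N), cov, ridged)


def _jackknife_cov_samples(theta_hat, loo, weights):
    """Per-block contribution vectors y_j with cov = sum_j y_j y_j^T."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    loo = np.asarray(loo, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = len(w)
    h = (w.sum() / w)[:, None]
    theta_j = g * theta_hat - ((1 - w / w.sum())[:, None] * loo).sum(axis=0)
    tau = h * theta_hat - (h - 1) * loo
    return (tau - theta_j) / np.sqrt(g * (h - 1))


def shrink_covariance(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Covariance with Schafer-Strimmer off-diagonal shrinkage.

    ``samples`` are g contribution vectors whose outer-product sum is the
    raw covariance.  The off-diagonal correlations are shrunk toward zero
    by the analytic intensity (estimated variance of the correlation
    estimates over their squared magnitude), which stabilizes GLS
    weighting when the number of blocks is small relative to the
    dimension, as on a single chromosome.  Returns (covariance, lambda).
    """
    y = np.asarray(samples, dtype=float)
    g, d = y.shape
    S = y.T @ y
    sd = np.sqrt(np.diag(S))
    ys = y / sd[None, :]
    R = ys.T @ ys  # correlation matrix (unit diagonal)
    # Var of each off-diagonal correlation across block contributions:
    # sum_k (w_kij - R_ij/g)^2 = sum_k w_kij^2 - R_ij^2/g with w_kij = y_ki y_kj
    y2 = ys**2
    var_r = g / (g - 1) * (y2.T @ y2 - R**2 / g)
    off = ~np.eye(d, dtype=bool)
    denom = float((R[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_shrunk = np.where(off, (1 - lam) * R, 1.0)
    return R_shrunk * np.outer(sd, sd), lam


def _gls_rank_fit(X, Qinv, r, A0=None, B0=None):
    """Rank-r GLS approximation of X by alternating least squares.

    Minimizes (vec(X)-vec(AB))' Qinv (vec(X)-vec(AB)); SVD start, stops
    when the objective changes by < 1e-8.  Returns (chisq, A, B).
    """
    l, m = X.shape
    x = X.ravel()
    if r == 0:
        return float(x @ Qinv @ x), np.zeros((l, 0)), np.zeros((0, m))
    if r >= min(l, m):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        return 0.0, U * s, Vt
    if A0 is None or B0 is None:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        A = U[:, :r] * s[:r]
        B = Vt[:r]
    else:
        A, B = A0.copy(), B0.copy()
    I_l, I_m = np.eye(l), np.eye(m)
    prev = np.inf
    for _ in range(ALS_MAX_ITER):
        M = np.kron(A, I_m)  # vec(AB) = M @ vec(B)
        MtQ = M.T @ Qinv
        B = np.linalg.solve(MtQ @ M, MtQ @ x).reshape(r, m)
        M = np.kron(I_l, B.T)  # vec(AB) = M @ vec(A)
        MtQ = M.T @ Qinv
        A = np.linalg.solve(MtQ @ M, MtQ @ x).reshape(l, r)
        resid = x - (A @ B).ravel()
        chisq = float(resid @ Qinv @ resid)
        if abs(prev - chisq) < ALS_TOL:
            return chisq, A, B
        prev = chisq
    raise RuntimeError(f"rank-{r} GLS fit did not converge; last chisq={chisq:.6g}")


def qpwave_rank_test(fm: F4Matrix, rank: int) -> tuple[float, int, float]:
    """Chi-square test that the f4 matrix has rank <= ``rank``.

    Returns (chisq, dof, p) with dof = (|L|-1-r)(|R|-1-r); rank 0 against
    two left populations is the cladality test.
    """
    l, m = fm.shape
    if not 0 <= rank <= min(l, m):
        raise ValueError(f"rank must be in [0, {min(l, m)}]")
    Qinv = linalg.inv(fm.cov)
    chisq, _, _ = _gls_rank_fit(fm.X, Qinv, rank)
    dof = (l - rank) * (m - rank)
    p = float(stats.chi2.sf(chisq, dof)) if dof > 0 else 1.0
    return chisq, dof, p


@dataclass
class AdmixtureModel:
    target: str
    sources: list[str]
    outgroups: list[str]
    weights: np.ndarray
    se: np.ndarray
    chisq: float
    dof: int
    p_value: float
    feasible: bool
    n_snps: int
    n_blocks: int

    def summary(self) -> str:
        parts = [
            f"{s}: {w:.3f} ± {e:.3f}" for s, w, e in zip(self.sources, self.weights, self.se)
        ]
        return (
            f"{self.target} = " + " + ".join(parts)
            + f"  (p={self.p_value:.3g}, feasible={self.feasible})"
        )


def _weights_from_matrix(X, Qinv, r, warm=None):
    """Fit rank r = k-1, return weights (left null vector of the fit) and fit."""
    if r == 0:
        chisq = float(X.ravel() @ Qinv @ X.ravel())
        return np.array([1.0]), chisq, (None, None)
    chisq, A, B = _gls_rank_fit(X, Qinv, r, *(warm or (None, None)))
    U, s, Vt = np.linalg.svd(A @ B)
    null = U[:, -1]
    total = null.sum()
    if abs(total) < 1e-12:
        raise RuntimeError("degenerate left null vector; weights undefined")
    return null / total, chisq, (A, B)


def qpadm_fit(
    target: str,
    sources,
    outgroups,
    freqs: GroupFrequencies,
    block_cm: float = 5.0,
    chroms=AUTOSOMES,
    fm: F4Matrix | None = None,
) -> AdmixtureModel:
    """Estimate admixture weights of ``target`` from ``sources``.

    The p-value is the qpWave rank-(k-1) test: small p rejects the model
    that the target is a mixture of the chosen sources relative to the
    outgroups.  Out-of-[0,1] weights are reported and flagged infeasible,
    never clipped.
    """
    sources = list(sources)
    if fm is None:
        fm = build_f4_matrix(target, sources, outgroups, freqs, block_cm, chroms)
    k = len(sources)
    r = k - 1
    l, m = fm.shape
    g = len(fm.block_counts)
    # model-fit chi-square uses the plain jackknife covariance
    Qinv = linalg.inv(fm.cov)
    chisq, _, _ = _gls_rank_fit(fm.X, Qinv, r)

    def weight_cov(theta, loo, counts):
        y = _jackknife_cov_samples(theta, loo, counts)
        Q, _ = shrink_covariance(y)
        cond = np.linalg.cond(Q)
        if not np.isfinite(cond) or cond > RIDGE_CONDITION:
            Q = Q + RIDGE_LAMBDA * np.mean(np.diag(Q)) * np.eye(Q.shape[0])
        return Q

    S_tot = fm.block_sums.sum(axis=0)
    N = fm.block_counts.sum()
    flat_sums = fm.block_sums.reshape(g, -1)
    loo_all = (S_tot.ravel()[None] - flat_sums) / (N - fm.block_counts)[:, None]
    # GLS weighting uses the shrunk covariance: with few blocks (single
    # chromosome fits) the raw inverse is unstable and destabilizes weights
    Qw = weight_cov(fm.X.ravel(), loo_all, fm.block_counts)
    w_hat, _, warm = _weights_from_matrix(fm.X, linalg.inv(Qw), r)
    # each delete-one-block refit re-estimates the covariance from the
    # remaining blocks, so noise in Q itself propagates into the weight SEs
    loo_w = np.empty((g, k))
    for j in range(g):
        Xj = fm.loo(j)
        keep = np.arange(g) != j
        cj = fm.block_counts[keep]
        inner = (S_tot.ravel()[None] - flat_sums[j][None] - flat_sums[keep]) / (
            N - fm.block_counts[j] - cj
        )[:, None]
        Qj = weight_cov(Xj.ravel(), inner, cj)
        loo_w[j], _, _ = _weights_from_matrix(Xj, linalg.inv(Qj), r, warm=warm)
    _, se = weighted_block_jackknife(w_hat, loo_w, fm.block_counts)
    dof = (l - r) * (m - r)
    p = float(stats.chi2.sf(chisq, dof))
    feasible = bool(np.all((w_hat >= 0) & (w_hat <= 1)))
    return AdmixtureModel(
        target, sources, list(fm.right), w_hat, np.atleast_1d(se), chisq, dof, p,
        feasible, fm.n_snps, g,
    )


@dataclass
class CladalityResult:
    test: str
    reference: str
    p_value: float | None
    chisq: float | None
    dof: int
    n_snps: int
    status: str  # cladal / distinct / insufficient-data


def test_cladality(
    test_pop: str,
    reference_pop: str,
    outgroups,
    freqs: GroupFrequencies,
    block_cm: float = 5.0,
    chroms=AUTOSOMES,
    p_threshold: float = 0.05,
    min_snps: int = 10_000,
) -> CladalityResult:
    """qpWave rank-0 test of whether two populations form a clade.

    p above the threshold reports "cladal" (genetically indistinguishable
    relative to the outgroups); insufficient SNP overlap yields an
    insufficient-data result rather than a p-value.
    """
    if test_pop == reference_pop:
        raise ValueError("test and reference populations must differ")
    fm = build_f4_matrix(test_pop, [reference_pop], outgroups, freqs, block_cm, chroms)
    if fm.n_snps < min_snps:
        return CladalityResult(test_pop, reference_pop, None, None, 0, fm.n_snps,
                               "insufficient-data")
    chisq, dof, p = qpwave_rank_test(fm, 0)
    status = "cladal" if p > p_threshold else "distinct"
    return CladalityResult(test_pop, reference_pop, p, chisq, dof, fm.n_snps, status)


@dataclass
class SexBiasResult:
    ancestry: str
    p_autosomal: float
    se_autosomal: float
    p_x: float
    se_x: float
    z: float
    usable: bool


def sex_bias_z_score(p_a: float, se_a: float, p_x: float, se_x: float) -> float:
    """Z = (P_A - P_X) / sqrt(sigma_A^2 + sigma_X^2)."""
    denom = np.hypot(se_a, se_x)
    return float((p_a - p_x) / denom) if denom > 0 else float("nan")


def sex_bias_z(
    target: str,
    sources,
    outgroups,
    freqs: GroupFrequencies,
    block_cm: float = 5.0,
) -> list[SexBiasResult]:
    """Autosomes-vs-X comparison of ancestry proportions per source.

    Fits the same qpAdm model on autosomal SNPs and on X-chromosome SNPs
    and reports Z = (P_A - P_X)/sqrt(sA^2 + sX^2) per ancestry; positive Z
    indicates the ancestry is enriched on autosomes (male-driven
    admixture), negative Z female-driven.
    """
    auto = qpadm_fit(target, sources, outgroups, freqs, block_cm, chroms=AUTOSOMES)
    x = qpadm_fit(target, sources, outgroups, freqs, block_cm, chroms=("X",))
    out = []
    for i, src in enumerate(auto.sources):
        pa, sa = float(auto.weights[i]), float(auto.se[i])
        px, sx = float(x.weights[i]), float(x.se[i])
        z = sex_bias_z_score(pa, sa, px, sx)
        out.append(SexBiasResult(src, pa, sa, px, sx, z, usable=x.feasible))
    return out


def model_search(
    target: str,
    source_sets: list[list[str]],
    outgroups,
    freqs: GroupFrequencies,
    block_cm: float = 5.0,
    p_threshold: float = 0.05,
) -> tuple[AdmixtureModel | None, pd.DataFrame]:
    """Try source sets in order; report the first fitting model and all rows.

    A model "fits" when its rank-test p-value is at or above the threshold
    (0.05 by default) and its weights are feasible.
    """
    rows = []
    best = None
    for sources in source_sets:
        try:
            model = qpadm_fit(target, sources, outgroups, freqs, block_cm)
        except (ValueError, RuntimeError) as exc:
            rows.append((target, "+".join(sources), None, None, False, str(exc)))
            continue
        rows.append(
            (
                target,
                "+".join(sources),
                " ".join(f"{w:.3f}±{e:.3f}" for w, e in zip(model.weights, model.se)),
                model.p_value,
                model.feasible,
                "",
            )
        )
        if best is None and model.p_value >= p_threshold and model.feasible:
            best = model
    table = pd.DataFrame(
        rows, columns=["target", "sources", "weights", "p_value", "feasible", "error"]
    )
    return best, table
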