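"""Admixture dating from the decay of weighted ancestry covariance.

After a single-pulse admixture G generations ago, linkage between
ancestry-informative alleles decays as exp(-G d) with genetic distance d
(in Morgans).  For each SNP we form the reference-frequency contrast
``u = a - b`` and the residual ``r = g/2 - (alpha a + (1-alpha) b)`` of
the target genotype against the mixture expectation (alpha estimated by
least squares); for every intra-chromosomal SNP pair the product
``(u_i r_i)(u_j r_j)``, averaged over target individuals, is binned by
genetic distance.  An exponential ``A exp(-n d) + c`` fitted beyond a
start distance (0.45 cM by default, bin width 0.001 M, pairs up to 1 M)
estimates the admixture age n in generations; its standard error comes
from a leave-one-chromosome-out weighted jackknife, and calendar dates
use 29 years per generation with variances combined in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .genodata import AUTOSOMES, MISSING, GenotypeDataset

YEARS_PER_GENERATION = 29.0
DEFAULT_BINSIZE = 0.001  # Morgans
DEFAULT_MAXDIS = 1.0  # Morgans
DEFAULT_FIT_START_CM = 0.45


@dataclass
class DecayCurve:
    bin_centers: np.ndarray  # Morgans
    chroms: list[str]
    per_chrom_num: np.ndarray  # (n_chroms, n_bins) summed products
    per_chrom_den: np.ndarray  # (n_chroms, n_bins) pair counts
    chrom_snp_counts: np.ndarray
    binsize: float
    maxdis: float
    alpha: float  # genome-wide mixture fraction used for residuals

    def covariance(self, drop_chrom: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(bin centers, weighted ancestry covariance), optionally one chrom out."""
        num = self.per_chrom_num.sum(axis=0)
        den = self.per_chrom_den.sum(axis=0)
        if drop_chrom is not None:
            num = num - self.per_chrom_num[drop_chrom]
            den = den - self.per_chrom_den[drop_chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        return self.bin_centers, cov


@dataclass
class DecayFit:
    amplitude: float
    generations: float
    offset: float
    se_generations: float
    fit_start_cm: float
    n_bins_used: int
    detectable: bool

    def __str__(self) -> str:
        if not self.detectable:
            return "no detectable admixture decay"
        return (
            f"admixture {self.generations:.2f} ± {self.se_generations:.2f} "
            f"generations ago (fit from {self.fit_start_cm} cM)"
        )


def ancestry_covariance(
    target: GenotypeDataset,
    ref_freqs_a: np.ndarray,
    ref_freqs_b: np.ndarray,
    binsize: float = DEFAULT_BINSIZE,
    maxdis: float = DEFAULT_MAXDIS,
    chroms=AUTOSOMES,
) -> DecayCurve:
    """Binned weighted ancestry covariance of the target against two references.

    Products are accumulated per chromosome only (the decay model's
    domain), averaged over target individuals, and normalized per bin by
    the number of observed pairs.  Missing genotypes contribute nothing.
    """
    panel = target.panel
    keep = np.isin(panel.chrom, chroms)
    a = np.asarray(ref_freqs_a, dtype=float)
    b = np.asarray(ref_freqs_b, dtype=float)
    g = target.calls
    dose = np.where(g == MISSING, np.nan, g / 2.0)

    u = a - b
    # genome-wide mixture fraction by pooled least squares of (dose - b) on u
    y = dose[keep] - b[keep, None]
    x = np.broadcast_to(u[keep, None], y.shape)
    ok = ~np.isnan(y)
    denom = float((x[ok] ** 2).sum())
    if denom == 0:
        raise ValueError("reference populations are identical; no contrast to weight")
    alpha = float((x[ok] * y[ok]).sum() / denom)

    resid = dose - (alpha * a + (1 - alpha) * b)[:, None]
    z = u[:, None] * resid  # (n_snps, n_ind), NaN at missing
    obs = ~np.isnan(z)
    z0 = np.where(obs, z, 0.0)

    n_bins = int(round(maxdis / binsize))
    centers = (np.arange(n_bins) + 0.5) * binsize
    chrom_list = [c for c in dict.fromkeys(panel.chrom) if c in set(chroms)]
    num = np.zeros((len(chrom_list), n_bins))
    den = np.zeros_like(num)
    snp_counts = np.zeros(len(chrom_list))
    gpos = panel.genetic_pos
    for ci, chrom in enumerate(chrom_list):
        m = panel.chrom == chrom
        zc = z0[m]
        oc = obs[m].astype(float)
        gc = gpos[m]
        nloc = int(m.sum())
        snp_counts[ci] = nloc
        steps = np.diff(gc)
        if nloc > 2 and np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            # evenly spaced map: per-offset pair sums are autocorrelations,
            # computed for all offsets at once by FFT
            L = 2 * nloc
            pz = (np.abs(np.fft.rfft(zc, L, axis=0)) ** 2).sum(axis=1)
            po = (np.abs(np.fft.rfft(oc, L, axis=0)) ** 2).sum(axis=1)
            ac_z = np.fft.irfft(pz, L)[1:nloc]  # offset k = 1..n-1
            ac_o = np.fft.irfft(po, L)[1:nloc]
            d_k = np.arange(1, nloc) * steps[0]
            binidx = np.floor(d_k / binsize).astype(np.int64)
            ok = binidx < n_bins
            num[ci] = np.bincount(binidx[ok], weights=ac_z[ok], minlength=n_bins)
            den[ci] = np.bincount(binidx[ok], weights=ac_o[ok], minlength=n_bins)
        else:
            S = zc @ zc.T  # sum over individuals of z_i z_j
            C = oc @ oc.T  # number of individuals observing both sites
            B = np.abs(gc[:, None] - gc[None, :])
            np.floor_divide(B, binsize, out=B)
            idx = B.astype(np.int32).ravel()
            inside = idx < n_bins
            ns = np.bincount(idx[inside], weights=S.ravel()[inside], minlength=n_bins)
            nc = np.bincount(idx[inside], weights=C.ravel()[inside], minlength=n_bins)
            ns[0] -= float(np.trace(S))
            nc[0] -= float(np.trace(C))
            num[ci] = ns / 2.0
            den[ci] = nc / 2.0
    return DecayCurve(centers, chrom_list, num, den, snp_counts, binsize, maxdis, alpha)


# decay rates above ~1/fit_start are unresolvable from the fitted range;
# bounding n keeps jackknife replicates from chasing single-bin spikes
MAX_RATE = 500.0


def _fit_exponential(
    d: np.ndarray,
    y: np.ndarray,
    n0: float,
    A0: float | None = None,
    c0: float | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Bounded least-squares A*exp(-n*d) + c; returns (A, n, c).

    Bin variances scale inversely with their pair counts, so when counts
    are supplied the fit is weighted with sigma ~ 1/sqrt(count).
    """
    if A0 is None:
        A0 = max(y[0] - y[-1], 1e-6)
    if c0 is None:
        c0 = float(y[-1])
    n0 = float(np.clip(n0, 1e-3, MAX_RATE - 1))
    sigma = None if weights is None else 1.0 / np.sqrt(np.maximum(weights, 1.0))
    popt, _ = curve_fit(
        lambda x, A, n, c: A * np.exp(-n * x) + c,
        d, y, p0=(A0, n0, c0), sigma=sigma,
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, MAX_RATE, np.inf]),
        maxfev=20_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(
    curve: DecayCurve,
    fit_start_cm: float = DEFAULT_FIT_START_CM,
    min_bins: int = 20,
) -> DecayFit:
    """Fit the exponential decay and jackknife its rate over chromosomes.

    Bins below the start distance are retained in the curve but excluded
    from the fit (they carry short-range LD the pulse model does not
    describe).  A non-positive fitted amplitude is reported as "no
    detectable admixture decay" rather than a date.
    """
    start_m = fit_start_cm / 100.0

    def usable(dc: int | None):
        d, y = curve.covariance(drop_chrom=dc)
        den = curve.per_chrom_den.sum(axis=0)
        if dc is not None:
            den = den - curve.per_chrom_den[dc]
        m = (d >= start_m) & ~np.isnan(y)
        return d[m], y[m], den[m]

    d, y, w = usable(None)
    if len(d) < min_bins:
        raise ValueError(f"only {len(d)} defined bins beyond fit start; need {min_bins}")
    # initial rate from a log-linear fit on the positive part
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(d[pos], np.log(y[pos]), 1)[0]
        n0 = max(-slope, 1.0)
    else:
        n0 = 10.0
    try:
        A, n, c = _fit_exponential(d, y, n0, weights=w)
    except RuntimeError:
        A, n, c = -1.0, np.nan, np.nan
    if not (A > 0 and n > 0):
        return DecayFit(A, np.nan, c, np.nan, fit_start_cm, len(d), detectable=False)

    loo = []
    weights = []
    for ci in range(len(curve.chroms)):
        dd, yy, ww = usable(ci)
        try:
            _, n_c, _ = _fit_exponential(dd, yy, n, A0=A, c0=c, weights=ww)
        except RuntimeError:
            continue
        loo.append(n_c)
        weights.append(curve.chrom_snp_counts[ci])
    if len(loo) >= 2:
        _, se = weighted_block_jackknife_scalar(n, np.array(loo), np.array(weights))
    else:
        se = np.nan
    return DecayFit(A, n, c, float(se), fit_start_cm, len(d), detectable=True)


def weighted_block_jackknife_scalar(theta, loo, weights):
    from .fstats import weighted_block_jackknife

    est, se = weighted_block_jackknife(theta, loo, weights)
    return float(est), float(se)


def generations_to_years(
    n: float,
    se_n: float,
    sample_age_bp: float = 0.0,
    se_age: float = 0.0,
    years_per_generation: float = YEARS_PER_GENERATION,
) -> tuple[float, float]:
    """Convert an admixture age in generations to calendar years BP.

    date = sample age + years_per_generation * n; the uncertainty combines
    the dating SE and the sample-age SE in quadrature (independence
    assumed).
    """
    if n <= 0:
        raise ValueError("generations must be positive")
    if se_n < 0 or se_age < 0 or sample_age_bp < 0:
        raise ValueError("negative inputs not allowed")
    date = sample_age_bp + years_per_generation * n
    se = float(np.hypot(years_per_generation * se_n, se_age))
    return float(date), se
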