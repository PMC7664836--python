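"""Synthetic-data generator for the whole pipeline, with known ground truth.

Everything the analyses consume can be generated here: drifted source
allele frequencies (Balding–Nichols around a shared ancestral frequency,
optionally along a small population tree so that outgroups are
differentially related to the admixture sources), admixed target
individuals with recorded ancestry tracts on a genetic map, pseudo-haploid
sampling with missingness, read counts with terminal deamination damage,
small pedigrees with recombination for kinship truth, and sex-dependent
chromosome coverage.

Model summary
-------------
* Ancestral derived-allele frequency per SNP: Uniform(0.05, 0.95).
* Drift by F along an edge: Beta(p(1-F)/F, (1-p)(1-F)/F) around p.
* Single-pulse admixture G generations ago: ancestry along each haploid
  chromosome is a Markov chain with switch events Poisson(G per Morgan),
  the new ancestry drawn from the mixture proportions.  This produces the
  exponential decay of ancestry covariance with rate G that the dating
  module measures.
* Reads: depth Poisson(mean_depth); allele from the genotype with
  symmetric error; 5' C>T / 3' G>A damage decaying exponentially from the
  read ends (position-1 rate equals ``damage_rate``).

All simulators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeDataset,
    Individual,
    ReadObservations,
    ReadRecord,
    SnpPanel,
)

# Read geometry for the damage model: fixed read length and exponential
# decay scale (in positions) of the terminal misincorporation rate.
READ_LENGTH = 60
DAMAGE_DECAY = 3.0


@dataclass
class SourcePopulation:
    name: str
    allele_freqs: np.ndarray
    drift_param: float = 0.0

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.drift_param < 0:
            raise ValueError("drift_param must be >= 0")


@dataclass
class AdmixtureSpec:
    source_names: list[str]
    proportions: list[float]
    generations_ago: int
    n_individuals: int

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.generations_ago < 1:
            raise ValueError("generations_ago must be >= 1")


@dataclass
class GroundTruth:
    """Tract, pedigree and sex truth emitted alongside simulated genotypes."""

    tracts: pd.DataFrame  # individual, hap, chrom, start_m, end_m, source
    pedigree: list[tuple[str, str]] = field(default_factory=list)
    sex: dict[str, str] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def ancestry_fractions(self) -> pd.DataFrame:
        """Genome-wide ancestry fraction per individual from tract lengths."""
        t = self.tracts.copy()
        t["length"] = t["end_m"] - t["start_m"]
        tot = t.groupby("individual")["length"].sum()
        frac = (
            t.groupby(["individual", "source"])["length"].sum().unstack(fill_value=0.0)
        )
        return frac.div(tot, axis=0)

    def mean_tract_length(self) -> float:
        t = self.tracts
        return float((t["end_m"] - t["start_m"]).mean())


# ---------------------------------------------------------------------------
# Panel and allele frequencies
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
# biallelic pairs with the 1240K-like excess of transitions
_PAIRS = [("C", "T"), ("G", "A"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
_PAIR_WEIGHTS = np.array([0.33, 0.33, 0.085, 0.085, 0.085, 0.085])


X_LENGTH_FACTOR = 1.8  # genetic length of X relative to a model autosome


def make_panel(
    n_snps: int,
    seed: int | np.random.Generator = 0,
    chrom_length_m: float = 1.0,
    include_x: bool = True,
) -> SnpPanel:
    """Evenly spaced SNP panel: 22 autosomes (+X), ``chrom_length_m`` each.

    ``n_snps`` is the autosomal total; the X chromosome (when included) is
    1.8 model-autosome lengths (its real genetic length relative to a
    typical autosome) at the same per-Morgan SNP density.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = [n_snps // 22 + (1 if i < n_snps % 22 else 0) for i in range(22)]
    lengths = [chrom_length_m] * 22
    chroms = [str(i + 1) for i in range(22)]
    if include_x:
        chroms.append("X")
        per.append(max(2, int(round(X_LENGTH_FACTOR * n_snps / 22))))
        lengths.append(X_LENGTH_FACTOR * chrom_length_m)
    rows = []
    for chrom, n, clen in zip(chroms, per, lengths):
        g = (np.arange(n) + 0.5) / n * clen
        phys = np.round(g * 1.0e8).astype(int) + 1
        pick = rng.choice(len(_PAIRS), size=n, p=_PAIR_WEIGHTS / _PAIR_WEIGHTS.sum())
        flip = rng.random(n) < 0.5
        for k in range(n):
            ref, alt = _PAIRS[pick[k]]
            if flip[k]:
                ref, alt = alt, ref
            rows.append((f"rs_{chrom}_{k}", chrom, g[k], phys[k], ref, alt))
    return SnpPanel(
        pd.DataFrame(
            rows, columns=["snp_id", "chrom", "genetic_pos", "physical_pos", "ref", "alt"]
        )
    )


def ancestral_frequencies(n_snps: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=n_snps)


def drift_frequencies(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols drift step of magnitude F around frequencies p."""
    if F < 0:
        raise ValueError("drift parameter must be >= 0")
    if F == 0:
        return p.copy()
    out = p.copy()
    interior = (p > 0) & (p < 1)  # fixed alleles stay fixed
    a = p[interior] * (1.0 - F) / F
    b = (1.0 - p[interior]) * (1.0 - F) / F
    out[interior] = rng.beta(a, b)
    return out


def simulate_sources(
    n_snps: int,
    n_sources: int,
    drift_params,
    seed: int | np.random.Generator = 0,
    panel: SnpPanel | None = None,
) -> tuple[list[SourcePopulation], SnpPanel]:
    """Star-topology sources: independent drift from one ancestral frequency."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drift_params = list(np.broadcast_to(np.asarray(drift_params, dtype=float), n_sources))
    if panel is None:
        panel = make_panel(n_snps, rng)
    p = ancestral_frequencies(len(panel), rng)
    sources = [
        SourcePopulation(f"pop{i + 1}", drift_frequencies(p, F, rng), F)
        for i, F in enumerate(drift_params)
    ]
    return sources, panel


def simulate_graph(
    panel: SnpPanel,
    edges: list[tuple[str, str, float]],
    seed: int | np.random.Generator = 0,
    root: str = "root",
) -> dict[str, np.ndarray]:
    """Drift allele frequencies along a population tree.

    ``edges`` is a list of (parent, child, F); the root node gets the
    ancestral Uniform(0.05, 0.95) frequencies and every child drifts from
    its parent by the edge's F.  Returns frequencies for every node.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {root: ancestral_frequencies(len(panel), rng)}
    remaining = list(edges)
    while remaining:
        progress = False
        for e in list(remaining):
            parent, child, F = e
            if parent in freqs:
                freqs[child] = drift_frequencies(freqs[parent], F, rng)
                remaining.remove(e)
                progress = True
        if not progress:
            raise ValueError(f"unreachable nodes in graph: {[e[1] for e in remaining]}")
    return freqs


# Canonical synthetic study: a western and an eastern source clade, each
# carrying outgroups that share drift with its source, plus a deep African
# style outgroup — the topology qpAdm's eight-outgroup design needs.
DEFAULT_GRAPH_EDGES: list[tuple[str, str, float]] = [
    ("root", "african", 0.12),
    ("root", "eurasia", 0.04),
    ("eurasia", "west", 0.03),
    ("eurasia", "east", 0.03),
    ("west", "WSH", 0.05),
    ("west", "anatolia", 0.04),
    ("west", "iran", 0.05),
    ("west", "natufian", 0.06),
    ("west", "villabruna", 0.06),
    ("east", "onge", 0.07),
    ("east", "eastcore", 0.02),
    ("eastcore", "han", 0.04),
    ("eastcore", "ami", 0.05),
    ("eastcore", "north", 0.02),
    ("north", "ANA", 0.04),
    ("north", "mixe", 0.07),
]

DEFAULT_OUTGROUPS = [
    "african",
    "onge",
    "ami",
    "mixe",
    "natufian",
    "iran",
    "anatolia",
    "villabruna",
]


# ---------------------------------------------------------------------------
# Admixed individuals with ancestry tracts
# ---------------------------------------------------------------------------

def _chromosome_slices(panel: SnpPanel) -> list[tuple[str, slice, np.ndarray, float]]:
    out = []
    chrom = panel.chrom
    gpos = panel.genetic_pos
    start = 0
    for c in dict.fromkeys(chrom):
        n = int((chrom == c).sum())
        sl = slice(start, start + n)
        g = gpos[sl]
        length = float(g.max()) + (float(g.min()) if n > 1 else 0.01)
        out.append((c, sl, g, max(length, float(g.max()) + 1e-6)))
        start += n
    return out


def simulate_admixed_individuals(
    spec: AdmixtureSpec,
    sources: list[SourcePopulation],
    panel: SnpPanel,
    seed: int | np.random.Generator = 0,
    group_label: str = "target",
) -> tuple[GenotypeDataset, GroundTruth]:
    """Diploid genotypes for a single-pulse admixed population, with tracts.

    Per haploid chromosome, ancestry switches occur as a Poisson process of
    rate G per Morgan; each new tract's ancestry is an independent draw
    from the mixture proportions.  Alleles are Bernoulli draws from the
    local ancestry's source frequency; the diploid genotype is the sum of
    the two haploid copies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_name = {s.name: s for s in sources}
    for name in spec.source_names:
        if name not in by_name:
            raise KeyError(f"source {name!r} not found")
    freq = np.column_stack([by_name[n].allele_freqs for n in spec.source_names])
    props = np.asarray(spec.proportions, dtype=float)
    G = spec.generations_ago
    chrom_info = _chromosome_slices(panel)
    n_snps = len(panel)

    calls = np.zeros((n_snps, spec.n_individuals), dtype=np.int8)
    tract_rows = []
    sexes = {}
    for j in range(spec.n_individuals):
        iid = f"{group_label}{j:03d}"
        sexes[iid] = "M" if rng.random() < 0.5 else "F"
        for hap in (0, 1):
            for chrom, sl, g, length in chrom_info:
                n_switch = rng.poisson(G * length)
                cuts = np.sort(rng.uniform(0.0, length, size=n_switch))
                bounds = np.concatenate(([0.0], cuts, [length]))
                anc = rng.choice(len(props), size=len(bounds) - 1, p=props)
                # one tract per inter-switch segment (not collapsed), so mean
                # tract length carries the 1/G signature of the pulse
                for k, a in enumerate(anc):
                    tract_rows.append(
                        (iid, hap, chrom, bounds[k], bounds[k + 1], spec.source_names[a])
                    )
                idx = np.searchsorted(bounds[1:-1], g, side="right")
                local = anc[idx]
                p = freq[sl.start + np.arange(sl.stop - sl.start), local]
                calls[sl, j] += (rng.random(len(g)) < p).astype(np.int8)
    individuals = [
        Individual(f"{group_label}{j:03d}", genetic_sex=sexes[f"{group_label}{j:03d}"],
                   group_label=group_label)
        for j in range(spec.n_individuals)
    ]
    dataset = GenotypeDataset(panel, individuals, calls, ploidy_mode="diploid")
    truth = GroundTruth(
        tracts=pd.DataFrame(
            tract_rows,
            columns=["individual", "hap", "chrom", "start_m", "end_m", "source"],
        ),
        sex=sexes,
        info={"proportions": dict(zip(spec.source_names, props)), "generations": G},
    )
    return dataset, truth


def sample_individuals_from_freqs(
    freqs: np.ndarray,
    panel: SnpPanel,
    n: int,
    group_label: str,
    seed: int | np.random.Generator = 0,
    ploidy: str = "diploid",
) -> GenotypeDataset:
    """Hardy–Weinberg individuals drawn straight from population frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(freqs)[:, None]
    if ploidy == "diploid":
        calls = (rng.random((len(panel), n)) < p).astype(np.int8)
        calls += (rng.random((len(panel), n)) < p).astype(np.int8)
    else:
        calls = 2 * (rng.random((len(panel), n)) < p).astype(np.int8)
    individuals = [
        Individual(f"{group_label}{j:03d}", group_label=group_label) for j in range(n)
    ]
    return GenotypeDataset(panel, individuals, calls, ploidy_mode=ploidy)


def pseudohaploid_sample(
    dataset: GenotypeDataset,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeDataset:
    """Draw one allele per site from diploid truth, with random missingness.

    Shortcut for the read-simulation + random-base-call path when read-level
    detail (damage, depth variation) is not under study.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = dataset.calls
    p_alt = np.where(g == MISSING, 0.0, g / 2.0)
    calls = np.where(rng.random(g.shape) < p_alt, 2, 0).astype(np.int8)
    drop = (rng.random(g.shape) < missing_rate) | (g == MISSING)
    calls[drop] = MISSING
    return GenotypeDataset(
        dataset.panel, list(dataset.individuals), calls, ploidy_mode="pseudo-haploid"
    )


# ---------------------------------------------------------------------------
# Reads with deamination damage
# ---------------------------------------------------------------------------

def _positional_damage_rates(damage_rate: float, masked_width: int = 0) -> np.ndarray:
    i = np.arange(READ_LENGTH)
    r = damage_rate * np.exp(-i / DAMAGE_DECAY)
    if masked_width:
        r = r[masked_width:READ_LENGTH - masked_width]
    return r


def simulate_reads(
    dataset: GenotypeDataset,
    mean_depth: float,
    error_rate: float = 0.0,
    damage_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    apply_end_masking: bool = True,
    library_type: str = "UDG-half",
    max_recorded_reads: int = 2000,
) -> ReadObservations:
    """Per-site read counts plus capped per-read records for damage profiling.

    Counts at C/T and G/A SNPs reflect the processing convention of counting
    from end-masked reads when ``apply_end_masking`` (reads whose SNP base
    falls in the masked window are discarded; residual interior damage
    remains).  Recorded reads are always unmasked, as damage profiling
    requires.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0 <= error_rate < 1 and 0 <= damage_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .genodata import MASK_WIDTHS

    g = dataset.calls
    known = g != MISSING
    dose = np.where(known, g / 2.0, 0.0)
    depth = rng.poisson(mean_depth, size=g.shape)
    depth[~known] = 0

    p_alt = dose * (1 - 2 * error_rate) + error_rate

    ct = dataset.panel.transition_ct_ga_mask()
    w = MASK_WIDTHS[library_type] if apply_end_masking else 0
    rates = _positional_damage_rates(damage_rate, masked_width=w)
    p_dmg = float(rates.mean()) * len(rates) / READ_LENGTH  # mean over all offsets
    if apply_end_masking and w:
        keep = (READ_LENGTH - 2 * w) / READ_LENGTH
        depth_ct = rng.binomial(depth, keep)
        depth = np.where(ct[:, None], depth_ct, depth)
    if damage_rate > 0:
        ref_is_ct = np.isin(dataset.panel.ref, ("C", "G"))  # 5' C>T or 3' G>A hits ref
        toward_alt = (ct & ref_is_ct)[:, None]
        toward_ref = (ct & ~ref_is_ct)[:, None]
        p_alt = np.where(toward_alt, p_alt + (1 - p_alt) * p_dmg, p_alt)
        p_alt = np.where(toward_ref, p_alt * (1 - p_dmg), p_alt)
    n_alt = rng.binomial(depth, p_alt)
    n_ref = depth - n_alt

    reads: dict[str, list[ReadRecord]] = {}
    if max_recorded_reads > 0:
        rates_full = _positional_damage_rates(damage_rate)
        for j, ind in enumerate(dataset.individuals):
            n_rec = min(max_recorded_reads, int(depth[:, j].sum()))
            if n_rec == 0:
                continue
            ref_mat = rng.choice(_BASES, size=(n_rec, READ_LENGTH))
            seq = ref_mat.copy()
            if damage_rate > 0:
                u = rng.random((n_rec, READ_LENGTH))
                flip5 = (ref_mat == "C") & (u < rates_full[None, :])
                flip3 = (ref_mat == "G") & (u < rates_full[None, ::-1])
                seq[flip5] = "T"
                seq[flip3] = "A"
            reads[ind.individual_id] = [
                ReadRecord("".join(r), "".join(s)) for r, s in zip(ref_mat, seq)
            ]
    return ReadObservations(dataset.panel, list(dataset.individuals), n_ref, n_alt, reads=reads)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

RELATIONSHIPS = ("identical", "parent-offspring", "full-sib", "second-degree", "unrelated")


def _founder_haps(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((2, len(freqs))) < freqs[None, :]).astype(np.int8)


def _meiosis(
    haps: np.ndarray,
    labels: tuple,
    chrom_info,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, float, float, object]]]:
    """One gamete: recombine a parent's two haplotypes on the genetic map.

    Returns the gamete allele vector and tracts labelled by the founder
    haplotype each segment descends from.
    """
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    tracts = []
    for chrom, sl, g, length in chrom_info:
        n_x = rng.poisson(length)
        cuts = np.sort(rng.uniform(0.0, length, size=n_x))
        bounds = np.concatenate(([0.0], cuts, [length]))
        phase0 = rng.integers(0, 2)
        idx = np.searchsorted(bounds[1:-1], g, side="right")
        which = (phase0 + idx) % 2
        gamete[sl] = np.where(which == 0, haps[0, sl], haps[1, sl])
        for k in range(len(bounds) - 1):
            tracts.append((chrom, bounds[k], bounds[k + 1], labels[(phase0 + k) % 2]))
    return gamete, tracts


def _ibd_fractions(tr_a: dict, tr_b: dict, chrom_info) -> tuple[float, float, float]:
    """Fractions of the genome where two individuals share 0/1/2 founder haps.

    ``tr_a``/``tr_b`` map 'pat'/'mat' to per-chromosome label step functions
    (list of (chrom, start, end, label))."""
    total = sum(length for _, _, _, length in chrom_info)
    shared = {0: 0.0, 1: 0.0, 2: 0.0}
    for chrom, _, _, length in chrom_info:
        # build breakpoints from all four tract sets on this chromosome
        funcs = []
        for tr in (tr_a["pat"], tr_a["mat"], tr_b["pat"], tr_b["mat"]):
            segs = [(s, e, lab) for c, s, e, lab in tr if c == chrom]
            funcs.append(sorted(segs))
        points = sorted({p for segs in funcs for s, e, _ in segs for p in (s, e)})
        for s, e in zip(points[:-1], points[1:]):
            mid = 0.5 * (s + e)
            labs = []
            for segs in funcs:
                for ss, ee, lab in segs:
                    if ss <= mid < ee:
                        labs.append(lab)
                        break
            a_p, a_m, b_p, b_m = labs
            n = int(a_p == b_p) + int(a_m == b_m)
            # also catch cross-matching (paternal of one = maternal of other)
            n = max(n, int(a_p == b_m) + int(a_m == b_p))
            shared[n] += e - s
    return tuple(shared[k] / total for k in (0, 1, 2))


def simulate_pedigree(
    source: SourcePopulation,
    relationship: str,
    panel: SnpPanel,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeDataset, GroundTruth]:
    """A pair of diploid genomes with the requested degree of relatedness.

    Founders are Hardy–Weinberg draws from the source frequencies; children
    arise by Mendelian transmission with Poisson recombination on the
    genetic map.  Second degree is realised as grandparent–grandchild.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}; choose from {RELATIONSHIPS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_info = _chromosome_slices(panel)
    freqs = source.allele_freqs

    def founder(name):
        haps = _founder_haps(freqs, rng)
        tr = {
            "pat": [(c, 0.0, L, (name, 0)) for c, _, _, L in chrom_info],
            "mat": [(c, 0.0, L, (name, 1)) for c, _, _, L in chrom_info],
        }
        return haps, tr

    def child_of(haps_f, tr_f, haps_m, tr_m, fname, mname):
        # gametes recombine the parent's own two haplotype mosaics; founder
        # labels propagate through the parent's tract functions
        g_f, t_f = _meiosis(haps_f, ("pat", "mat"), chrom_info, rng)
        g_m, t_m = _meiosis(haps_m, ("pat", "mat"), chrom_info, rng)

        def relabel(tracts, parent_tr):
            out = []
            for chrom, s, e, side in tracts:
                for cc, ss, ee, lab in parent_tr[side]:
                    if cc != chrom:
                        continue
                    lo, hi = max(s, ss), min(e, ee)
                    if hi > lo:
                        out.append((chrom, lo, hi, lab))
            return out

        haps = np.stack([g_f, g_m])
        tr = {"pat": relabel(t_f, tr_f), "mat": relabel(t_m, tr_m)}
        return haps, tr

    pedigree: list[tuple[str, str]] = []
    if relationship == "identical":
        haps, tr = founder("A")
        pair = [(haps, tr), (haps, tr)]
    elif relationship == "unrelated":
        pair = [founder("A"), founder("B")]
    elif relationship == "parent-offspring":
        fa, tr_fa = founder("A")
        mo, tr_mo = founder("B")
        ch = child_of(fa, tr_fa, mo, tr_mo, "A", "B")
        pair = [(fa, tr_fa), ch]
        pedigree = [("ind2", "ind1")]
    elif relationship == "full-sib":
        fa, tr_fa = founder("A")
        mo, tr_mo = founder("B")
        pair = [child_of(fa, tr_fa, mo, tr_mo, "A", "B") for _ in range(2)]
    else:  # second-degree: grandparent–grandchild
        gp, tr_gp = founder("A")
        sp, tr_sp = founder("B")
        parent = child_of(gp, tr_gp, sp, tr_sp, "A", "B")
        other, tr_other = founder("C")
        grandchild = child_of(parent[0], parent[1], other, tr_other, "P", "C")
        pair = [(gp, tr_gp), grandchild]

    calls = np.stack([h.sum(axis=0) for h, _ in pair], axis=1).astype(np.int8)
    individuals = [Individual("ind1", group_label="ped"), Individual("ind2", group_label="ped")]
    dataset = GenotypeDataset(panel, individuals, calls, ploidy_mode="diploid")
    ibd0, ibd1, ibd2 = _ibd_fractions(pair[0][1], pair[1][1], chrom_info)
    truth = GroundTruth(
        tracts=pd.DataFrame(
            columns=["individual", "hap", "chrom", "start_m", "end_m", "source"]
        ),
        pedigree=pedigree,
        info={"relationship": relationship, "ibd0": ibd0, "ibd1": ibd1, "ibd2": ibd2},
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Sex-dependent chromosome coverage
# ---------------------------------------------------------------------------

def simulate_sex_coverage(
    sex: str,
    autosomal_depth: float,
    seed: int | np.random.Generator = 0,
    n_autosomal_sites: int = 50_000,
    n_x_sites: int = 4_100,
    n_y_sites: int = 600,
    x_efficiency: float = 0.8,
    y_efficiency: float = 0.8,
) -> dict[str, float]:
    """Read totals per chromosome class under sex-dependent dosage.

    Expected per-site coverage is ``autosomal_depth * copies/2 * efficiency``;
    capture efficiency on the sex chromosomes defaults to the 0.8 that makes
    females show an X-ratio near 0.8 and males near 0.4.
    """
    if autosomal_depth <= 0:
        raise ValueError("autosomal_depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_copies = 2 if sex == "F" else 1
    y_copies = 0 if sex == "F" else 1
    reads_auto = rng.poisson(autosomal_depth * n_autosomal_sites)
    reads_x = rng.poisson(autosomal_depth * (x_copies / 2) * x_efficiency * n_x_sites)
    reads_y = rng.poisson(autosomal_depth * (y_copies / 2) * y_efficiency * n_y_sites)
    auto_cov = reads_auto / n_autosomal_sites
    return {
        "autosomal_coverage": auto_cov,
        "x_coverage": reads_x / n_x_sites,
        "y_coverage": reads_y / n_y_sites,
        "x_ratio": (reads_x / n_x_sites) / auto_cov if auto_cov > 0 else np.nan,
        "y_ratio": (reads_y / n_y_sites) / auto_cov if auto_cov > 0 else np.nan,
    }
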