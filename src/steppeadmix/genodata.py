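"""Data model and I/O for SNP panels, genotypes and read observations.

The central object is :class:`GenotypeDataset`: an alternate-allele count
matrix over a 1240K-style SNP panel, either diploid ({0,1,2}) or
pseudo-haploid ({0,2}), with ``9`` marking missing data as in the
EIGENSTRAT geno format.  Low-coverage ancient individuals are represented
pseudo-haploidly: at every covered site a single sequencing read is drawn
at random and its allele is doubled, so no heterozygous calls exist.

Read-level data (per-SNP ref/alt counts plus optional per-read records)
live in :class:`ReadObservations`; they feed pseudo-haploid calling,
damage profiling and read-count likelihood models.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 9

AUTOSOMES = tuple(str(c) for c in range(1, 23))

_CHROM_ORDER = {c: i for i, c in enumerate(AUTOSOMES + ("X", "Y"))}

_EIG_CHROM = {"X": "23", "Y": "24"}
_EIG_CHROM_REV = {"23": "X", "24": "Y", "90": "MT"}


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, bad symbol, bad column)."""


def normalize_chrom(c: str) -> str:
    c = str(c)
    if c.startswith("chr"):
        c = c[3:]
    return _EIG_CHROM_REV.get(c, c)


def chrom_sort_key(c: str) -> int:
    return _CHROM_ORDER.get(c, 99)


@dataclass
class SnpPanel:
    """A biallelic SNP panel sorted by (chromosome, physical position).

    ``genetic_pos`` is stored in Morgans (EIGENSTRAT snp-file column 3);
    conversion to centiMorgans happens only at presentation time.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, genetic_pos, physical_pos, ref, alt

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp_id", "chrom", "genetic_pos", "physical_pos", "ref", "alt"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise FormatError(f"panel table missing columns {missing_cols}")
        if (t["ref"] == t["alt"]).any():
            bad = t.index[t["ref"] == t["alt"]][0]
            raise FormatError(f"ref == alt at panel row {bad}")
        order = t["chrom"].map(chrom_sort_key)
        key = pd.DataFrame({"c": order.values, "p": t["physical_pos"].values})
        if not key.sort_values(["c", "p"]).index.equals(key.index):
            raise FormatError("panel not sorted by (chromosome, physical_pos)")
        for _, sub in t.groupby("chrom", sort=False):
            g = sub["genetic_pos"].to_numpy()
            if np.any(np.diff(g) < 0):
                raise FormatError("genetic_pos decreasing within a chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def genetic_pos(self) -> np.ndarray:
        return self.table["genetic_pos"].to_numpy(dtype=float)

    @property
    def ref(self) -> np.ndarray:
        return self.table["ref"].to_numpy()

    @property
    def alt(self) -> np.ndarray:
        return self.table["alt"].to_numpy()

    def autosomal_mask(self) -> np.ndarray:
        return np.isin(self.chrom, AUTOSOMES)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def transition_ct_ga_mask(self) -> np.ndarray:
        """C/T and G/A SNPs: the classes affected by deamination damage."""
        pairs = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}
        return np.fromiter(
            ((r, a) in pairs for r, a in zip(self.ref, self.alt)),
            dtype=bool,
            count=len(self),
        )

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        return SnpPanel(self.table.loc[mask].reset_index(drop=True))

    def block_ids(self, block_cm: float = 5.0, chroms: Sequence[str] | None = None) -> np.ndarray:
        """Contiguous genetic-distance blocks for the block jackknife.

        Returns an int array mapping every SNP to a block; blocks never
        span chromosomes and are ``block_cm`` centiMorgans wide (the last
        block of a chromosome may be short).  SNPs on chromosomes outside
        ``chroms`` (when given) get block id -1.
        """
        width_m = block_cm / 100.0
        ids = np.full(len(self), -1, dtype=int)
        nxt = 0
        for chrom in dict.fromkeys(self.chrom):
            if chroms is not None and chrom not in chroms:
                continue
            m = self.chrom == chrom
            g = self.genetic_pos[m]
            local = np.floor((g - g.min()) / width_m).astype(int)
            # re-index to consecutive ids so empty windows don't create empty blocks
            _, local = np.unique(local, return_inverse=True)
            ids[m] = local + nxt
            nxt = ids[m].max() + 1
        return ids


@dataclass
class Individual:
    individual_id: str
    genetic_sex: str = "U"  # {M, F, U}
    group_label: str = ""
    age_bp: float | None = None
    age_se: float | None = None
    library_type: str = "UDG-half"  # {UDG-half, ssDNA, none}


@dataclass
class GenotypeDataset:
    """Alternate-allele counts per (SNP, individual).

    ``calls`` has shape (n_snps, n_individuals) with values in {0, 1, 2, 9};
    pseudo-haploid mode restricts non-missing values to {0, 2}.
    """

    panel: SnpPanel
    individuals: list[Individual]
    calls: np.ndarray
    ploidy_mode: str = "pseudo-haploid"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.panel), len(self.individuals)):
            raise FormatError(
                f"calls shape {self.calls.shape} != (n_snps={len(self.panel)}, "
                f"n_individuals={len(self.individuals)})"
            )
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate individual ids")
        allowed = {0, 1, 2, MISSING} if self.ploidy_mode == "diploid" else {0, 2, MISSING}
        observed = set(np.unique(self.calls).tolist())
        if not observed <= allowed:
            raise FormatError(
                f"calls contain {sorted(observed - allowed)} not allowed in "
                f"{self.ploidy_mode} mode"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def column(self, individual_id: str) -> np.ndarray:
        return self.calls[:, self.individual_ids.index(individual_id)]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def group_map(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for j, ind in enumerate(self.individuals):
            groups.setdefault(ind.group_label, []).append(j)
        return groups

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.panel.subset(mask), list(self.individuals), self.calls[mask], self.ploidy_mode
        )


@dataclass
class ReadRecord:
    """One aligned read: reference bases and read bases over the alignment.

    Positions are 1-based along the read; ``"N"`` in ``seq`` marks a masked
    base.  Used for terminal-damage profiling, so only substitutions matter
    (no indel representation).
    """

    ref: str
    seq: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.ref) != len(self.seq):
            raise FormatError("read ref/seq length mismatch")


@dataclass
class ReadObservations:
    """Per-(SNP, individual) counts of panel-allele reads, plus optional reads.

    Counts refer only to bases that already passed the configured base/mapping
    quality thresholds (the pipeline's Q30/q30 convention); bases matching
    neither panel allele are dropped before counting.
    """

    panel: SnpPanel
    individuals: list[Individual]
    n_ref: np.ndarray  # (n_snps, n_individuals) int32
    n_alt: np.ndarray
    reads: dict[str, list[ReadRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_ref = np.asarray(self.n_ref, dtype=np.int32)
        self.n_alt = np.asarray(self.n_alt, dtype=np.int32)
        shape = (len(self.panel), len(self.individuals))
        if self.n_ref.shape != shape or self.n_alt.shape != shape:
            raise FormatError("read count matrices must be (n_snps, n_individuals)")
        if (self.n_ref < 0).any() or (self.n_alt < 0).any():
            raise ValueError("negative read counts")

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O (unpacked ASCII dialect)
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeDataset:
    """Read an unpacked-ASCII EIGENSTRAT trio into a :class:`GenotypeDataset`.

    Geno symbols map 0/1/2 to alternate-allele counts and '9' to missing.
    The dataset is flagged pseudo-haploid when no '1' occurs anywhere.
    """
    with _open_text(snp_path) as fh:
        rows = []
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FormatError(f"{snp_path}:{lineno}: expected 6 columns, got {len(parts)}")
            rows.append(
                (
                    parts[0],
                    normalize_chrom(parts[1]),
                    float(parts[2]),
                    int(parts[3]),
                    parts[4],
                    parts[5],
                )
            )
    panel = SnpPanel(
        pd.DataFrame(
            rows, columns=["snp_id", "chrom", "genetic_pos", "physical_pos", "ref", "alt"]
        )
    )

    individuals = []
    with _open_text(ind_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sex = parts[1] if len(parts) > 1 else "U"
            label = parts[2] if len(parts) > 2 else ""
            individuals.append(
                Individual(parts[0], genetic_sex=sex if sex in "MFU" else "U", group_label=label)
            )

    n_ind = len(individuals)
    calls = np.empty((len(panel), n_ind), dtype=np.int8)
    lut = np.full(128, -1, dtype=np.int8)
    for sym, val in (("0", 0), ("1", 1), ("2", 2), ("9", MISSING)):
        lut[ord(sym)] = val
    with _open_text(geno_path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if n_lines >= len(panel):
                raise FormatError(
                    f"{geno_path}:{lineno}: more geno rows than snp rows ({len(panel)})"
                )
            if len(line) != n_ind:
                raise FormatError(
                    f"{geno_path}:{lineno}: {len(line)} genotypes for {n_ind} individuals"
                )
            codes = lut[np.frombuffer(line.encode(), dtype=np.uint8)]
            if (codes < 0).any():
                bad = line[int(np.argmax(codes < 0))]
                raise FormatError(f"{geno_path}:{lineno}: invalid geno symbol {bad!r}")
            calls[n_lines] = codes
            n_lines += 1
    if n_lines != len(panel):
        raise FormatError(
            f"{geno_path}: {n_lines} geno rows but {len(panel)} snp rows"
        )
    mode = "diploid" if (calls == 1).any() else "pseudo-haploid"
    return GenotypeDataset(panel, individuals, calls, ploidy_mode=mode)


def write_eigenstrat(dataset: GenotypeDataset, out_prefix) -> tuple[str, str, str]:
    """Write ``<prefix>.geno/.snp/.ind`` in the unpacked ASCII dialect."""
    if dataset.n_individuals == 0:
        raise ValueError("refusing to write geno rows of length 0 (no individuals)")
    prefix = str(out_prefix)
    geno_path, snp_path, ind_path = prefix + ".geno", prefix + ".snp", prefix + ".ind"
    symbols = np.array([b"0", b"1", b"2", b"", b"", b"", b"", b"", b"", b"9"])
    with open(geno_path, "w") as fh:
        for row in dataset.calls:
            fh.write("".join(s.decode() for s in symbols[row]) + "\n")
    with open(snp_path, "w") as fh:
        for r in dataset.panel.table.itertuples(index=False):
            chrom = _EIG_CHROM.get(r.chrom, r.chrom)
            fh.write(
                f"{r.snp_id}\t{chrom}\t{r.genetic_pos:.6f}\t{r.physical_pos}\t{r.ref}\t{r.alt}\n"
            )
    with open(ind_path, "w") as fh:
        for ind in dataset.individuals:
            fh.write(f"{ind.individual_id}\t{ind.genetic_sex}\t{ind.group_label or 'Ignore'}\n")
    return geno_path, snp_path, ind_path


# ---------------------------------------------------------------------------
# Pileup input
# ---------------------------------------------------------------------------

def _parse_pileup_bases(bases: str) -> list[str]:
    """Expand a samtools-pileup base string into one symbol per read base."""
    out: list[str] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # start-of-read marker + mapping quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num or 0)
        elif c in ".,":
            out.append(".")
            i += 1
        else:
            out.append(c.upper())
            i += 1
    return out


def read_pileup_counts(
    pileup_path, panel: SnpPanel, individuals: Sequence[Individual]
) -> ReadObservations:
    """Count panel-allele bases from samtools-pileup-style text.

    Expected columns per individual block: chrom, pos, ref, depth, bases
    (a sixth sample-id column selects the individual; single-sample files
    map everything to the sole individual).  Bases matching neither panel
    allele are dropped — the panel is biallelic.
    """
    ind_ids = [ind.individual_id for ind in individuals]
    col = {iid: j for j, iid in enumerate(ind_ids)}
    site = {
        (c, p): i
        for i, (c, p) in enumerate(
            zip(panel.chrom, panel.table["physical_pos"].to_numpy())
        )
    }
    n_ref = np.zeros((len(panel), len(individuals)), dtype=np.int32)
    n_alt = np.zeros_like(n_ref)
    with _open_text(pileup_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if len(parts) < 5:
                raise FormatError(f"{pileup_path}:{lineno}: expected ≥5 columns")
            key = (normalize_chrom(parts[0]), int(parts[1]))
            if key not in site:
                continue
            i = site[key]
            if len(parts) >= 6 and parts[5] in col:
                j = col[parts[5]]
            elif len(individuals) == 1:
                j = 0
            else:
                raise FormatError(
                    f"{pileup_path}:{lineno}: multi-sample pileup needs a sample-id column"
                )
            ref, alt = panel.ref[i], panel.alt[i]
            for b in _parse_pileup_bases(parts[4]):
                base = ref if b == "." else b
                if base == ref:
                    n_ref[i, j] += 1
                elif base == alt:
                    n_alt[i, j] += 1
    return ReadObservations(panel, list(individuals), n_ref, n_alt)


# ---------------------------------------------------------------------------
# Pseudo-haploid calling, end masking, sample merging
# ---------------------------------------------------------------------------

def call_pseudohaploid(obs: ReadObservations, seed: int | np.random.Generator = 0) -> GenotypeDataset:
    """Randomly draw one read per covered site: the pseudo-haploid caller.

    For each (individual, SNP) with at least one read, one read is chosen
    uniformly at random; the call is 0 if it carries the reference allele
    and 2 if the alternate.  Zero coverage gives missing.  Reproducible for
    a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = obs.depth
    u = rng.random(depth.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(depth > 0, obs.n_alt / np.maximum(depth, 1), 0.0)
    calls = np.where(depth == 0, MISSING, np.where(u < p_alt, 2, 0)).astype(np.int8)
    return GenotypeDataset(obs.panel, list(obs.individuals), calls, ploidy_mode="pseudo-haploid")


MASK_WIDTHS = {"UDG-half": 2, "ssDNA": 10, "none": 0}


def mask_read_ends(read: ReadRecord, library_type: str) -> ReadRecord:
    """Mask terminal bases carrying residual deamination damage.

    UDG-half libraries keep damage in the outermost 2 bases; single-stranded
    (non-UDG) libraries in the outermost 10.  Reads shorter than twice the
    mask width are fully masked.  Idempotent.
    """
    if library_type not in MASK_WIDTHS:
        raise KeyError(f"unknown library_type {library_type!r}")
    w = MASK_WIDTHS[library_type]
    if w == 0:
        return read
    n = len(read.seq)
    if n <= 2 * w:
        return replace(read, seq="N" * n)
    seq = "N" * w + read.seq[w:-w] + "N" * w
    return replace(read, seq=seq)


def merge_duplicate_samples(
    observations: Sequence[ReadObservations], individual_mapping: Mapping[str, str]
) -> ReadObservations:
    """Sum read counts of multiple samples (e.g. tooth + petrosal) per individual.

    ``individual_mapping`` maps sample id -> merged individual id; counts are
    added before pseudo-haploid calling so merged coverage is the union.
    """
    seen: dict[str, str] = {}
    for sample, ind in individual_mapping.items():
        if sample in seen and seen[sample] != ind:
            raise ValueError(f"sample {sample} assigned to two individuals")
        seen[sample] = ind
    panel = observations[0].panel
    merged_ids = list(dict.fromkeys(individual_mapping.values()))
    index = {iid: j for j, iid in enumerate(merged_ids)}
    n_ref = np.zeros((len(panel), len(merged_ids)), dtype=np.int32)
    n_alt = np.zeros_like(n_ref)
    meta: dict[str, Individual] = {}
    reads: dict[str, list[ReadRecord]] = {}
    for obs in observations:
        if len(obs.panel) != len(panel):
            raise FormatError("cannot merge observations over different panels")
        for j, ind in enumerate(obs.individuals):
            if ind.individual_id not in individual_mapping:
                raise KeyError(f"sample {ind.individual_id} missing from mapping")
            target = individual_mapping[ind.individual_id]
            k = index[target]
            n_ref[:, k] += obs.n_ref[:, j]
            n_alt[:, k] += obs.n_alt[:, j]
            meta.setdefault(target, replace(ind, individual_id=target))
            if ind.individual_id in obs.reads:
                reads.setdefault(target, []).extend(obs.reads[ind.individual_id])
    individuals = [meta[iid] for iid in merged_ids]
    return ReadObservations(panel, individuals, n_ref, n_alt, reads=reads)
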