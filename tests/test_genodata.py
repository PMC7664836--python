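"""Genotype data model, EIGENSTRAT/pileup I/O and pseudo-haploid calling."""

import numpy as np
import pytest

from steppeadmix import simulate as sim
from steppeadmix.genodata import (
    MISSING,
    FormatError,
    GenotypeDataset,
    Individual,
    ReadObservations,
    ReadRecord,
    call_pseudohaploid,
    mask_read_ends,
    merge_duplicate_samples,
    read_eigenstrat,
    read_pileup_counts,
    write_eigenstrat,
)

from helpers import tiny_panel


def _dataset(panel, calls, mode="pseudo-haploid"):
    inds = [Individual(f"i{j}", "M", "g") for j in range(calls.shape[1])]
    return GenotypeDataset(panel, inds, calls, ploidy_mode=mode)


class TestEigenstrat:
    def test_round_trip_identity(self, tmp_path, rng):
        panel = sim.make_panel(30, rng)
        calls = rng.choice([0, 2, MISSING], size=(len(panel), 3)).astype(np.int8)
        ds = _dataset(panel, calls)
        prefix = tmp_path / "trio"
        g, s, i = write_eigenstrat(ds, prefix)
        back = read_eigenstrat(g, s, i)
        np.testing.assert_array_equal(back.calls, ds.calls)
        assert back.individual_ids == ds.individual_ids
        assert list(back.panel.table["snp_id"]) == list(panel.table["snp_id"])
        assert list(back.panel.chrom) == list(panel.chrom)
        assert back.ploidy_mode == "pseudo-haploid"

    def test_symbol_mapping(self, tmp_path):
        (tmp_path / "x.geno").write_text("029\n")
        (tmp_path / "x.snp").write_text("rs1\t1\t0.01\t100\tA\tG\n")
        (tmp_path / "x.ind").write_text("a\tM\tP\nb\tF\tP\nc\tU\tP\n")
        ds = read_eigenstrat(tmp_path / "x.geno", tmp_path / "x.snp", tmp_path / "x.ind")
        np.testing.assert_array_equal(ds.calls[0], [0, 2, MISSING])

    def test_diploid_het_written_as_1(self, tmp_path):
        panel = tiny_panel(1)
        ds = _dataset(panel, np.array([[1]], dtype=np.int8), mode="diploid")
        g, s, i = write_eigenstrat(ds, tmp_path / "het")
        assert open(g).read().strip() == "1"

    def test_dimension_mismatch(self, tmp_path):
        (tmp_path / "x.geno").write_text("00\n00\n")
        (tmp_path / "x.snp").write_text(
            "rs1\t1\t0.01\t100\tA\tG\nrs2\t1\t0.02\t200\tA\tG\nrs3\t1\t0.03\t300\tA\tG\n"
        )
        (tmp_path / "x.ind").write_text("a\tM\tP\nb\tF\tP\n")
        with pytest.raises(FormatError, match="geno rows"):
            read_eigenstrat(tmp_path / "x.geno", tmp_path / "x.snp", tmp_path / "x.ind")

    def test_bad_symbol(self, tmp_path):
        (tmp_path / "x.geno").write_text("0X\n")
        (tmp_path / "x.snp").write_text("rs1\t1\t0.01\t100\tA\tG\n")
        (tmp_path / "x.ind").write_text("a\tM\tP\nb\tF\tP\n")
        with pytest.raises(FormatError, match="invalid geno symbol"):
            read_eigenstrat(tmp_path / "x.geno", tmp_path / "x.snp", tmp_path / "x.ind")

    def test_write_empty_dataset_rejected(self, tmp_path):
        panel = tiny_panel(2)
        ds = GenotypeDataset(panel, [], np.empty((2, 0), dtype=np.int8))
        with pytest.raises(ValueError, match="no individuals"):
            write_eigenstrat(ds, tmp_path / "empty")


class TestPseudohaploidCalling:
    def _obs(self, n_ref, n_alt):
        panel = tiny_panel(len(n_ref))
        inds = [Individual("a")]
        return ReadObservations(
            panel, inds, np.array(n_ref)[:, None], np.array(n_alt)[:, None]
        )

    def test_unanimous_and_missing(self):
        obs = self._obs([5, 0], [0, 0])
        ds = call_pseudohaploid(obs, seed=0)
        assert ds.calls[0, 0] == 0
        assert ds.calls[1, 0] == MISSING

    def test_alt_fraction_matches_binomial(self):
        """n_ref=1, n_alt=1 -> alt call with probability 1/2."""
        panel = tiny_panel(1)
        inds = [Individual("a")]
        n = 10_000
        rng = np.random.default_rng(42)
        hits = 0
        obs = ReadObservations(panel, inds, np.array([[1]]), np.array([[1]]))
        for _ in range(n):
            hits += call_pseudohaploid(obs, seed=rng).calls[0, 0] == 2
        assert abs(hits / n - 0.5) < 0.015

    def test_never_heterozygous_and_missingness_preserved(self, rng):
        panel = sim.make_panel(200, rng)
        n_ref = rng.poisson(0.7, size=(len(panel), 4))
        n_alt = rng.poisson(0.7, size=(len(panel), 4))
        obs = ReadObservations(panel, [Individual(f"i{j}") for j in range(4)], n_ref, n_alt)
        ds = call_pseudohaploid(obs, seed=7)
        assert set(np.unique(ds.calls)) <= {0, 2, MISSING}
        np.testing.assert_array_equal(ds.calls == MISSING, obs.depth == 0)

    def test_seed_reproducibility(self, rng):
        panel = sim.make_panel(100, rng)
        n_ref = rng.poisson(1.0, size=(len(panel), 2))
        n_alt = rng.poisson(1.0, size=(len(panel), 2))
        obs = ReadObservations(panel, [Individual("a"), Individual("b")], n_ref, n_alt)
        a = call_pseudohaploid(obs, seed=5).calls
        b = call_pseudohaploid(obs, seed=5).calls
        np.testing.assert_array_equal(a, b)


class TestEndMasking:
    def test_udg_half_masks_two(self):
        read = ReadRecord("C" * 30, "C" * 30)
        masked = mask_read_ends(read, "UDG-half")
        assert masked.seq == "NN" + "C" * 26 + "NN"

    def test_short_ssdna_fully_masked(self):
        read = ReadRecord("A" * 15, "A" * 15)
        assert mask_read_ends(read, "ssDNA").seq == "N" * 15

    def test_idempotent(self):
        read = ReadRecord("ACGT" * 10, "ACGT" * 10)
        once = mask_read_ends(read, "ssDNA")
        assert mask_read_ends(once, "ssDNA").seq == once.seq

    def test_unknown_library(self):
        with pytest.raises(KeyError):
            mask_read_ends(ReadRecord("AA", "AA"), "mystery")


class TestMergeSamples:
    def _obs(self, sample_id, n_ref, n_alt, panel):
        return ReadObservations(
            panel, [Individual(sample_id)], np.array(n_ref)[:, None], np.array(n_alt)[:, None]
        )

    def test_counts_add(self):
        panel = tiny_panel(1)
        a = self._obs("s1", [3], [0], panel)
        b = self._obs("s2", [1], [2], panel)
        merged = merge_duplicate_samples([a, b], {"s1": "ind", "s2": "ind"})
        assert merged.n_ref[0, 0] == 4 and merged.n_alt[0, 0] == 2

    def test_singleton_identity(self):
        panel = tiny_panel(2)
        a = self._obs("s1", [3, 1], [0, 2], panel)
        merged = merge_duplicate_samples([a], {"s1": "ind"})
        np.testing.assert_array_equal(merged.n_ref[:, 0], [3, 1])
        np.testing.assert_array_equal(merged.n_alt[:, 0], [0, 2])

    def test_merged_coverage_dominates(self, rng):
        panel = sim.make_panel(100, rng)
        obs = [
            ReadObservations(
                panel, [Individual(f"s{k}")],
                rng.poisson(0.5, size=(len(panel), 1)),
                rng.poisson(0.5, size=(len(panel), 1)),
            )
            for k in range(3)
        ]
        merged = merge_duplicate_samples(obs, {f"s{k}": "ind" for k in range(3)})
        for o in obs:
            assert np.all(merged.depth[:, 0] >= o.depth[:, 0])

    def test_conflicting_mapping_rejected(self):
        panel = tiny_panel(1)
        a = self._obs("s1", [1], [0], panel)
        with pytest.raises(KeyError):
            merge_duplicate_samples([a], {"other": "ind"})


class TestPileup:
    def test_counts_panel_alleles_only(self, tmp_path):
        panel = tiny_panel(2, chroms=["1", "2"], ref="A", alt="G")
        # '.'/',' = ref; 'G' = alt; 'T' neither (dropped); ^~ start marker; +2AC insertion
        text = "1\t1000\tA\t5\t..G,T\n2\t1000\tA\t4\t^~.+2ACGg$\n"
        (tmp_path / "p.txt").write_text(text)
        obs = read_pileup_counts(tmp_path / "p.txt", panel, [Individual("a")])
        assert obs.n_ref[0, 0] == 3 and obs.n_alt[0, 0] == 1
        assert obs.n_ref[1, 0] == 1 and obs.n_alt[1, 0] == 2
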