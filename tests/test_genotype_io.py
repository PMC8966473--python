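"""Genotype reading, polarized frequencies, ΔAF and fixed-difference summaries."""

import numpy as np
import pandas as pd
import pytest

import afvec
from afvec.genotype_io import MISSING


def write_vcf_text(path, records, samples):
    """Hand-rolled VCF writer independent of the package's pysam writer."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = {r[0] for r in records}
    for c in sorted(chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, gts in records:
        gt_strs = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gt_strs[g] for g in gts))
    path.write_text("\n".join(lines) + "\n")


class TestReadVariants:
    def test_round_trip_identity(self, tmp_path, small_dataset):
        p = tmp_path / "x.vcf"
        afvec.write_variants(small_dataset.variants, p)
        vt = afvec.read_variants(p, registry=small_dataset.registry)
        assert vt.n_sites == small_dataset.variants.n_sites
        assert np.array_equal(vt.genotypes, small_dataset.variants.genotypes)
        assert np.array_equal(vt.pos, small_dataset.variants.pos)
        assert list(vt.samples) == list(small_dataset.variants.samples)

    def test_skips_multiallelic_and_indels(self, tmp_path):
        samples = ["a", "b"]
        lines = ["##fileformat=VCFv4.2",
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                 "##contig=<ID=chr1>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb"]
        for i in range(1, 10):
            lines.append(f"chr1\t{i * 100}\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0")
        lines.append("chr1\t5000\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2")  # triallelic
        p = tmp_path / "m.vcf"
        p.write_text("\n".join(lines) + "\n")
        vt = afvec.read_variants(p)
        assert vt.n_sites == 9

    def test_region_query_subsets_one_chromosome(self, tmp_path):
        samples = ["a"]
        recs = ([("chr1", i * 10, "A", "C", [1]) for i in range(1, 6)]
                + [("chr2", i * 10, "A", "C", [2]) for i in range(1, 4)])
        p = tmp_path / "r.vcf"
        write_vcf_text(p, recs, samples)
        vt = afvec.read_variants(p, region="chr2")
        assert set(vt.chrom) == {"chr2"} and vt.n_sites == 3
        vt2 = afvec.read_variants(p, region="chr1:10-30")
        assert vt2.n_sites == 3

    def test_unknown_sample_fatal(self, tmp_path):
        p = tmp_path / "u.vcf"
        write_vcf_text(p, [("chr1", 5, "A", "C", [1, 0])], ["s1", "intruder"])
        reg = afvec.SampleRegistry({"P": ("s1",)}, "P")
        with pytest.raises(ValueError, match="intruder"):
            afvec.read_variants(p, registry=reg)


class TestReadPopmap:
    def test_study_shaped_popmap(self, tmp_path):
        # 94 samples over 5 populations, ~20 per site, one flagged as source
        sizes = {"SRC": 20, "D1": 19, "D2": 18, "D3": 19, "D4": 18}
        lines = [f"{pop}_{i}\t{pop}" for pop, n in sizes.items() for i in range(n)]
        p = tmp_path / "popmap.tsv"
        p.write_text("\n".join(lines) + "\n")
        reg = afvec.read_popmap(p, source="SRC")
        assert len(reg.pop_labels) == 5
        assert sum(reg.size(x) for x in reg.pop_labels) == 94
        assert reg.derived == ["D1", "D2", "D3", "D4"]

    def test_single_sample_registry(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("s1\tP\n")
        reg = afvec.read_popmap(p, source="P")
        assert reg.size("P") == 1

    def test_duplicate_sample_fatal(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("s1\tP\ns1\tQ\n")
        with pytest.raises(ValueError, match="duplicate"):
            afvec.read_popmap(p, source="P")

    def test_missing_source_fatal(self, tmp_path):
        p = tmp_path / "ns.tsv"
        p.write_text("s1\tP\n")
        with pytest.raises(ValueError, match="source"):
            afvec.read_popmap(p, source="Z")


def make_table(genotype_rows, samples, chrom="chr1"):
    g = np.array(genotype_rows, dtype=np.int8)
    n = g.shape[0]
    return afvec.VariantTable(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.arange(1, n + 1) * 100,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        genotypes=g, samples=samples)


class TestComputeFrequencies:
    def test_single_site_hand_count(self):
        # pop of 2 samples with genotypes {0,1}: one alt copy in 4 chromosomes
        vt = make_table([[0, 1, 1, 1]], ["a", "b", "c", "d"])
        reg = afvec.SampleRegistry({"S": ("a", "b"), "D": ("c", "d")}, "S")
        f = afvec.compute_frequencies(vt, reg)
        assert f.source_freq[0] == pytest.approx(0.25)

    def test_polarization_flips_major_source_allele(self):
        # source alt frequency 0.8 → polarized allele is REF, reported freq 0.2
        vt = make_table([[2, 2, 1, 1, 0, 1]], ["a", "b", "c", "d", "e", "f"])
        reg = afvec.SampleRegistry({"S": ("a", "b", "c"), "D": ("d", "e", "f")}, "S")
        f = afvec.compute_frequencies(vt, reg)
        src_alt = (2 + 2 + 1) / 6
        assert src_alt > 0.5
        assert f.source_freq[0] == pytest.approx(1 - src_alt)
        assert f.polarized_allele[0] == "A"

    def test_tie_polarizes_to_alt(self):
        vt = make_table([[1, 1, 0, 2]], ["a", "b", "c", "d"])
        reg = afvec.SampleRegistry({"S": ("a", "b"), "D": ("c", "d")}, "S")
        f = afvec.compute_frequencies(vt, reg)
        assert f.source_freq[0] == pytest.approx(0.5)
        assert f.polarized_to_alt[0]

    def test_matches_brute_force_count_with_missingness(self, small_dataset):
        """Frequencies under a fixed seed equal an independent per-site count."""
        ds = small_dataset
        f = afvec.compute_frequencies(ds.variants, ds.registry)
        cols = ds.registry.column_indices(ds.variants.samples)
        rng = np.random.default_rng(0)
        for row in rng.choice(f.n_sites, size=30, replace=False):
            site = f.site_index[row]
            for j, pop in enumerate(f.pops):
                gts = [int(ds.variants.genotypes[site, c]) for c in cols[pop]]
                alt = sum(g for g in gts if g >= 0)
                called = 2 * sum(g >= 0 for g in gts)
                expect = alt / called
                if not f.polarized_to_alt[row]:
                    expect = 1 - expect
                assert f.freqs[row, j] == pytest.approx(expect, abs=1e-12)

    def test_frequencies_bounded_and_source_minor(self, small_freqs):
        assert np.all((small_freqs.freqs >= 0) & (small_freqs.freqs <= 1))
        assert np.all(small_freqs.source_freq <= 0.5)

    def test_polarization_idempotent(self, small_freqs):
        """Re-running the polarization rule on polarized output changes nothing."""
        flip = small_freqs.source_freq > 0.5
        assert not np.any(flip)

    def test_low_call_sites_dropped(self):
        vt = make_table([[MISSING, MISSING, 1, 1], [0, 1, 1, 1]], ["a", "b", "c", "d"])
        reg = afvec.SampleRegistry({"S": ("a", "b"), "D": ("c", "d")}, "S")
        f = afvec.compute_frequencies(vt, reg, min_called_fraction=0.5)
        assert f.n_sites == 1 and f.pos[0] == 200


class TestFixedAndWindowed:
    def test_fixed_count_by_construction(self, rng):
        n = 100
        src = np.full(n, 0.3)
        der = np.full(n, 0.6)
        der[[4, 40, 77]] = 1.0  # polarized allele fixed at exactly 3 sites
        f = afvec.AlleleFrequencyTable(
            chrom=np.array(["chr1"] * n, dtype=object), pos=np.arange(1, n + 1),
            ref=np.array(["A"] * n, dtype=object), alt=np.array(["G"] * n, dtype=object),
            pops=["S", "D"], source="S", freqs=np.column_stack([src, der]),
            called=np.full((n, 2), 40), polarized_to_alt=np.ones(n, bool),
            site_index=np.arange(n))
        assert afvec.count_fixed_source_minor(f, "D") == 3

    def test_fixed_count_zero_when_polymorphic(self, small_freqs):
        oracle = int(np.sum(small_freqs.freq(small_freqs.derived[0]) == 1.0))
        assert afvec.count_fixed_source_minor(small_freqs, small_freqs.derived[0]) == oracle

    def test_windowed_delta_af_examples(self):
        f = afvec.AlleleFrequencyTable(
            chrom=np.array(["chr1"] * 3, dtype=object), pos=np.array([10, 80_000, 80_500]),
            ref=np.array(["A"] * 3, dtype=object), alt=np.array(["G"] * 3, dtype=object),
            pops=["S", "D"], source="S",
            freqs=np.array([[0.2, 0.5], [0.3, 0.4], [0.1, 0.4]]),
            called=np.full((3, 2), 40), polarized_to_alt=np.ones(3, bool),
            site_index=np.arange(3))
        w = afvec.windowed_delta_af(f, "D", window_bp=75_000)
        assert w.loc[0, "mean_abs_delta_af"] == pytest.approx(0.3)   # single SNP |0.5-0.2|
        assert w.loc[1, "mean_abs_delta_af"] == pytest.approx(0.2)   # mean of 0.1, 0.3
        assert list(w["n_snps"]) == [1, 2]

    def test_windowed_delta_af_matches_groupby_oracle(self, small_freqs):
        pop = small_freqs.derived[0]
        w = afvec.windowed_delta_af(small_freqs, pop, window_bp=5_000_000)
        oracle = (pd.DataFrame({
            "chrom": small_freqs.chrom,
            "win": (small_freqs.pos - 1) // 5_000_000,
            "v": np.abs(small_freqs.freq(pop) - small_freqs.source_freq)})
            .groupby(["chrom", "win"])["v"].mean())
        got = w.dropna(subset=["mean_abs_delta_af"]).set_index(
            ["chrom", (w["start"] - 1) // 5_000_000])["mean_abs_delta_af"]
        for (chrom, win), val in oracle.items():
            assert got.loc[(chrom, win)] == pytest.approx(val, abs=1e-12)
        # tiling covers every SNP exactly once
        assert w["n_snps"].sum() == small_freqs.n_sites
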