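"""Weir-Cockerham Fst, PBS/PBSn1, block building, outliers, intersection."""

import math

import numpy as np
import pandas as pd
import pytest

from splicediv import formats_io, pbs_scan, synthdata
from splicediv.pbs_scan import (
    block_fst,
    call_outliers,
    filter_sites,
    intersect_genes,
    pbs_scores,
    site_fst_components,
)


def wc_fst_oracle(n1, alt1, het1, n2, alt2, het2):
    """Independent scalar transcription of the Weir & Cockerham (1984)
    two-population estimator (r=2) from genotype tallies."""
    p1 = alt1 / (2.0 * n1)
    p2 = alt2 / (2.0 * n2)
    h1 = het1 / n1
    h2 = het2 / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        a, d = site_fst_components([10], [0], [0], [10], [20], [0])
        assert a[0] / d[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_near_zero(self):
        # same allele frequency and sample size: estimator at or below 0
        a, d = site_fst_components([10], [10], [10], [10], [10], [10])
        assert a[0] / d[0] <= 1e-12

    def test_monomorphic_site_missing(self):
        a, d = site_fst_components([10], [0], [0], [10], [0], [0])
        assert np.isnan(a[0]) and np.isnan(d[0])

    def test_matches_independent_oracle(self, rng):
        for _ in range(300):
            n1, n2 = rng.integers(4, 30, size=2)
            alt1 = int(rng.integers(0, 2 * n1 + 1))
            alt2 = int(rng.integers(0, 2 * n2 + 1))
            het1 = int(rng.integers(0, min(alt1, 2 * n1 - alt1) + 1))
            het2 = int(rng.integers(0, min(alt2, 2 * n2 - alt2) + 1))
            if alt1 + alt2 == 0 or alt1 + alt2 == 2 * (n1 + n2):
                continue
            a, d = site_fst_components([n1], [alt1], [het1], [n2], [alt2], [het2])
            ao, do = wc_fst_oracle(n1, alt1, het1, n2, alt2, het2)
            assert a[0] == pytest.approx(ao, abs=1e-10)
            assert d[0] == pytest.approx(do, abs=1e-10)


class TestFilterSites:
    def _geno(self, tmp_path, rows):
        p = tmp_path / "f.vcf"
        samples = [f"a{i}" for i in range(8)] + ["b1", "b2", "c1", "c2"]
        head = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=99999>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        p.write_text(head + rows)
        s2p = {s: s[0] for s in samples}
        return formats_io.read_vcf_genotypes(p, s2p)

    def test_few_focal_genotyped_excluded(self, tmp_path):
        gt_few = "\t".join(["./."] * 3 + ["0/1"] * 5 + ["0/0", "1/1", "0/1", "0/0"])
        gt_ok = "\t".join(["0/1"] * 8 + ["0/0", "1/1", "0/1", "0/0"])
        geno = self._geno(
            tmp_path,
            f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t{gt_few}\n"
            f"chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t{gt_ok}\n",
        )
        mask = filter_sites(geno, "a", min_focal_genotyped=6)
        assert mask.tolist() == [False, True]

    def test_monomorphic_in_focal_but_polymorphic_in_union_kept(self, tmp_path):
        gt = "\t".join(["0/0"] * 8 + ["0/1", "1/1", "0/0", "0/1"])
        geno = self._geno(tmp_path, f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t{gt}\n")
        assert filter_sites(geno, "a").tolist() == [True]

    def test_empty_vcf_empty_mask(self, tmp_path):
        geno = self._geno(tmp_path, "")
        assert len(filter_sites(geno, "a")) == 0


class TestBlockFst:
    def test_all_zero_components(self):
        assert block_fst(np.zeros(5), np.ones(5)) == pytest.approx(0.0)

    def test_uniform_components_equal_per_site_value(self):
        a = np.full(5, 0.03)
        d = np.full(5, 0.10)
        assert block_fst(a, d) == pytest.approx(0.3, abs=1e-12)

    def test_hand_ratio_of_sums(self):
        a = np.array([0.1, 0.0, -0.02, 0.05, 0.07])
        d = np.array([0.2, 0.1, 0.10, 0.20, 0.20])
        assert block_fst(a, d) == pytest.approx(0.2 / 0.8, abs=1e-12)

    def test_zero_denominator_missing(self):
        assert np.isnan(block_fst(np.zeros(5), np.zeros(5)))


class TestPbsScores:
    def test_all_zero_fst(self):
        s = pbs_scores(0.0, 0.0, 0.0)
        assert all(v == 0.0 for v in s.values())

    def test_symmetric_short_branches(self):
        f = 1.0 - math.exp(-0.2)  # T = 0.2
        s = pbs_scores(f, f, 0.0)
        assert s["PBS_A"] == pytest.approx(0.2, abs=1e-12)
        assert s["PBS_B"] == pytest.approx(0.0, abs=1e-12)

    def test_unit_branch_case(self):
        f = 1.0 - math.exp(-1.0)  # T = 1
        s = pbs_scores(f, f, 0.0)
        assert s["PBS_A"] == pytest.approx(1.0, abs=1e-12)
        assert s["PBSn1_A"] == pytest.approx(0.5, abs=1e-12)
        assert s["PBS_B"] == s["PBS_C"] == 0.0

    def test_population_relabelling_permutes_scores(self, rng):
        fab, fac, fbc = rng.uniform(0.0, 0.8, 3)
        s = pbs_scores(fab, fac, fbc)
        # labels (B, A, C): pairs BA=AB, BC, AC
        t = pbs_scores(fab, fbc, fac)
        assert t["PBS_A"] == pytest.approx(s["PBS_B"], abs=1e-12)
        assert t["PBS_B"] == pytest.approx(s["PBS_A"], abs=1e-12)
        assert t["PBS_C"] == pytest.approx(s["PBS_C"], abs=1e-12)

    def test_pbsn1_bounded(self, rng):
        for _ in range(100):
            s = pbs_scores(*rng.uniform(0.0, 0.99, 3))
            for k in ("PBSn1_A", "PBSn1_B", "PBSn1_C"):
                assert 0.0 <= s[k] < 1.0

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            pbs_scores(1.0, 0.2, 0.2)


class TestOutliersAndIntersection:
    def test_top_fraction_cardinality(self, rng):
        blocks = pd.DataFrame({"PBSn1_A": rng.uniform(0, 0.5, 200)})
        out = call_outliers(blocks)
        assert out["outlier"].sum() == 2

    def test_constant_scores_all_tie(self):
        blocks = pd.DataFrame({"PBSn1_A": np.full(50, 0.1)})
        out = call_outliers(blocks)
        assert out["outlier"].all()

    def test_overlap_and_half_open_boundary(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 100],
             "end": [200, 200], "name": ["gA", "gB"]}
        )
        blocks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [150, 200], "end": [160, 210]}
        )
        hits = intersect_genes(blocks, genes.iloc[[0]])
        assert len(hits) == 1 and hits["gene"].iloc[0] == "gA"
        # block starting exactly at gene end: no overlap under half-open
        hits2 = intersect_genes(blocks.iloc[[1]], genes.iloc[[0]])
        assert hits2.empty

    def test_chromosome_mismatch_zero_overlaps(self):
        genes = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100],
                              "name": ["g"]})
        blocks = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        assert intersect_genes(blocks, genes).empty

    def test_matches_quadratic_brute_force(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 60),
                "start": rng.integers(0, 900, 60),
                "name": [f"g{i}" for i in range(60)],
            }
        )
        genes["end"] = genes["start"] + rng.integers(1, 150, 60)
        blocks = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 40),
                "start": rng.integers(0, 950, 40),
            }
        )
        blocks["end"] = blocks["start"] + rng.integers(1, 80, 40)
        hits = intersect_genes(blocks, genes)
        got = {(r.gene, r.block_start, r.block_end)
               for r in hits.itertuples(index=False)}
        expected = set()
        for b in blocks.itertuples(index=False):
            for g in genes.itertuples(index=False):
                if b.chrom == g.chrom and b.start < g.end and g.start < b.end:
                    expected.add((g.name, b.start, b.end))
        assert got == expected


class TestScanIntegration:
    def test_symmetric_drift_gives_symmetric_pbsn1(self, tmp_path):
        path, s2p, _ = synthdata.gen_genotype_vcf(
            tmp_path / "sym.vcf", n_snps=600, n_blocks_swept=0,
            pop_sizes={"a": 12, "b": 12, "c": 12},
            divergence_f={"a": 0.1, "b": 0.1, "c": 0.1}, seed=31,
        )
        geno = formats_io.read_vcf_genotypes(path, s2p)
        blocks = pbs_scan.pbs_block_table(geno, "a", "b", "c")
        means = [blocks[f"PBSn1_{x}"].mean() for x in "ABC"]
        assert max(means) - min(means) < 0.02

    def test_tiny_divergence_gives_near_zero_fst(self, tmp_path):
        path, s2p, _ = synthdata.gen_genotype_vcf(
            tmp_path / "flat.vcf", n_snps=400, n_blocks_swept=0,
            pop_sizes={"a": 15, "b": 15, "c": 15},
            divergence_f={"a": 0.005, "b": 0.005, "c": 0.005}, seed=8,
        )
        geno = formats_io.read_vcf_genotypes(path, s2p)
        a, d = site_fst_components(
            geno.n_genotyped["a"], geno.alt_count["a"], geno.het_count["a"],
            geno.n_genotyped["b"], geno.alt_count["b"], geno.het_count["b"],
        )
        ok = ~np.isnan(a)
        mean_fst = np.sum(a[ok]) / np.sum(d[ok])
        assert abs(mean_fst) < 0.02
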