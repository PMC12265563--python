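"""Population-branch-statistic selection scan.

Per-site Weir & Cockerham (1984) Fst variance components are computed for the
three population pairs, combined over non-overlapping 5-SNP blocks as a ratio
of sums, converted to branch lengths ``T = -ln(1 - Fst)``, and summarised as
the population branch statistic

    PBS_A = (T_AB + T_AC - T_BC) / 2        (cyclically for B and C)

with per-branch values floored at zero, and its bounded normalisation

    PBSn1_A = PBS_A / (1 + PBS_A + PBS_B + PBS_C).

Blocks in the top 1% of PBSn1 for the focal population are flagged as
genomic outliers (no neutral-model p-values are attached), and outlier
blocks are intersected with gene intervals.

Numerical conventions: negative per-site Fst components enter the block
ratio-of-sums unclipped; the block Fst is clipped to [0, 1 - 1e-6] before
the log so branch lengths stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import PopGenotypes, get_logger

__all__ = [
    "site_fst_components",
    "filter_sites",
    "block_fst",
    "pbs_scores",
    "pbs_block_table",
    "call_outliers",
    "intersect_genes",
    "sweep_enrichment_test",
    "FST_CLIP",
]

FST_CLIP = 1.0 - 1e-6


def site_fst_components(n1, alt1, het1, n2, alt2, het2):
    """Weir & Cockerham (1984) two-population variance components per site.

    Inputs are arrays over sites: genotyped individuals ``n``, alternate
    allele count ``alt`` and heterozygote count ``het`` per population.
    Returns ``(a, d)`` with ``d = a + b + c``; sites monomorphic across both
    populations (or with a non-positive denominator) get NaN in both.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.asarray(alt1, dtype=float) / (2.0 * n1)
        p2 = np.asarray(alt2, dtype=float) / (2.0 * n2)
        h1 = np.asarray(het1, dtype=float) / n1
        h2 = np.asarray(het2, dtype=float) / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        d = a + b + c

    mono = (pbar <= 0.0) | (pbar >= 1.0)
    invalid = mono | ~np.isfinite(d) | (n1 < 1) | (n2 < 1)
    a = np.where(invalid, np.nan, a)
    d = np.where(invalid, np.nan, d)
    return a, d


def filter_sites(geno: PopGenotypes, focal_pop: str,
                 min_focal_genotyped: int = 6) -> np.ndarray:
    """Boolean mask of sites usable in the scan.

    Keeps sites polymorphic across the union of the three populations with at
    least ``min_focal_genotyped`` genotyped individuals in the focal
    population.  (Multi-allelic records were already dropped at read time.)
    """
    if focal_pop not in geno.pops:
        raise ValueError(f"unknown focal population {focal_pop!r}")
    total_alt = sum(geno.alt_count[p] for p in geno.pops)
    total_n = sum(geno.n_genotyped[p] for p in geno.pops)
    poly = (total_alt > 0) & (total_alt < 2 * total_n)
    enough = geno.n_genotyped[focal_pop] >= min_focal_genotyped
    return poly & enough


def block_fst(a: np.ndarray, d: np.ndarray) -> float:
    """Ratio-of-sums block Fst from per-site WC components, clipped to
    [0, 1 - 1e-6].  Returns NaN for a non-positive denominator."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(a) & np.isfinite(d)
    denom = float(np.sum(d[ok]))
    if denom <= 0:
        return float("nan")
    return float(np.clip(np.sum(a[ok]) / denom, 0.0, FST_CLIP))


def pbs_scores(fst_ab: float, fst_ac: float, fst_bc: float):
    """PBS for the three populations plus PBSn1, from pairwise block Fst.

    Branch lengths ``T = -ln(1 - Fst)``; per-branch PBS floored at zero;
    ``PBSn1_X = PBS_X / (1 + PBS_A + PBS_B + PBS_C)``.  Returns a dict with
    keys PBS_A/B/C and PBSn1_A/B/C.
    """
    for f in (fst_ab, fst_ac, fst_bc):
        if not np.isfinite(f) or f < 0 or f > FST_CLIP:
            raise ValueError("block Fst must be finite in [0, 1 - 1e-6]")
    t_ab = -np.log(1.0 - fst_ab)
    t_ac = -np.log(1.0 - fst_ac)
    t_bc = -np.log(1.0 - fst_bc)
    pbs_a = max(0.0, (t_ab + t_ac - t_bc) / 2.0)
    pbs_b = max(0.0, (t_ab + t_bc - t_ac) / 2.0)
    pbs_c = max(0.0, (t_ac + t_bc - t_ab) / 2.0)
    norm = 1.0 + pbs_a + pbs_b + pbs_c
    return {
        "PBS_A": pbs_a,
        "PBS_B": pbs_b,
        "PBS_C": pbs_c,
        "PBSn1_A": pbs_a / norm,
        "PBSn1_B": pbs_b / norm,
        "PBSn1_C": pbs_c / norm,
    }


def pbs_block_table(
    geno: PopGenotypes,
    focal_pop: str,
    pop_b: str,
    pop_c: str,
    block_size: int = 5,
    min_focal_genotyped: int = 6,
) -> pd.DataFrame:
    """Full block scan: filter sites, form non-overlapping ``block_size``-SNP
    blocks in genomic order per chromosome (trailing partial blocks dropped),
    compute pairwise block Fst, PBS and PBSn1 for the focal population.

    Block intervals are reported in BED convention (0-based half-open, from
    the first to the last SNP of the block).
    """
    pops = (focal_pop, pop_b, pop_c)
    if len(set(pops)) != 3 or not set(pops) <= set(geno.pops):
        raise ValueError("need three distinct populations present in the data")
    mask = filter_sites(geno, focal_pop, min_focal_genotyped)

    comp = {}
    for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
        px = pops[("A", "B", "C").index(x)]
        py = pops[("A", "B", "C").index(y)]
        comp[f"{x}{y}"] = site_fst_components(
            geno.n_genotyped[px], geno.alt_count[px], geno.het_count[px],
            geno.n_genotyped[py], geno.alt_count[py], geno.het_count[py],
        )

    rows = []
    skipped = 0
    for chrom in pd.unique(geno.chrom):
        idx = np.where((geno.chrom == chrom) & mask)[0]
        idx = idx[np.argsort(geno.pos[idx], kind="mergesort")]
        n_blocks = len(idx) // block_size
        for b in range(n_blocks):
            sites = idx[b * block_size:(b + 1) * block_size]
            fst = {}
            for pair, (a, d) in comp.items():
                fst[pair] = block_fst(a[sites], d[sites])
            if any(np.isnan(v) for v in fst.values()):
                skipped += 1
                continue
            scores = pbs_scores(fst["AB"], fst["AC"], fst["BC"])
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(geno.pos[sites[0]]) - 1,
                    "end": int(geno.pos[sites[-1]]),
                    "block_index": b,
                    "n_snps": block_size,
                    "fst_AB": fst["AB"],
                    "fst_AC": fst["AC"],
                    "fst_BC": fst["BC"],
                    **scores,
                }
            )
    if skipped:
        get_logger().info("pbs_block_table: skipped %d blocks with zero "
                          "Fst denominator", skipped)
    return pd.DataFrame(rows)


def call_outliers(blocks: pd.DataFrame, score_col: str = "PBSn1_A",
                  top_fraction: float = 0.01) -> pd.DataFrame:
    """Flag blocks at or above the empirical (1 - top_fraction) quantile of
    the score; ties at the threshold are all included."""
    out = blocks.copy()
    if out.empty:
        out["outlier"] = pd.Series(dtype=bool)
        return out
    scores = out[score_col].to_numpy(dtype=float)
    thr = float(np.quantile(scores, 1.0 - top_fraction))
    out["outlier"] = scores >= thr
    if np.all(scores == scores[0]):
        get_logger().warning("call_outliers: constant scores, every block "
                             "ties at the threshold")
    return out


def intersect_genes(blocks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Half-open interval intersection of (outlier) blocks with gene
    intervals; any overlap of >= 1 bp counts; one row per (gene, block)."""
    if blocks.empty or genes.empty:
        return pd.DataFrame(columns=["gene", "chrom", "gene_start", "gene_end",
                                     "block_start", "block_end"])
    shared = set(blocks["chrom"]) & set(genes["chrom"])
    if not shared:
        get_logger().warning("intersect_genes: no shared chromosome names")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), r.name)
            for r in sub.itertuples(index=False)
        )
    rows = []
    for r in blocks.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(int(r.start), int(r.end))):
            rows.append(
                {
                    "gene": iv.data,
                    "chrom": r.chrom,
                    "gene_start": iv.begin,
                    "gene_end": iv.end,
                    "block_start": int(r.start),
                    "block_end": int(r.end),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "gene_start", "gene_end",
                                       "block_start", "block_end"]
                        ).drop_duplicates().reset_index(drop=True)


def sweep_enrichment_test(outlier_flags, swept_flags, n_perm: int = 1000,
                          seed: int = 0) -> float:
    """One-sided permutation p for enrichment of truly swept blocks among
    outlier calls: the swept-flag labels are reshuffled across blocks and the
    overlap count recomputed; +1-corrected p."""
    outlier = np.asarray(outlier_flags, dtype=bool)
    swept = np.asarray(swept_flags, dtype=bool)
    if outlier.shape != swept.shape:
        raise ValueError("flag vectors must align")
    rng = np.random.default_rng(seed)
    obs = int(np.sum(outlier & swept))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(swept)
        if int(np.sum(outlier & perm)) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)
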