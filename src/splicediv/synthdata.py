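"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline (differential splicing, allele-specific
splicing, cis/trans assignment, the PBSn1 scan, pleiotropy contrasts) can be
exercised on data produced here, with a :class:`TruthLedger` recording the
planted effects so that recovery and calibration are testable.

Count model
-----------
Total junction depth per event per sample is log-normal around ``depth_mean``;
the split into inclusion vs skipping reads is beta-binomial around the
length-weighted inclusion probability implied by the true PSI (concentration
``bb_concentration``; ``None`` gives the clean binomial limit).

Genotype model
--------------
Balding-Nichols: each site draws an ancestral frequency, then per-population
frequencies from a Beta distribution whose spread is set by a per-branch drift
parameter F.  A selective sweep is emulated by multiplying the focal
population's F by ``sweep_factor`` (default 20x) inside chosen 5-SNP blocks.

These generators emulate the experimental design of a wild-derived inbred
mouse panel reared on standard vs high-fat diets, with F1 hybrids for
allele-resolved splicing and three-population exome genotypes for selection
scans; they simulate junction counts and allele frequencies directly, not
reads or alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import EVENT_CLASSES, EventTable, write_bed_intervals, \
    write_event_table, write_sample_sheet

__all__ = [
    "SimConfig",
    "TruthLedger",
    "AnnotationBundle",
    "gen_splice_dataset",
    "gen_f1_dataset",
    "gen_genotype_vcf",
    "gen_annotations",
    "write_fixture_bundle",
]

TRUTH_CATEGORIES = (
    "null",
    "group_effect",
    "gxe",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "sweep",
)

# effective form lengths drawn per event class (inclusion form, skip form)
_FORM_LENGTHS = {
    "SE": ((2, 3), (1,)),
    "RI": ((2, 3), (1,)),
    "MXE": ((2,), (2,)),
    "A3SS": ((1, 2), (1,)),
    "A5SS": ((1, 2), (1,)),
}


@dataclass
class SimConfig:
    """Study-design parameters for the splicing simulators.

    Defaults mirror the experimental design being emulated: two wild-derived
    strains, five replicates per group, and read depths around 100 junction
    reads per event per sample.
    """

    n_events: int = 2000
    n_reps_per_group: int = 5
    groups: tuple = (("SARB", "F", "STD"), ("MANB", "F", "STD"))
    depth_mean: float = 100.0
    effect_frac: float = 0.1
    effect_dpsi: float = 0.2
    gxe_frac: float = 0.0
    bb_concentration: float | None = 50.0
    depth_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("effect_frac", "gxe_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.effect_dpsi <= 1.0:
            raise ValueError("effect_dpsi must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_reps_per_group < 2:
            raise ValueError("n_reps_per_group must be >= 2")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")


@dataclass
class TruthLedger:
    """Ground truth for simulated entities, one row per entity."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        bad = ~self.df["category"].isin(TRUTH_CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown truth categories: {sorted(self.df.loc[bad, 'category'].unique())}"
            )
        if self.df["unit_id"].duplicated().any():
            raise ValueError("duplicate unit_id in truth ledger")

    def category_counts(self) -> pd.Series:
        return self.df["category"].value_counts()


def _group_label(g) -> str:
    return "_".join(g)


def _draw_counts(rng, true_psi, l_I, l_S, depth_mean, depth_sigma, conc):
    """Draw (I, S) matrices given an (events x samples) true-PSI matrix."""
    n_ev, n_s = true_psi.shape
    mu = np.log(depth_mean) - 0.5 * depth_sigma**2
    total = np.maximum(
        np.rint(rng.lognormal(mu, depth_sigma, size=(n_ev, n_s))).astype(np.int64), 1
    )
    p_eff = true_psi * l_I / (true_psi * l_I + (1.0 - true_psi) * l_S)
    if conc is None:
        I = rng.binomial(total, p_eff)
    else:
        a = p_eff * conc
        b = (1.0 - p_eff) * conc
        p_rep = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
        I = rng.binomial(total, p_rep)
    S = total - I
    return I, S


def _event_frame(rng, n_events):
    classes = np.array([EVENT_CLASSES[i % 5] for i in range(n_events)])
    l_I = np.array([rng.choice(_FORM_LENGTHS[c][0]) for c in classes])
    l_S = np.array([rng.choice(_FORM_LENGTHS[c][1]) for c in classes])
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_events)])
    event_ids = np.array([f"ev{i:05d}" for i in range(n_events)])
    return event_ids, gene_ids, classes, l_I, l_S


def gen_splice_dataset(config: SimConfig):
    """Replicate junction-count table with strain/diet effects on PSI.

    Returns ``(event_table, sample_sheet, truth)``.  A fraction
    ``effect_frac`` of events carries a true strain effect of magnitude
    ``effect_dpsi`` (random sign); a fraction ``gxe_frac`` of those is
    diet-specific (effect present in HF groups only), which requires both
    diets among the groups.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    event_ids, gene_ids, classes, l_I, l_S = _event_frame(rng, n)

    diets = {g[2] for g in config.groups}
    if config.gxe_frac > 0 and config.effect_frac > 0 and diets != {"STD", "HF"}:
        raise ValueError("gxe effects require both STD and HF groups")

    n_effect = int(round(config.effect_frac * n))
    n_gxe = int(round(config.gxe_frac * n_effect))
    category = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    effect_idx = order[:n_effect]
    category[effect_idx] = "group_effect"
    category[effect_idx[:n_gxe]] = "gxe"

    psi0 = rng.uniform(0.2, 0.8, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    d = config.effect_dpsi * sign

    # strain contrast: groups sharing the first group's strain sit at
    # psi0 - d/2, all other strains at psi0 + d/2
    base_strain = config.groups[0][0]
    samples, cols = [], []
    true_psi_cols = {}
    for g in config.groups:
        label = _group_label(g)
        strain, _, diet = g
        shift = np.where(
            category == "null",
            0.0,
            np.where(
                (category == "gxe") & (diet != "HF"),
                0.0,
                np.where(strain == base_strain, -0.5, 0.5),
            ),
        )
        psi_g = np.clip(psi0 + shift * d, 0.01, 0.99)
        true_psi_cols[f"true_psi_{label}"] = psi_g
        for r in range(config.n_reps_per_group):
            samples.append(f"{label}_r{r + 1}")
            cols.append(psi_g)
    true_psi = np.column_stack(cols)

    I, S = _draw_counts(
        rng, true_psi, l_I.reshape(-1, 1), l_S.reshape(-1, 1),
        config.depth_mean, config.depth_sigma, config.bb_concentration,
    )
    df = pd.DataFrame(
        {
            "event_id": event_ids,
            "gene_id": gene_ids,
            "event_class": classes,
            "IJC": [",".join(map(str, row)) for row in I],
            "SJC": [",".join(map(str, row)) for row in S],
            "IncFormLen": l_I,
            "SkipFormLen": l_S,
        }
    )
    table = EventTable(df=df, samples=samples)

    sheet_rows = []
    for g in config.groups:
        for r in range(config.n_reps_per_group):
            sheet_rows.append(
                {
                    "sample_id": f"{_group_label(g)}_r{r + 1}",
                    "strain": g[0],
                    "sex": g[1],
                    "diet": g[2],
                    "replicate": r + 1,
                }
            )
    sheet = pd.DataFrame(sheet_rows)

    truth_df = pd.DataFrame(
        {
            "unit_id": event_ids,
            "category": category,
            "effect_size": np.where(category == "null", 0.0, d),
            **true_psi_cols,
        }
    )
    return table, sheet, TruthLedger(df=truth_df)


def gen_f1_dataset(
    config: SimConfig,
    cis_frac: float,
    trans_frac: float,
    cis_by_diet_frac: float = 0.0,
):
    """Parental event tables plus paired allele-resolved hybrid counts.

    Category construction (per affected event, effect magnitude
    ``config.effect_dpsi``):

    * ``cis_only`` — parents differ by d and the hybrid's two alleles differ
      by the same d (the regulatory change rides with the allele);
    * ``trans_only`` — parents differ by d but both hybrid alleles sit at the
      parental midpoint (a shared diffusible factor);
    * ``cis_plus_trans`` (requested via ``cis_by_diet_frac``? no —) see below;
    * ``gxe`` marks cis-by-diet events: the cis pattern is present on the
      high-fat diet only, with parents and alleles equal on standard diet.

    Returns ``(parent_tables, hybrid_pairs, truth)`` where ``parent_tables``
    maps diet -> :class:`EventTable` over both parental strains and
    ``hybrid_pairs`` is a long DataFrame with per-replicate allele-1/allele-2
    counts per diet.
    """
    for name, v in [("cis_frac", cis_frac), ("trans_frac", trans_frac),
                    ("cis_by_diet_frac", cis_by_diet_frac)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if cis_frac + trans_frac + cis_by_diet_frac > 1.0 + 1e-12:
        raise ValueError("category fractions must sum to at most 1")

    rng = np.random.default_rng(config.seed)
    n = config.n_events
    event_ids, gene_ids, classes, l_I, l_S = _event_frame(rng, n)

    n_cis = int(round(cis_frac * n))
    n_trans = int(round(trans_frac * n))
    n_cbd = int(round(cis_by_diet_frac * n))
    category = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    category[order[:n_cis]] = "cis_only"
    category[order[n_cis:n_cis + n_trans]] = "trans_only"
    category[order[n_cis + n_trans:n_cis + n_trans + n_cbd]] = "gxe"

    psi0 = rng.uniform(0.3, 0.7, size=n)
    d = config.effect_dpsi * rng.choice([-1.0, 1.0], size=n)
    half = d / 2.0

    def clip(x):
        return np.clip(x, 0.01, 0.99)

    strains = (config.groups[0][0], config.groups[1][0])
    parent_tables = {}
    truth_cols = {}
    n_rep = config.n_reps_per_group
    hybrid_rows = []
    for diet in ("STD", "HF"):
        active = (category == "cis_only") | (category == "trans_only") | (
            (category == "gxe") & (diet == "HF")
        )
        p1 = clip(np.where(active, psi0 + half, psi0))
        p2 = clip(np.where(active, psi0 - half, psi0))
        cis_like = (category == "cis_only") | ((category == "gxe") & (diet == "HF"))
        a1 = clip(np.where(cis_like, psi0 + half, psi0))
        a2 = clip(np.where(cis_like, psi0 - half, psi0))
        truth_cols[f"true_psi_parent1_{diet}"] = p1
        truth_cols[f"true_psi_parent2_{diet}"] = p2
        truth_cols[f"true_psi_allele1_{diet}"] = a1
        truth_cols[f"true_psi_allele2_{diet}"] = a2

        par_psi = np.column_stack([p1] * n_rep + [p2] * n_rep)
        I, S = _draw_counts(
            rng, par_psi, l_I.reshape(-1, 1), l_S.reshape(-1, 1),
            config.depth_mean, config.depth_sigma, config.bb_concentration,
        )
        par_samples = [f"{strains[0]}_{diet}_r{r + 1}" for r in range(n_rep)] + [
            f"{strains[1]}_{diet}_r{r + 1}" for r in range(n_rep)
        ]
        pdf = pd.DataFrame(
            {
                "event_id": event_ids,
                "gene_id": gene_ids,
                "event_class": classes,
                "IJC": [",".join(map(str, row)) for row in I],
                "SJC": [",".join(map(str, row)) for row in S],
                "IncFormLen": l_I,
                "SkipFormLen": l_S,
            }
        )
        parent_tables[diet] = EventTable(df=pdf, samples=par_samples)

        hyb_psi1 = np.column_stack([a1] * n_rep)
        hyb_psi2 = np.column_stack([a2] * n_rep)
        I1, S1 = _draw_counts(
            rng, hyb_psi1, l_I.reshape(-1, 1), l_S.reshape(-1, 1),
            config.depth_mean, config.depth_sigma, config.bb_concentration,
        )
        I2, S2 = _draw_counts(
            rng, hyb_psi2, l_I.reshape(-1, 1), l_S.reshape(-1, 1),
            config.depth_mean, config.depth_sigma, config.bb_concentration,
        )
        for i in range(n):
            for r in range(n_rep):
                hybrid_rows.append(
                    (
                        event_ids[i], gene_ids[i], classes[i], diet, r + 1,
                        I1[i, r], S1[i, r], I2[i, r], S2[i, r],
                        l_I[i], l_S[i],
                    )
                )
    hybrid_pairs = pd.DataFrame(
        hybrid_rows,
        columns=[
            "event_id", "gene_id", "event_class", "diet", "replicate",
            "IJC1", "SJC1", "IJC2", "SJC2", "IncFormLen", "SkipFormLen",
        ],
    )
    truth_df = pd.DataFrame(
        {
            "unit_id": event_ids,
            "category": category,
            "effect_size": np.where(category == "null", 0.0, d),
            **truth_cols,
        }
    )
    return parent_tables, hybrid_pairs, TruthLedger(df=truth_df)


def _write_vcf(path, chrom, positions, gt_mat, sample_names):
    """Minimal VCF 4.2 writer for GT-only biallelic SNPs.

    ``gt_mat`` holds alt-allele dosage per (site, sample): 0, 1, 2, or -1
    for missing.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={int(positions[-1]) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for i, pos in enumerate(positions):
            gts = "\t".join(gt_str[int(g)] for g in gt_mat[i])
            fh.write(f"{chrom}\t{int(pos)}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def gen_genotype_vcf(
    path,
    n_snps: int,
    n_blocks_swept: int,
    pop_sizes: dict[str, int],
    divergence_f: dict[str, float],
    seed: int,
    sweep_factor: float = 20.0,
    block_size: int = 5,
    missing_rate: float = 0.0,
    chrom: str = "chr1",
):
    """Three-population genotype VCF with planted high-differentiation blocks.

    The first population (sorted order) is the sweep focal population.  Sites
    that come out monomorphic across the union of populations are redrawn
    (capped retries) so that block indices in the scan line up with the truth
    ledger.  Returns ``(path, sample_to_pop, truth)`` where the truth ledger
    has one row per ``block_size``-SNP block with its swept flag.
    """
    if len(pop_sizes) != 3:
        raise ValueError("exactly three populations required")
    for p, f in divergence_f.items():
        if not 0.0 < f < 1.0:
            raise ValueError(f"divergence_f[{p!r}] must be in (0, 1)")
    if set(pop_sizes) != set(divergence_f):
        raise ValueError("pop_sizes and divergence_f must name the same populations")

    rng = np.random.default_rng(seed)
    pops = sorted(pop_sizes)
    focal = pops[0]
    n_blocks = n_snps // block_size
    swept_blocks = rng.choice(n_blocks, size=n_blocks_swept, replace=False)
    swept_mask = np.zeros(n_blocks, dtype=bool)
    swept_mask[swept_blocks] = True

    sample_names = []
    sample_to_pop = {}
    for p in pops:
        for i in range(pop_sizes[p]):
            s = f"{p}_ind{i + 1}"
            sample_names.append(s)
            sample_to_pop[s] = p

    n_total = sum(pop_sizes.values())
    gt_mat = np.zeros((n_snps, n_total), dtype=np.int8)
    positions = 1000 * (np.arange(n_snps) + 1)

    for i in range(n_snps):
        block = i // block_size
        swept = block < n_blocks and swept_mask[block]
        for _try in range(100):
            p_anc = rng.uniform(0.1, 0.9)
            gts = []
            for p in pops:
                F = divergence_f[p]
                if swept and p == focal:
                    F = min(F * sweep_factor, 0.99)
                a = p_anc * (1.0 - F) / F
                b = (1.0 - p_anc) * (1.0 - F) / F
                freq = rng.beta(a, b)
                g = rng.binomial(2, freq, size=pop_sizes[p]).astype(np.int8)
                if missing_rate > 0:
                    miss = rng.random(pop_sizes[p]) < missing_rate
                    g[miss] = -1
                gts.append(g)
            row = np.concatenate(gts)
            called = row[row >= 0]
            if len(called) and 0 < called.sum() < 2 * len(called):
                gt_mat[i] = row
                break
        else:
            gt_mat[i] = row  # extremely unlikely; keep last draw

    _write_vcf(path, chrom, positions, gt_mat, sample_names)

    rows = []
    for b in range(n_blocks):
        first = b * block_size
        last = first + block_size - 1
        rows.append(
            {
                "unit_id": f"block{b:04d}",
                "category": "sweep" if swept_mask[b] else "null",
                "effect_size": sweep_factor if swept_mask[b] else 0.0,
                "chrom": chrom,
                "start": int(positions[first]) - 1,  # BED convention
                "end": int(positions[last]),
            }
        )
    return Path(path), sample_to_pop, TruthLedger(df=pd.DataFrame(rows))


@dataclass
class AnnotationBundle:
    """Synthetic gene-annotation inputs for the pleiotropy analyses."""

    fpkm: pd.DataFrame = field(repr=False)       # genes x 94 tissue-timepoints
    edges: pd.DataFrame = field(repr=False)      # gene_a, gene_b, score
    terms: pd.DataFrame = field(repr=False)      # gene_id, term
    de_genes: list[str] = field(default_factory=list)
    ds_genes: list[str] = field(default_factory=list)
    truth: TruthLedger | None = None


def gen_annotations(
    n_genes: int,
    seed: int,
    shift: float = 0.0,
    shifted_frac: float = 0.2,
    n_tissue_timepoints: int = 94,
) -> AnnotationBundle:
    """Tissue-expression matrix, scored interaction edges, ontology terms and
    DE/DS gene lists.

    ``shift`` plants a log2 mean-shift in the FPKM values of a labelled gene
    set (the DE list) relative to the rest, raising its tissue breadth; with
    ``shift=0`` the DE list is an unbiased random subset, so downstream
    permutation tests are null-calibrated.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]

    base = rng.lognormal(np.log(4.0), 1.2, size=n_genes)
    noise = rng.lognormal(0.0, 0.6, size=(n_genes, n_tissue_timepoints))
    fpkm = base.reshape(-1, 1) * noise

    n_shift = max(1, int(round(shifted_frac * n_genes)))
    labelled = list(rng.choice(n_genes, size=n_shift, replace=False))
    if shift != 0.0:
        fpkm[labelled] *= 2.0**shift
    fpkm_df = pd.DataFrame(
        fpkm, index=genes,
        columns=[f"tissue{t // 14}_tp{t % 14}" for t in range(n_tissue_timepoints)],
    )
    fpkm_df.index.name = "gene_id"

    n_edges = 4 * n_genes
    a = rng.integers(0, n_genes, size=n_edges)
    b = rng.integers(0, n_genes, size=n_edges)
    keep = a != b
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in a[keep]],
            "gene_b": [genes[i] for i in b[keep]],
            "score": rng.uniform(0.0, 1.0, size=int(keep.sum())),
        }
    )

    term_pool = [f"BP:{i:04d}" for i in range(200)]
    term_rows = []
    n_terms = rng.poisson(5.0, size=n_genes)
    for g, k in zip(genes, n_terms):
        for t in rng.choice(200, size=min(k, 200), replace=False):
            term_rows.append((g, term_pool[t]))
    terms = pd.DataFrame(term_rows, columns=["gene_id", "term"])

    de_genes = sorted(genes[i] for i in labelled)
    ds_pool = rng.choice(n_genes, size=n_shift, replace=False)
    ds_genes = sorted(genes[i] for i in ds_pool)

    truth = TruthLedger(
        df=pd.DataFrame(
            {
                "unit_id": genes,
                "category": [
                    "group_effect" if (i in set(labelled) and shift != 0.0) else "null"
                    for i in range(n_genes)
                ],
                "effect_size": [
                    shift if i in set(labelled) else 0.0 for i in range(n_genes)
                ],
            }
        )
    )
    return AnnotationBundle(
        fpkm=fpkm_df, edges=edges, terms=terms,
        de_genes=de_genes, ds_genes=ds_genes, truth=truth,
    )


def write_fixture_bundle(outdir, config: SimConfig | None = None) -> Path:
    """Write a complete fixture bundle (all input formats plus truth tables
    and a manifest) under ``outdir``.  Fully determined by ``config.seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimConfig(n_events=200)

    table, sheet, truth = gen_splice_dataset(config)
    write_event_table(table, outdir / "events.tsv")
    write_sample_sheet(sheet, outdir / "samples.tsv")
    truth.df.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)

    f1cfg = SimConfig(
        n_events=max(config.n_events // 2, 10),
        n_reps_per_group=config.n_reps_per_group,
        depth_mean=max(config.depth_mean, 200.0),
        effect_dpsi=0.25,
        bb_concentration=config.bb_concentration,
        seed=config.seed + 1,
    )
    parents, hybrids, f1_truth = gen_f1_dataset(
        f1cfg, cis_frac=0.2, trans_frac=0.2, cis_by_diet_frac=0.1
    )
    for diet, tab in parents.items():
        write_event_table(tab, outdir / f"parents_{diet}.tsv")
    hybrids.to_csv(outdir / "hybrid_pairs.tsv", sep="\t", index=False)
    f1_truth.df.to_csv(outdir / "truth_f1.tsv", sep="\t", index=False)

    vcf_path, sample_to_pop, vcf_truth = gen_genotype_vcf(
        outdir / "populations.vcf",
        n_snps=1000,
        n_blocks_swept=10,
        pop_sizes={"popA": 10, "popB": 10, "popC": 10},
        divergence_f={"popA": 0.05, "popB": 0.05, "popC": 0.05},
        seed=config.seed + 2,
    )
    pd.DataFrame(
        sorted(sample_to_pop.items()), columns=["sample", "population"]
    ).to_csv(outdir / "populations.tsv", sep="\t", index=False)
    vcf_truth.df.to_csv(outdir / "truth_blocks.tsv", sep="\t", index=False)

    # gene intervals tiling part of the simulated chromosome
    rng = np.random.default_rng(config.seed + 3)
    gene_rows = []
    for i in range(100):
        start = int(rng.integers(0, 990_000))
        gene_rows.append(("chr1", start, start + int(rng.integers(2000, 20_000)),
                          f"gene{i:05d}"))
    genes_bed = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name"])
    genes_bed = genes_bed.sort_values(["chrom", "start"]).reset_index(drop=True)
    write_bed_intervals(genes_bed, outdir / "genes.bed")

    ann = gen_annotations(n_genes=300, seed=config.seed + 4, shift=1.0)
    ann.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
    ann.edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    ann.terms.to_csv(outdir / "go_terms.tsv", sep="\t", index=False)
    Path(outdir / "de_genes.txt").write_text("\n".join(ann.de_genes) + "\n")
    Path(outdir / "ds_genes.txt").write_text("\n".join(ann.ds_genes) + "\n")
    ann.truth.df.to_csv(outdir / "truth_annotations.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_events": config.n_events,
        "n_reps_per_group": config.n_reps_per_group,
        "depth_mean": config.depth_mean,
        "n_snps": 1000,
        "block_size": 5,
        "n_blocks": 200,
        "populations": sorted({*sample_to_pop.values()}),
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
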