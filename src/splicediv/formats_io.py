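"""Readers and writers for the on-disk formats the pipeline consumes.

Formats handled here:

* junction-count event tables (TSV, rMATS-JC style count columns with
  comma-separated per-sample lists and a ``#samples=`` header line);
* sample sheets (TSV);
* multi-sample VCF 4.x genotypes (via cyvcf2), reduced to per-population
  allele/heterozygote tallies;
* BED gene intervals (0-based half-open);
* a flat key=value pipeline config.

All readers validate loudly: malformed rows raise ``FormatError`` naming the
offending record rather than coercing silently.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "EVENT_CLASSES",
    "EventTable",
    "read_event_table",
    "write_event_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "PopGenotypes",
    "read_vcf_genotypes",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_config",
    "write_config",
    "get_logger",
]

EVENT_CLASSES = ("SE", "RI", "MXE", "A3SS", "A5SS")

_log = logging.getLogger("splicediv")


def get_logger(verbose: bool = False) -> logging.Logger:
    """Structured stderr logger shared by the pipeline."""
    if not _log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        _log.addHandler(h)
    _log.setLevel(logging.DEBUG if verbose else logging.INFO)
    return _log


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class EventTable:
    """Junction-count table: one row per splicing event, per-sample counts.

    ``df`` columns: event_id, gene_id, event_class, IJC, SJC (comma-separated
    per-sample integer lists in ``samples`` order), IncFormLen, SkipFormLen.
    """

    df: pd.DataFrame = field(repr=False)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.samples)
        for col in ("IJC", "SJC"):
            for eid, cell in zip(self.df["event_id"], self.df[col]):
                parts = str(cell).split(",")
                if len(parts) != n:
                    raise FormatError(
                        f"event {eid}: {col} has {len(parts)} values, "
                        f"expected {n} samples"
                    )
                for v in parts:
                    if not v.lstrip("-").isdigit() or int(v) < 0:
                        raise FormatError(
                            f"event {eid}: {col} contains non-count value {v!r}"
                        )
        bad = ~self.df["event_class"].isin(EVENT_CLASSES)
        if bad.any():
            eid = self.df.loc[bad, "event_id"].iloc[0]
            raise FormatError(f"event {eid}: unknown event class")
        for col in ("IncFormLen", "SkipFormLen"):
            if (self.df[col].astype(float) <= 0).any():
                eid = self.df.loc[
                    self.df[col].astype(float) <= 0, "event_id"
                ].iloc[0]
                raise FormatError(f"event {eid}: non-positive {col}")
        if self.df["event_id"].duplicated().any():
            dup = self.df.loc[self.df["event_id"].duplicated(), "event_id"].iloc[0]
            raise FormatError(f"duplicate event_id {dup}")

    def counts(self, which: str, sample_ids: list[str] | None = None) -> np.ndarray:
        """(events x samples) integer count matrix for IJC or SJC."""
        mat = np.array(
            [[int(v) for v in str(cell).split(",")] for cell in self.df[which]],
            dtype=np.int64,
        )
        if sample_ids is None:
            return mat
        idx = []
        for s in sample_ids:
            if s not in self.samples:
                raise KeyError(f"sample {s!r} not in event table")
            idx.append(self.samples.index(s))
        return mat[:, idx]

    def subset_samples(self, sample_ids: list[str]) -> "EventTable":
        ijc = self.counts("IJC", sample_ids)
        sjc = self.counts("SJC", sample_ids)
        df = self.df.copy()
        df["IJC"] = [",".join(map(str, row)) for row in ijc]
        df["SJC"] = [",".join(map(str, row)) for row in sjc]
        return EventTable(df=df, samples=list(sample_ids))


_EVENT_COLS = ["event_id", "gene_id", "event_class", "IJC", "SJC",
               "IncFormLen", "SkipFormLen"]


def write_event_table(table: EventTable, path, per_class: bool = False) -> None:
    """Write the TSV dialect; ``per_class=True`` splits into one file per
    event class with the class name suffixed before the extension."""
    path = Path(path)
    if per_class:
        for cls, sub in table.df.groupby("event_class"):
            out = path.with_name(f"{path.stem}.{cls}{path.suffix}")
            _write_event_tsv(sub, table.samples, out)
    else:
        _write_event_tsv(table.df, table.samples, path)


def _write_event_tsv(df: pd.DataFrame, samples: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#samples=" + ",".join(samples) + "\n")
        df[_EVENT_COLS].to_csv(fh, sep="\t", index=False)


def read_event_table(path, sample_sheet: pd.DataFrame | None = None) -> EventTable:
    """Parse the event-table TSV.  Sample order comes from the ``#samples=``
    header line, or from ``sample_sheet['sample_id']`` when given."""
    path = Path(path)
    samples = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#samples="):
            samples = first.strip().split("=", 1)[1].split(",")
            df = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype=str)
    if samples is None:
        if sample_sheet is None:
            raise FormatError(
                f"{path}: no #samples= header and no sample sheet supplied"
            )
        samples = list(sample_sheet["sample_id"])
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df[_EVENT_COLS].copy()
    df["IncFormLen"] = df["IncFormLen"].astype(int)
    df["SkipFormLen"] = df["SkipFormLen"].astype(int)
    return EventTable(df=df, samples=samples)


_SHEET_COLS = ["sample_id", "strain", "sex", "diet", "replicate"]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SHEET_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    key = df[["strain", "sex", "diet", "replicate"]]
    if "allele" in df.columns:
        key = df[["strain", "sex", "diet", "replicate", "allele"]]
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicate (strain, sex, diet, replicate) rows")
    bad = ~df["diet"].isin(["STD", "HF"])
    if bad.any():
        raise FormatError(f"{path}: diet must be STD or HF")
    return df


@dataclass
class PopGenotypes:
    """Per-site, per-population genotype tallies from a multi-sample VCF.

    Arrays are (n_sites,) per population: ``n_genotyped`` individuals,
    ``alt_count`` alternate alleles among genotyped individuals, and
    ``het_count`` heterozygotes.  Positions keep the VCF 1-based convention.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: list[str]
    n_genotyped: dict[str, np.ndarray]
    alt_count: dict[str, np.ndarray]
    het_count: dict[str, np.ndarray]
    n_skipped_multiallelic: int = 0

    def __len__(self) -> int:
        return len(self.pos)

    def allele_freq(self, pop: str) -> np.ndarray:
        n = self.n_genotyped[pop]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_count[pop] / (2.0 * n), np.nan)


def read_vcf_genotypes(path, sample_to_pop: dict[str, str]) -> PopGenotypes:
    """Load biallelic SNP genotypes and tally them per population.

    Multi-allelic or non-SNP records are skipped (count logged); sites where
    every sample is missing are excluded.  Samples present in the VCF but
    absent from ``sample_to_pop`` raise ``FormatError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    missing = [s for s in vcf.samples if s not in sample_to_pop]
    if missing:
        raise FormatError(f"samples missing from population mapping: {missing}")
    pops = sorted(set(sample_to_pop.values()))
    pop_idx = {p: np.array([i for i, s in enumerate(vcf.samples)
                            if sample_to_pop[s] == p]) for p in pops}

    chroms, poss = [], []
    n_g = {p: [] for p in pops}
    alt_c = {p: [] for p in pops}
    het_c = {p: [] for p in pops}
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = var.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=missing (gts012)
        if np.all(gt == 3):
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        for p in pops:
            g = gt[pop_idx[p]]
            called = g != 3
            n_g[p].append(int(called.sum()))
            alt_c[p].append(int(g[called].sum()))
            het_c[p].append(int((g == 1).sum()))
    vcf.close()
    if n_skipped:
        get_logger().info("read_vcf_genotypes: skipped %d non-biallelic-SNP records",
                          n_skipped)
    return PopGenotypes(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        pops=pops,
        n_genotyped={p: np.array(n_g[p], dtype=np.int64) for p in pops},
        alt_count={p: np.array(alt_c[p], dtype=np.int64) for p in pops},
        het_count={p: np.array(het_c[p], dtype=np.int64) for p in pops},
        n_skipped_multiallelic=n_skipped,
    )


def read_bed_intervals(path) -> pd.DataFrame:
    """BED3+ gene intervals -> DataFrame(chrom, start, end, name), 0-based
    half-open, sorted within chromosome.  ``start >= end`` is an error."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def write_bed_intervals(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` config; '#' comments; later keys win."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{ln}: expected key = value")
            k, v = line.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
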