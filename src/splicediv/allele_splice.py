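"""Allele-specific alternative splicing (ASAS) in F1 hybrids.

In an F1 hybrid both parental alleles share one cellular environment, so a
difference in PSI between the two alleles of the same animal is diagnostic of
cis-regulatory divergence.  Input is a long "allele pair" table with one row
per event x diet x replicate carrying inclusion/skipping junction counts for
each allele (columns IJC1/SJC1/IJC2/SJC2) plus the effective form lengths.

Events are filtered for junction support (default: at least 20 supporting
reads per allele in every replicate) and then tested with the same
length-aware binomial likelihood-ratio test used for parental differential
splicing, contrasting allele 1 vs allele 2 across the paired replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats_io import get_logger
from .splice_psi import bh_adjust, diff_splice_test, estimate_psi

__all__ = [
    "filter_junction_support",
    "asas_test",
    "asas_table",
    "DEFAULT_MIN_READS",
]

DEFAULT_MIN_READS = 20

_PAIR_COLS = ["event_id", "diet", "replicate", "IJC1", "SJC1", "IJC2", "SJC2",
              "IncFormLen", "SkipFormLen"]


def _check_pairs(pairs: pd.DataFrame) -> None:
    missing = set(_PAIR_COLS) - set(pairs.columns)
    if missing:
        raise ValueError(f"allele-pair table missing columns {sorted(missing)}")
    for c in ("IJC1", "SJC1", "IJC2", "SJC2"):
        if (pairs[c] < 0).any():
            raise ValueError(f"negative counts in column {c}")


def filter_junction_support(
    pairs: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS
) -> pd.DataFrame:
    """Keep only events whose every replicate has >= ``min_reads`` supporting
    reads (I + S) on both alleles, within each diet.

    Support is evaluated at event level as min over alleles of I + S per
    replicate — a conservative proxy for the per-junction read filter.
    Discarded events are logged with a reason.
    """
    _check_pairs(pairs)
    if pairs.empty:
        return pairs.copy()
    sup1 = pairs["IJC1"] + pairs["SJC1"]
    sup2 = pairs["IJC2"] + pairs["SJC2"]
    support = np.minimum(sup1, sup2)
    ok = support >= min_reads
    bad_events = pairs.loc[~ok, ["event_id", "diet"]].drop_duplicates()
    if len(bad_events):
        get_logger().info(
            "filter_junction_support: discarded %d event/diet combinations "
            "with a replicate below %d supporting reads",
            len(bad_events), min_reads,
        )
    key = pairs[["event_id", "diet"]].apply(tuple, axis=1)
    bad_keys = set(bad_events.apply(tuple, axis=1))
    return pairs[~key.isin(bad_keys)].reset_index(drop=True)


def asas_test(event_pairs: pd.DataFrame, min_coverage: int = 0):
    """LRT for allele-specific splicing of one event (rows: replicates).

    Returns ``(p, allelic_dpsi)`` with allelic dPSI = mean PSI(allele 1) -
    mean PSI(allele 2).  Assumes the support filter has already run; the
    internal coverage gate is therefore off by default.
    """
    l_I = float(event_pairs["IncFormLen"].iloc[0])
    l_S = float(event_pairs["SkipFormLen"].iloc[0])
    p, dpsi = diff_splice_test(
        event_pairs["IJC1"].to_numpy(),
        event_pairs["SJC1"].to_numpy(),
        event_pairs["IJC2"].to_numpy(),
        event_pairs["SJC2"].to_numpy(),
        l_I, l_S,
        min_coverage=min_coverage,
    )
    return p, dpsi


def allele_psi(event_pairs: pd.DataFrame):
    """Per-replicate PSI vectors for the two alleles of one event."""
    l_I = float(event_pairs["IncFormLen"].iloc[0])
    l_S = float(event_pairs["SkipFormLen"].iloc[0])
    psi1 = estimate_psi(
        event_pairs["IJC1"].to_numpy(), event_pairs["SJC1"].to_numpy(), l_I, l_S
    )
    psi2 = estimate_psi(
        event_pairs["IJC2"].to_numpy(), event_pairs["SJC2"].to_numpy(), l_I, l_S
    )
    return np.atleast_1d(psi1), np.atleast_1d(psi2)


def asas_table(
    pairs: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    fdr: float = 0.05,
    diet: str | None = None,
) -> pd.DataFrame:
    """Run the ASAS test for every event (optionally restricted to one diet).

    Returns a DataFrame with event_id, diet, allelic_dpsi, p, q and the
    significance flag at ``fdr``.  BH adjustment is pooled over all tested
    events in the table.
    """
    _check_pairs(pairs)
    if diet is not None:
        pairs = pairs[pairs["diet"] == diet]
    kept = filter_junction_support(pairs, min_reads=min_reads)
    rows = []
    for (eid, dt), sub in kept.groupby(["event_id", "diet"], sort=True):
        p, dpsi = asas_test(sub)
        rows.append({"event_id": eid, "diet": dt, "allelic_dpsi": dpsi, "p": p})
    out = pd.DataFrame(rows, columns=["event_id", "diet", "allelic_dpsi", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"].notna() & (out["q"] < fdr)
    return out
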