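"""Pleiotropy proxies and gene-set contrasts.

Three per-gene proxies for functional reach: tissue/developmental expression
breadth (number of tissue-timepoints with FPKM >= 3 out of 94), high-
confidence protein-protein interaction degree (STRING-style scores strictly
above 0.7), and Biological Process ontology-term count.  Gene sets (e.g.
differentially expressed vs differentially spliced genes) are contrasted by
label-shuffling permutation tests on the mean (10,000 shuffles, +1-corrected
two-sided p by default), Fisher's exact overlap tests, and expression-binned
overlap (genes under 20 mean reads removed, five quantile bins).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import get_logger

__all__ = [
    "tissue_breadth",
    "ppi_degree",
    "go_term_counts",
    "gene_features",
    "permutation_mean_test",
    "fisher_overlap",
    "expression_bins",
    "binned_overlap_tests",
    "event_sharing_test",
]


def tissue_breadth(fpkm: pd.DataFrame, cutoff: float = 3.0) -> pd.Series:
    """Per-gene count of tissue-timepoint columns with FPKM >= cutoff."""
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return (fpkm >= cutoff).sum(axis=1).rename("tissue_breadth")


def ppi_degree(edges: pd.DataFrame, min_score: float = 0.7) -> pd.Series:
    """Degree per gene over edges with score strictly above ``min_score``.

    Duplicate edges (either orientation) are collapsed, self-loops ignored.
    Genes appearing only in sub-threshold edges get degree 0.
    """
    scores = edges["score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("interaction scores must lie in [0, 1]")
    genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    keep = edges[edges["score"] > min_score]
    seen = set()
    deg = {g: 0 for g in genes}
    for a, b in zip(keep["gene_a"], keep["gene_b"]):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        deg[a] += 1
        deg[b] += 1
    return pd.Series(deg, name="ppi_degree")


def go_term_counts(terms: pd.DataFrame) -> pd.Series:
    """Number of distinct ontology terms annotated per gene."""
    return terms.drop_duplicates().groupby("gene_id")["term"].count().rename(
        "go_bp_terms"
    )


def gene_features(
    fpkm: pd.DataFrame,
    edges: pd.DataFrame,
    terms: pd.DataFrame,
    mean_expression: pd.Series | None = None,
    fpkm_cutoff: float = 3.0,
    min_score: float = 0.7,
) -> pd.DataFrame:
    """Assemble the per-gene pleiotropy feature table (missing genes get 0)."""
    genes = fpkm.index
    feats = pd.DataFrame(index=genes)
    feats["tissue_breadth"] = tissue_breadth(fpkm, fpkm_cutoff)
    feats["ppi_degree"] = ppi_degree(edges, min_score).reindex(genes).fillna(0).astype(int)
    feats["go_bp_terms"] = go_term_counts(terms).reindex(genes).fillna(0).astype(int)
    if mean_expression is not None:
        feats["mean_expression"] = mean_expression.reindex(genes)
    feats.index.name = "gene_id"
    return feats


def permutation_mean_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
    exhaustive: bool = False,
) -> float:
    """Label-shuffling permutation test for a difference in means.

    The group labels of the pooled observations are reshuffled ``n_perm``
    times; p = (1 + #{shuffles at least as extreme}) / (n_perm + 1).  With
    ``exhaustive=True`` every distinct assignment of labels is enumerated and
    the exact proportion (no +1 correction) is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sets must be non-empty")
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def extremity(diff):
        return abs(diff) if alternative == "two-sided" else diff

    obs = extremity(a.mean() - b.mean())
    if exhaustive:
        hits = total = 0
        for idx in combinations(range(len(pooled)), n_a):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            d = extremity(pooled[mask].mean() - pooled[~mask].mean())
            hits += d >= obs - 1e-12
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = extremity(perm[:n_a].mean() - perm[n_a:].mean())
        if d >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def fisher_overlap(set_a, set_b, universe):
    """Two-sided Fisher's exact test for overlap of two gene sets.

    Builds the 2x2 membership table over ``universe`` and returns
    ``(odds_ratio, p)``; the conditional odds ratio is ``inf`` for a
    zero-discordant table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sa = set(set_a) & universe
    sb = set(set_b) & universe
    both = len(sa & sb)
    only_a = len(sa - sb)
    only_b = len(sb - sa)
    neither = len(universe) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def expression_bins(
    mean_expression: pd.Series, min_mean: float = 20.0, n_bins: int = 5
) -> pd.Series:
    """Quantile bin labels (0..n_bins-1) for genes above the expression floor.

    Genes with mean expression below ``min_mean`` are excluded; the rest are
    split into ``n_bins`` near-equal quantile bins (ties broken
    deterministically by gene order).
    """
    expr = mean_expression[mean_expression >= min_mean]
    if len(expr) < n_bins:
        raise ValueError(f"only {len(expr)} genes above {min_mean}, "
                         f"cannot form {n_bins} bins")
    order = expr.rank(method="first")  # deterministic under ties
    labels = pd.cut(order, bins=n_bins, labels=False)
    return pd.Series(labels.astype(int), index=expr.index, name="expr_bin")


def binned_overlap_tests(set_a, set_b, bins: pd.Series) -> pd.DataFrame:
    """Fisher overlap of two gene sets within each expression bin."""
    rows = []
    for b in sorted(bins.unique()):
        uni = set(bins.index[bins == b])
        odds, p = fisher_overlap(set_a, set_b, uni)
        rows.append({"bin": int(b), "n_genes": len(uni), "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)


def event_sharing_test(events: pd.DataFrame) -> pd.DataFrame:
    """Per-class Fisher test of whether events of one splicing class are more
    often shared across genotypes than events of the other classes.

    ``events`` needs columns ``event_class`` and boolean ``shared``.  Classes
    absent from the data are skipped.  Returns class, 2x2 counts, odds ratio
    and two-sided p.
    """
    rows = []
    for cls, sub in events.groupby("event_class"):
        if sub.empty:
            get_logger().info("event_sharing_test: class %s empty, skipped", cls)
            continue
        rest = events[events["event_class"] != cls]
        table = [
            [int(sub["shared"].sum()), int((~sub["shared"]).sum())],
            [int(rest["shared"].sum()), int((~rest["shared"]).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "event_class": cls,
                "shared_in_class": table[0][0],
                "unique_in_class": table[0][1],
                "shared_other": table[1][0],
                "unique_other": table[1][1],
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
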