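"""Cis/trans assignment of splicing regulatory divergence.

The logic follows the classic comparison of two estimated quantities with
independent standard errors (Altman & Bland): the parental PSI log-ratio
``L_P`` is compared with the hybrid allele-specific PSI log-ratio ``L_H``.
Because both alleles of an F1 hybrid share one trans-acting environment,
``L_H`` isolates the cis component, while the parental contrast carries cis
plus trans.  The decomposition is additive by construction::

    cis   = L_H
    trans = L_P - L_H

The difference ``D = L_P - L_H`` is tested with ``Z = D / sqrt(SE_P^2 +
SE_H^2)`` against a standard normal; p-values are Benjamini-Hochberg
adjusted.  Category assignment uses three significance flags — parents differ
(``parent_sig``), alleles differ within hybrids (``hybrid_sig``), and the
two ratios differ (``ratio_sig``):

* cis_only        — parent_sig and hybrid_sig, ratios not different;
* trans_only      — parent_sig, alleles equal, ratios different;
* cis_plus_trans  — all three significant, L_P and L_H same sign;
* compensatory    — hybrid and ratio significant with opposite signs, or
                    without a parental difference;
* conserved       — nothing significant;
* ambiguous       — any other pattern, or missing flags.

The same Z machinery applied to ``L_H`` on a high-fat vs a standard diet
tests for cis-by-diet interactions (gene-by-environment effects that ride
with the allele).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allele_splice import allele_psi, asas_table
from .splice_psi import bh_adjust, diff_splice_table, estimate_psi

__all__ = [
    "DEFAULT_EPS",
    "CATEGORIES",
    "log_ratio_with_se",
    "ratio_difference_z",
    "classify_regulation",
    "equalize_samples",
    "assign_regulation",
    "cis_by_diet_test",
    "component_diet_correlation",
    "diet_divergence_compare",
    "trans_components",
]

DEFAULT_EPS = 0.01

CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)


def log_ratio_with_se(psi_a, psi_b, paired: bool, eps: float = DEFAULT_EPS):
    """Natural-log PSI ratio with its standard error.

    Paired (hybrid alleles within animals): per-replicate ratios
    ``r_i = ln((psi_a_i + eps) / (psi_b_i + eps))``, estimate = mean(r),
    SE = sd(r)/sqrt(n).  Unpaired (parental strains): estimate =
    ``ln((mean(psi_a) + eps) / (mean(psi_b) + eps))`` with a delta-method SE
    from the two variances of the mean.

    Returns ``(estimate, se)``; ``(nan, nan)`` with fewer than two
    informative replicates on either side.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    psi_a = np.asarray(psi_a, dtype=float)
    psi_b = np.asarray(psi_b, dtype=float)
    if paired:
        ok = ~(np.isnan(psi_a) | np.isnan(psi_b))
        a, b = psi_a[ok], psi_b[ok]
        if len(a) < 2:
            return float("nan"), float("nan")
        r = np.log((a + eps) / (b + eps))
        return float(np.mean(r)), float(np.std(r, ddof=1) / math.sqrt(len(r)))
    a = psi_a[~np.isnan(psi_a)]
    b = psi_b[~np.isnan(psi_b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    va = float(np.var(a, ddof=1)) / len(a)
    vb = float(np.var(b, ddof=1)) / len(b)
    est = math.log((ma + eps) / (mb + eps))
    se = math.sqrt(va / (ma + eps) ** 2 + vb / (mb + eps) ** 2)
    return est, se


def ratio_difference_z(L_P, SE_P, L_H, SE_H):
    """Z test for a difference between two independent log-ratio estimates.

    ``Z = (L_P - L_H) / sqrt(SE_P^2 + SE_H^2)``, two-sided normal p.
    Returns ``(nan, nan)`` when either SE is non-finite or both are zero.
    """
    if not (np.isfinite(SE_P) and np.isfinite(SE_H)):
        return float("nan"), float("nan")
    denom = math.sqrt(SE_P**2 + SE_H**2)
    if denom == 0.0:
        return float("nan"), float("nan")
    z = (L_P - L_H) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    # keep p strictly positive for downstream BH even when sf underflows
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return float(z), float(p)


def classify_regulation(parent_sig, hybrid_sig, ratio_sig,
                        sign_parent=0.0, sign_hybrid=0.0) -> str:
    """Map the three significance flags (plus the signs of L_P and L_H) to a
    regulatory category.  Missing flags (None/NaN) give ``ambiguous``."""
    flags = [parent_sig, hybrid_sig, ratio_sig]
    if any(f is None or (isinstance(f, float) and math.isnan(f)) for f in flags):
        return "ambiguous"
    p, h, r = (bool(f) for f in flags)
    same_sign = sign_parent * sign_hybrid > 0
    if p and h and not r:
        return "cis_only"
    if p and not h and r:
        return "trans_only"
    if p and h and r and same_sign:
        return "cis_plus_trans"
    if h and r and (not p or not same_sign):
        return "compensatory"
    if not p and not h and not r:
        return "conserved"
    return "ambiguous"


def equalize_samples(groups: dict[str, list], n: int = 5, seed: int = 0):
    """Randomly drop individuals to equalize sample size at ``n`` per group.

    Deterministic under ``seed``; a group smaller than ``n`` is an error.
    Selection order within each group is preserved.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(groups):
        members = list(groups[name])
        if len(members) < n:
            raise ValueError(f"group {name!r} has {len(members)} < {n} samples")
        if len(members) == n:
            out[name] = members
        else:
            idx = sorted(rng.choice(len(members), size=n, replace=False))
            out[name] = [members[i] for i in idx]
    return out


def _hybrid_ratio_rows(pairs: pd.DataFrame, eps: float) -> pd.DataFrame:
    rows = []
    for (eid, diet), sub in pairs.groupby(["event_id", "diet"], sort=True):
        psi1, psi2 = allele_psi(sub)
        L, se = log_ratio_with_se(psi1, psi2, paired=True, eps=eps)
        rows.append({"event_id": eid, "diet": diet, "L_H": L, "SE_H": se})
    return pd.DataFrame(rows, columns=["event_id", "diet", "L_H", "SE_H"])


def assign_regulation(
    parent_table,
    hybrid_pairs: pd.DataFrame,
    samples_parent1: list[str],
    samples_parent2: list[str],
    diet: str,
    fdr: float = 0.05,
    eps: float = DEFAULT_EPS,
    min_reads: int = 20,
    equalize_n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cis/trans assignment for one diet.

    Runs the parental LRT (coverage-gated at ``min_reads`` per sample), the
    hybrid ASAS test, and the ratio-difference Z test, BH-adjusts each family
    of p-values at ``fdr``, and classifies every event.  Returns a per-event
    DataFrame with L_P, L_H, the cis/trans decomposition, Z, q-values, the
    three flags and the category.
    """
    if equalize_n is not None:
        eq = equalize_samples(
            {"p1": samples_parent1, "p2": samples_parent2}, n=equalize_n, seed=seed
        )
        samples_parent1, samples_parent2 = eq["p1"], eq["p2"]

    par = diff_splice_table(
        parent_table, samples_parent1, samples_parent2, min_coverage=min_reads
    ).rename(columns={"p": "p_parent", "q": "q_parent", "delta_psi": "parent_dpsi"})

    hyb = asas_table(
        hybrid_pairs, min_reads=min_reads, fdr=fdr, diet=diet
    ).rename(columns={"p": "p_hybrid", "q": "q_hybrid"})

    pairs_d = hybrid_pairs[hybrid_pairs["diet"] == diet]
    ratios = _hybrid_ratio_rows(pairs_d, eps)

    # parental per-replicate PSI -> unpaired log ratio
    ijc1 = parent_table.counts("IJC", samples_parent1)
    sjc1 = parent_table.counts("SJC", samples_parent1)
    ijc2 = parent_table.counts("IJC", samples_parent2)
    sjc2 = parent_table.counts("SJC", samples_parent2)
    l_I = parent_table.df["IncFormLen"].to_numpy(float).reshape(-1, 1)
    l_S = parent_table.df["SkipFormLen"].to_numpy(float).reshape(-1, 1)
    psi1 = estimate_psi(ijc1, sjc1, l_I, l_S)
    psi2 = estimate_psi(ijc2, sjc2, l_I, l_S)
    lp_rows = []
    for i, eid in enumerate(parent_table.df["event_id"]):
        L, se = log_ratio_with_se(psi1[i], psi2[i], paired=False, eps=eps)
        lp_rows.append({"event_id": eid, "L_P": L, "SE_P": se})
    lp = pd.DataFrame(lp_rows)

    out = (
        par.merge(lp, on="event_id")
        .merge(hyb.drop(columns=["diet", "significant"]), on="event_id", how="inner")
        .merge(ratios.drop(columns=["diet"]), on="event_id", how="inner")
    )

    zs, ps = [], []
    for _, row in out.iterrows():
        z, p = ratio_difference_z(row["L_P"], row["SE_P"], row["L_H"], row["SE_H"])
        zs.append(z)
        ps.append(p)
    out["Z"] = zs
    out["p_ratio"] = ps
    out["q_ratio"] = bh_adjust(out["p_ratio"].to_numpy())

    out["parent_sig"] = out["q_parent"].notna() & (out["q_parent"] < fdr)
    out["hybrid_sig"] = out["q_hybrid"].notna() & (out["q_hybrid"] < fdr)
    out["ratio_sig"] = out["q_ratio"].notna() & (out["q_ratio"] < fdr)

    out["cis"] = out["L_H"]
    out["trans"] = out["L_P"] - out["L_H"]

    cats = []
    for _, row in out.iterrows():
        missing = (
            row[["p_parent", "p_hybrid", "p_ratio"]].isna().any()
        )
        if missing:
            cats.append("ambiguous")
            continue
        cats.append(
            classify_regulation(
                row["parent_sig"], row["hybrid_sig"], row["ratio_sig"],
                sign_parent=np.sign(row["L_P"]), sign_hybrid=np.sign(row["L_H"]),
            )
        )
    out["category"] = cats
    return out


def cis_by_diet_test(
    hybrid_pairs: pd.DataFrame,
    eps: float = DEFAULT_EPS,
    min_reads: int = 20,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Test each event for a diet-dependent cis effect.

    Compares the hybrid allele-specific log-ratio on the high-fat diet with
    the one on the standard diet using the ratio-difference Z test; BH
    adjustment over all events testable in both diets; flagged at ``fdr``
    (default 0.1).
    """
    from .allele_splice import filter_junction_support

    kept = filter_junction_support(hybrid_pairs, min_reads=min_reads)
    ratios = _hybrid_ratio_rows(kept, eps)
    wide = ratios.pivot(index="event_id", columns="diet", values=["L_H", "SE_H"])
    if not {"HF", "STD"} <= set(ratios["diet"].unique()):
        raise ValueError("cis_by_diet_test needs events measured on both diets")
    wide = wide.dropna()
    rows = []
    for eid, row in wide.iterrows():
        z, p = ratio_difference_z(
            row[("L_H", "HF")], row[("SE_H", "HF")],
            row[("L_H", "STD")], row[("SE_H", "STD")],
        )
        rows.append(
            {
                "event_id": eid,
                "L_H_HF": row[("L_H", "HF")],
                "L_H_STD": row[("L_H", "STD")],
                "Z": z,
                "p": p,
            }
        )
    out = pd.DataFrame(rows, columns=["event_id", "L_H_HF", "L_H_STD", "Z", "p"])
    out = out.dropna(subset=["p"]).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"].notna() & (out["q"] < fdr)
    return out


def component_diet_correlation(values_hf, values_std):
    """Spearman rank correlation (average ranks for ties, two-sided p)
    between a regulatory component measured on the two diets.

    Requires >= 3 finite pairs; a constant vector gives ``(nan, nan)``.
    """
    x = np.asarray(values_hf, dtype=float)
    y = np.asarray(values_std, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def diet_divergence_compare(cis_div, trans_div, alternative: str = "greater"):
    """Wilcoxon signed-rank test of paired per-gene diet divergences.

    ``cis_div``/``trans_div`` are |log2 fold-change| differences between
    diets for the cis and trans components of the same genes.  Zero
    differences are dropped; exact null distribution for n <= 25 without
    ties, normal approximation with continuity correction otherwise.
    ``alternative='greater'`` asks whether the trans component diverges more.
    Returns ``(W, p)``; all-zero differences raise ``ValueError``.
    """
    cis_div = np.asarray(cis_div, dtype=float)
    trans_div = np.asarray(trans_div, dtype=float)
    if cis_div.shape != trans_div.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = trans_div - cis_div
    diffs = diffs[np.isfinite(diffs)]
    nz = diffs[diffs != 0.0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero: untestable")
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) \
        else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative=alternative, method=method,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class TransComponent:
    """Additive decomposition of the parental contrast for one event:
    cis = L_H, trans = L_P - L_H, with log2 fold-change proxies L/ln(2)."""

    event_id: str
    diet: str
    cis: float
    trans: float

    @property
    def cis_log2(self) -> float:
        return self.cis / math.log(2.0)

    @property
    def trans_log2(self) -> float:
        return self.trans / math.log(2.0)


def trans_components(assigned: pd.DataFrame, diet: str) -> pd.DataFrame:
    """Extract per-event cis/trans components (log2 scale) from an
    :func:`assign_regulation` result."""
    out = assigned[["event_id", "cis", "trans"]].copy()
    out["diet"] = diet
    out["cis_log2"] = out["cis"] / math.log(2.0)
    out["trans_log2"] = out["trans"] / math.log(2.0)
    return out
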