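"""PSI estimation and differential-splicing tests.

The percent-spliced-in (PSI, ``psi``) of a splicing event is the fraction of a
gene's transcripts that include the alternative segment.  It is estimated from
inclusion-junction reads ``I`` and skipping-junction reads ``S`` after
normalising each by the effective length of its supporting form::

    psi = (I / l_I) / (I / l_I + S / l_S)

Differential splicing between two sample groups is tested with a likelihood
ratio test on the junction counts.  Each sample's ``(I, S)`` pair is modelled
as binomial with success probability

    p(psi) = psi * l_I / (psi * l_I + (1 - psi) * l_S),

the length-weighted inclusion probability.  The null model shares one ``psi``
across both groups; the alternative fits one ``psi`` per group; the statistic
is referred to a chi-square with one degree of freedom.  Because ``p`` is a
monotone bijection of ``psi`` for fixed lengths, the maximum-likelihood fits
are available in closed form from pooled counts.

An optional beta-binomial variant (shared method-of-moments dispersion,
numerically maximised) is provided for overdispersed replicate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_psi",
    "sample_psi_matrix",
    "group_delta_psi",
    "diff_splice_test",
    "diff_splice_table",
    "bh_adjust",
    "call_differential",
    "DiffSpliceResult",
]

DEFAULT_MIN_COVERAGE = 10


def estimate_psi(I, S, l_I, l_S):
    """Length-normalised PSI. Returns NaN where ``I + S == 0``.

    Accepts scalars or arrays (broadcast).  Raises ``ValueError`` for
    non-positive effective lengths or negative counts.
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    l_I = np.asarray(l_I, dtype=float)
    l_S = np.asarray(l_S, dtype=float)
    if np.any(l_I <= 0) or np.any(l_S <= 0):
        raise ValueError("effective form lengths must be positive")
    if np.any(I < 0) or np.any(S < 0):
        raise ValueError("junction counts must be non-negative")
    inc = I / l_I
    skip = S / l_S
    tot = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(tot > 0, inc / np.where(tot > 0, tot, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def _inclusion_prob(psi, l_I, l_S):
    """Map PSI to the binomial inclusion-read probability."""
    return psi * l_I / (psi * l_I + (1.0 - psi) * l_S)


def _psi_from_prob(p, l_I, l_S):
    """Inverse of :func:`_inclusion_prob`."""
    return (p / l_I) / (p / l_I + (1.0 - p) / l_S)


def sample_psi_matrix(ijc: np.ndarray, sjc: np.ndarray, l_I, l_S) -> np.ndarray:
    """Per-sample PSI for an (events x samples) pair of count matrices."""
    l_I = np.asarray(l_I, dtype=float).reshape(-1, 1)
    l_S = np.asarray(l_S, dtype=float).reshape(-1, 1)
    return estimate_psi(ijc, sjc, l_I, l_S)


def group_delta_psi(psi_a, psi_b):
    """Mean non-missing PSI of group A minus group B.

    Returns NaN (untestable) if either group has no informative sample.
    """
    psi_a = np.asarray(psi_a, dtype=float)
    psi_b = np.asarray(psi_b, dtype=float)
    if np.all(np.isnan(psi_a)) or np.all(np.isnan(psi_b)):
        return float("nan")
    return float(np.nanmean(psi_a) - np.nanmean(psi_b))


def _binom_ll(I, S, p):
    # log-likelihood up to the binomial coefficient, safe at p in {0,1}
    return float(np.sum(special.xlogy(I, p) + special.xlogy(S, 1.0 - p)))


def _betabinom_ll(I, n, p, conc):
    a = p * conc
    b = (1.0 - p) * conc
    return float(
        np.sum(
            special.betaln(I + a, n - I + b) - special.betaln(a, b)
        )
    )


def _mom_concentration(I, n, p):
    """Method-of-moments beta-binomial concentration, pooled over samples."""
    n = np.asarray(n, dtype=float)
    I = np.asarray(I, dtype=float)
    keep = n > 0
    n, I = n[keep], I[keep]
    if len(n) < 2 or p <= 0 or p >= 1:
        return np.inf
    phat = I / n
    # E[var(phat)] under beta-binomial: p(1-p)/n * (1 + (n-1)*rho)
    v_obs = np.mean((phat - p) ** 2)
    v_bin = np.mean(p * (1 - p) / n)
    excess = v_obs - v_bin
    if excess <= 0:
        return np.inf
    rho = excess / (p * (1 - p) * np.mean((n - 1) / n))
    rho = min(max(rho, 1e-6), 0.999)
    return (1.0 - rho) / rho


def diff_splice_test(
    ijc_a,
    sjc_a,
    ijc_b,
    sjc_b,
    l_I,
    l_S,
    model: str = "binomial",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
):
    """Likelihood-ratio test for differential splicing of one event.

    Parameters are per-sample inclusion/skipping counts in the two groups and
    the shared effective form lengths.  Returns ``(p_value, delta_psi)``;
    ``p_value`` is NaN when the event fails the coverage filter (total
    ``I + S < min_coverage`` in any sample) or when a group has fewer than two
    informative samples.
    """
    ijc_a = np.asarray(ijc_a, dtype=float)
    sjc_a = np.asarray(sjc_a, dtype=float)
    ijc_b = np.asarray(ijc_b, dtype=float)
    sjc_b = np.asarray(sjc_b, dtype=float)
    tot_a = ijc_a + sjc_a
    tot_b = ijc_b + sjc_b

    psi_a = estimate_psi(ijc_a, sjc_a, l_I, l_S)
    psi_b = estimate_psi(ijc_b, sjc_b, l_I, l_S)
    dpsi = group_delta_psi(psi_a, psi_b)

    if np.any(tot_a < min_coverage) or np.any(tot_b < min_coverage):
        return float("nan"), dpsi
    if np.sum(tot_a > 0) < 2 or np.sum(tot_b > 0) < 2:
        return float("nan"), dpsi

    Ia, Sa = float(ijc_a.sum()), float(sjc_a.sum())
    Ib, Sb = float(ijc_b.sum()), float(sjc_b.sum())
    p_a = Ia / (Ia + Sa)
    p_b = Ib / (Ib + Sb)
    p_0 = (Ia + Ib) / (Ia + Sa + Ib + Sb)

    if model == "binomial":
        ll_alt = _binom_ll(ijc_a, sjc_a, p_a) + _binom_ll(ijc_b, sjc_b, p_b)
        ll_null = _binom_ll(ijc_a, sjc_a, p_0) + _binom_ll(ijc_b, sjc_b, p_0)
    elif model == "betabinom":
        I_all = np.concatenate([ijc_a, ijc_b])
        n_all = np.concatenate([tot_a, tot_b])
        conc = _mom_concentration(I_all, n_all, p_0)
        if not np.isfinite(conc):
            # no detectable overdispersion: fall back to the binomial limit
            ll_alt = _binom_ll(ijc_a, sjc_a, p_a) + _binom_ll(ijc_b, sjc_b, p_b)
            ll_null = _binom_ll(ijc_a, sjc_a, p_0) + _binom_ll(ijc_b, sjc_b, p_0)
        else:
            def nll_group(I, n, p):
                return -_betabinom_ll(I, n, p, conc)

            def fit(I, n, start):
                res = optimize.minimize_scalar(
                    lambda q: nll_group(I, n, q),
                    bounds=(1e-9, 1 - 1e-9),
                    method="bounded",
                )
                return -res.fun

            ll_alt = fit(ijc_a, tot_a, p_a) + fit(ijc_b, tot_b, p_b)
            res0 = optimize.minimize_scalar(
                lambda q: nll_group(I_all, n_all, q),
                bounds=(1e-9, 1 - 1e-9),
                method="bounded",
            )
            ll_null = -res0.fun
    else:
        raise ValueError(f"unknown model {model!r}")

    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    p = max(p, float(np.finfo(float).tiny))  # avoid underflow to exactly 0
    return p, dpsi


def _vectorised_binomial_lrt(ijc_a, sjc_a, ijc_b, sjc_b, min_coverage):
    """Binomial LRT across all events at once (events x samples arrays)."""
    tot_a = ijc_a + sjc_a
    tot_b = ijc_b + sjc_b
    testable = (
        np.all(tot_a >= min_coverage, axis=1)
        & np.all(tot_b >= min_coverage, axis=1)
        & (np.sum(tot_a > 0, axis=1) >= 2)
        & (np.sum(tot_b > 0, axis=1) >= 2)
    )
    Ia = ijc_a.sum(axis=1)
    Sa = sjc_a.sum(axis=1)
    Ib = ijc_b.sum(axis=1)
    Sb = sjc_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = Ia / (Ia + Sa)
        p_b = Ib / (Ib + Sb)
        p_0 = (Ia + Ib) / (Ia + Sa + Ib + Sb)

    def ll(I, S, p):
        return special.xlogy(I, p) + special.xlogy(S, 1.0 - p)

    stat = 2.0 * (
        ll(Ia, Sa, p_a) + ll(Ib, Sb, p_b) - ll(Ia, Sa, p_0) - ll(Ib, Sb, p_0)
    )
    stat = np.clip(stat, 0.0, None)
    pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(stat <= 0, 1.0, pvals)
    pvals = np.maximum(pvals, np.finfo(float).tiny)  # no underflow to 0
    pvals = np.where(testable, pvals, np.nan)
    return pvals


@dataclass
class DiffSpliceResult:
    """Per-event differential-splicing results plus call thresholds."""

    table: pd.DataFrame = field(repr=False)
    fdr: float = 0.05
    min_abs_dpsi: float = 0.0

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]


def diff_splice_table(
    event_table,
    samples_a,
    samples_b,
    model: str = "binomial",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Run the differential-splicing LRT for every event in an event table.

    ``event_table`` is a :class:`~splicediv.formats_io.EventTable`;
    ``samples_a``/``samples_b`` are sample-id lists defining the two groups.
    Returns a DataFrame with event_id, gene_id, event_class, delta_psi, p, q.
    """
    ijc_a = event_table.counts("IJC", samples_a)
    sjc_a = event_table.counts("SJC", samples_a)
    ijc_b = event_table.counts("IJC", samples_b)
    sjc_b = event_table.counts("SJC", samples_b)
    l_I = event_table.df["IncFormLen"].to_numpy(dtype=float).reshape(-1, 1)
    l_S = event_table.df["SkipFormLen"].to_numpy(dtype=float).reshape(-1, 1)

    psi_a = estimate_psi(ijc_a, sjc_a, l_I, l_S)
    psi_b = estimate_psi(ijc_b, sjc_b, l_I, l_S)
    with np.errstate(invalid="ignore"):
        dpsi = np.nanmean(psi_a, axis=1) - np.nanmean(psi_b, axis=1)

    if model == "binomial":
        pvals = _vectorised_binomial_lrt(ijc_a, sjc_a, ijc_b, sjc_b, min_coverage)
    else:
        pvals = np.array(
            [
                diff_splice_test(
                    ijc_a[i], sjc_a[i], ijc_b[i], sjc_b[i],
                    float(l_I[i, 0]), float(l_S[i, 0]),
                    model=model, min_coverage=min_coverage,
                )[0]
                for i in range(len(event_table.df))
            ]
        )

    out = pd.DataFrame(
        {
            "event_id": event_table.df["event_id"].to_numpy(),
            "gene_id": event_table.df["gene_id"].to_numpy(),
            "event_class": event_table.df["event_class"].to_numpy(),
            "delta_psi": dpsi,
            "p": pvals,
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are passed through
    untouched and excluded from the adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    out = np.full(pvals.shape, np.nan)
    mask = ~np.isnan(pvals)
    if mask.sum() == 0:
        return out
    finite = pvals[mask]
    if np.any((finite <= 0) | (finite > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out[mask] = multipletests(finite, method="fdr_bh")[1]
    return out


def call_differential(
    results: pd.DataFrame,
    fdr: float = 0.05,
    min_abs_dpsi: float = 0.0,
) -> DiffSpliceResult:
    """Flag significant events (q < fdr and |dPSI| >= min_abs_dpsi), roll up
    to genes, and summarise by event class.

    The per-gene representative event is the significant event with largest
    |dPSI|.  Gene and class summaries are attached to the returned result as
    ``gene_calls`` and ``class_summary`` attributes.
    """
    tab = results.copy()
    tab["called"] = (
        tab["q"].notna()
        & (tab["q"] < fdr)
        & (tab["delta_psi"].abs() >= min_abs_dpsi)
    )
    res = DiffSpliceResult(table=tab, fdr=fdr, min_abs_dpsi=min_abs_dpsi)

    sig = tab[tab["called"]].copy()
    if len(sig):
        sig["abs_dpsi"] = sig["delta_psi"].abs()
        rep = sig.sort_values(
            ["gene_id", "abs_dpsi"], ascending=[True, False]
        ).drop_duplicates("gene_id")
        gene_calls = rep[["gene_id", "event_id", "delta_psi", "q"]].reset_index(
            drop=True
        )
    else:
        gene_calls = pd.DataFrame(columns=["gene_id", "event_id", "delta_psi", "q"])
    class_summary = (
        tab.groupby("event_class")["called"].agg(["sum", "count"])
        .rename(columns={"sum": "n_called", "count": "n_events"})
        .reset_index()
    )
    res.gene_calls = gene_calls
    res.class_summary = class_summary
    return res
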