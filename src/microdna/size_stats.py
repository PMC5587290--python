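"""Circle size distributions, laddering periodicity and group contrasts."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .samples import DRUGS

logger = logging.getLogger(__name__)


@dataclass
class SizeSummary:
    n: int
    mean: float
    central95: tuple[float, float]   # 2.5th-97.5th percentile of lengths
    iqr: tuple[float, float]         # 25th-75th percentile
    histogram: pd.DataFrame          # columns bin_start, count (10 bp bins)


@dataclass
class PeriodicityEstimate:
    period: int          # bp; multiple of the histogram bin width
    prominence: float    # autocorrelation at the reported lag
    significant: bool


def size_summary(lengths, bin_width: int = 10) -> SizeSummary:
    """Mean, central 95% range, IQR and a fixed-width histogram.

    Percentiles use linear interpolation between order statistics
    (numpy's default). The central 95% range is the 2.5th-97.5th
    percentile of the lengths themselves, bracketing the IQR.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValueError("size_summary requires at least one length")
    lo95, q25, q75, hi95 = np.percentile(x, [2.5, 25, 75, 97.5])
    edges = np.arange(0, x.max() + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=np.append(edges, edges[-1] + bin_width))
    hist = pd.DataFrame({"bin_start": edges.astype(int), "count": counts})
    return SizeSummary(
        n=int(x.size),
        mean=float(x.mean()),
        central95=(float(lo95), float(hi95)),
        iqr=(float(q25), float(q75)),
        histogram=hist,
    )


def _peak_lag(
    detrended: np.ndarray, bin_width: int, lag_min: int, lag_max: int
) -> tuple[int, float]:
    """Lag (bp) of the highest autocorrelation in [lag_min, lag_max] bp."""
    x = detrended - detrended.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return lag_min, 0.0
    lo = max(1, lag_min // bin_width)
    hi = min(len(x) - 1, lag_max // bin_width)
    best_lag, best_ac = lo, -np.inf
    for lag in range(lo, hi + 1):
        ac = float(np.dot(x[:-lag], x[lag:])) / denom
        if ac > best_ac:
            best_lag, best_ac = lag, ac
    return best_lag * bin_width, best_ac


def estimate_periodicity(
    lengths,
    bin_width: int = 10,
    detrend_window: int = 500,
    lag_range: tuple[int, int] = (50, 500),
    n_permutations: int = 200,
    seed: int = 0,
    min_n: int = 100,
) -> PeriodicityEstimate:
    """Ladder period of a length distribution by detrended autocorrelation.

    The 10 bp histogram is detrended by subtracting a centered moving
    average (window in bp), its autocorrelation is scanned over lags in
    `lag_range`, and the lag of the highest peak is reported. Significance:
    the peak must exceed the 95th percentile of the same statistic on
    histograms with bins randomly permuted (which destroys periodic
    structure but keeps the count distribution).
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < min_n:
        return PeriodicityEstimate(0, 0.0, False)
    edges = np.arange(0, x.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    # trim to the occupied support so the step at the distribution's edges
    # does not masquerade as low-lag structure
    nz = np.nonzero(counts)[0]
    counts = counts[nz[0]:nz[-1] + 1].astype(float)
    w = min(int(round(detrend_window / bin_width)), len(counts))
    if w % 2 == 0:
        w -= 1
    w = max(w, 3)  # odd window, no longer than the histogram
    kernel = np.ones(w)
    # moving average normalized by in-array coverage (no zero-pad bias)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts), kernel, mode="same")
    trend = num / den
    detr = counts - trend
    period, prom = _peak_lag(detr, bin_width, *lag_range)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(detr)
        null[i] = _peak_lag(perm, bin_width, *lag_range)[1]
    threshold = float(np.percentile(null, 95))
    return PeriodicityEstimate(period, prom, bool(prom > threshold))


STANDARD_CONTRASTS = (("S_T", "S_NT"), ("R_T", "R_NT"), ("S_T", "R_T"))


def mann_whitney(
    a, b, method: str = "auto", exact_max_n: int = 8
) -> float:
    """Two-sided Mann-Whitney U p-value.

    method='auto' uses the exact null distribution when the smaller group
    has <= exact_max_n observations (and no ties), otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "auto":
        method = "exact" if min(a.size, b.size) <= exact_max_n else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_length_groups(
    lengths_by_condition: dict[str, "np.ndarray"],
    contrasts=STANDARD_CONTRASTS,
    method: str = "auto",
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Mann-Whitney tests between condition groups
    (defaults: treated vs non-treated within each phenotype, and
    sensitive-treated vs resistant-treated). Empty groups skip their
    contrasts with a log line."""
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in contrasts:
        a = lengths_by_condition.get(g1)
        b = lengths_by_condition.get(g2)
        if a is None or b is None or len(a) == 0 or len(b) == 0:
            logger.info("contrast %s vs %s skipped (empty group)", g1, g2)
            continue
        out[(g1, g2)] = mann_whitney(a, b, method=method)
    return out


def treatment_fractions(
    table: pd.DataFrame, drug: str, against: float = 0.5
) -> pd.DataFrame:
    """Share of a drug's unique microDNAs that came from treated samples.

    Uses the group count table's Total column for the drug's four
    condition rows. Reports the treated percentage overall and within the
    resistant and sensitive phenotypes, each with a chi-square test of the
    T/NT split against `against` (default 50:50).
    """
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    tot = {cond: int(table.loc[(drug, cond), "Total"])
           for cond in ("R_T", "R_NT", "S_T", "S_NT")}
    rows = []
    for label, t, nt in (
        ("overall", tot["R_T"] + tot["S_T"], tot["R_NT"] + tot["S_NT"]),
        ("within_R", tot["R_T"], tot["R_NT"]),
        ("within_S", tot["S_T"], tot["S_NT"]),
    ):
        denom = t + nt
        if denom == 0:
            raise ValueError(f"zero denominator for {drug} {label}")
        pct = 100.0 * t / denom
        chi = sps.chisquare([t, nt], [denom * against, denom * (1 - against)])
        rows.append(
            {"drug": drug, "split": label, "treated": t, "non_treated": nt,
             "treated_percent": pct, "p_value": float(chi.pvalue)}
        )
    return pd.DataFrame(rows)
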