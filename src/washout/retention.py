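"""Per-taxon retention ratios for paired granular/effluent samples.

The retention ratio of a taxon at one sampling day is its relative read
abundance in the reactor (granular) sample divided by its relative read
abundance in the contemporaneous effluent sample.  A ratio above 1 means the
taxon is better represented inside the reactor than in what washes out —
good retention; below 1 means preferential wash-out (surface erosion or
suspended growth).  Under purely proportional wash-out every ratio is 1.

This module computes ratio time series per (taxon, reactor), assigns each
day to the start-up (weeks 1-6) or steady-state (weeks 7-12) phase, tests
steady-state ratios against 1 with a one-sample Wilcoxon signed-rank test
(exact null distribution for small n), and correlates ratios with time
(Pearson) to detect progressive retention or wash-out trends.

Zeros: a taxon absent from the effluent sample has an undefined ratio
(division by zero).  Undefined points are flagged with a reason and excluded
from the statistics — never interpolated, never silently dropped.  An
optional pseudocount mode (handled upstream, see ``pipeline``) trades this
transparency for completeness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import RelAbundTable
from .tables_io import PairedIndex, ValidationError

__all__ = [
    "STARTUP",
    "STEADY",
    "DEFAULT_STARTUP_END_DAY",
    "STAR_CUTOFFS",
    "RetentionSeries",
    "TrendResult",
    "PhaseTest",
    "assign_phase",
    "retention_ratio",
    "retention_series",
    "pearson_trend",
    "significance_stars",
    "wilcoxon_vs_one",
    "signed_rank_test",
    "summarize_boxplot",
    "trend_table",
    "phase_test_table",
]

STARTUP = "startup"
STEADY = "steady"

#: Last day of the start-up period: weeks 1-6 are start-up, weeks 7-12 steady.
DEFAULT_STARTUP_END_DAY = 42

#: Significance marks and their strict p-value cutoffs.
STAR_CUTOFFS = (("***", 0.001), ("**", 0.01), ("*", 0.05), ("•", 0.1))

ZERO_EFFLUENT = "zero_effluent"
ZERO_BOTH = "zero_both"


def assign_phase(day: int, startup_end_day: int = DEFAULT_STARTUP_END_DAY) -> str:
    """Classify a sampling day as start-up (day <= boundary) or steady state."""
    if day < 0:
        raise ValueError(f"negative day: {day}")
    return STARTUP if day <= startup_end_day else STEADY


def retention_ratio(granular_ra: float, effluent_ra: float) -> tuple[float, str | None]:
    """Ratio of granular to effluent relative abundance for one taxon/day.

    Returns ``(ratio, None)`` when defined, or ``(nan, reason)`` with reason
    ``"zero_effluent"`` (taxon seen in the granules but not the effluent) or
    ``"zero_both"`` (seen in neither).
    """
    for name, v in (("granular", granular_ra), ("effluent", effluent_ra)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} relative abundance outside [0, 1]: {v}")
    if effluent_ra > 0.0:
        return granular_ra / effluent_ra, None
    return math.nan, (ZERO_BOTH if granular_ra == 0.0 else ZERO_EFFLUENT)


@dataclass(frozen=True)
class RetentionSeries:
    """Time series of retention ratios for one taxon in one reactor.

    ``points`` has columns ``day, ratio, reason, phase``; undefined ratios
    are NaN with a non-null reason.
    """

    taxon: str
    reactor: str
    points: pd.DataFrame

    def defined(self, phase: str | None = None) -> pd.DataFrame:
        pts = self.points[self.points["ratio"].notna()]
        if phase is not None:
            pts = pts[pts["phase"] == phase]
        return pts

    @property
    def n_defined(self) -> int:
        return int(self.points["ratio"].notna().sum())

    @property
    def n_undefined(self) -> int:
        return len(self.points) - self.n_defined


def retention_series(
    ra: RelAbundTable,
    pairs: PairedIndex,
    taxa: Sequence[str],
    *,
    startup_end_day: int = DEFAULT_STARTUP_END_DAY,
) -> list[RetentionSeries]:
    """Retention-ratio series for each (taxon, reactor) over the paired days."""
    if len(pairs) == 0:
        raise ValidationError("paired index is empty")
    missing = [t for t in taxa if t not in ra.data.index]
    if missing:
        raise KeyError(f"taxa not in abundance table: {missing}")
    out: list[RetentionSeries] = []
    for reactor in pairs.reactors:
        rpairs = sorted(pairs.for_reactor(reactor), key=lambda p: p.day)
        for taxon in taxa:
            rows = []
            for p in rpairs:
                g = float(ra.data.at[taxon, p.granular])
                e = float(ra.data.at[taxon, p.effluent])
                ratio, reason = retention_ratio(g, e)
                rows.append(
                    {
                        "day": p.day,
                        "ratio": ratio,
                        "reason": reason,
                        "phase": assign_phase(p.day, startup_end_day),
                    }
                )
            out.append(RetentionSeries(taxon, reactor, pd.DataFrame(rows)))
    return out


def significance_stars(p: float) -> str:
    """Map a p-value to its significance mark (strict inequalities)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value outside (0, 1]: {p}")
    for mark, cutoff in STAR_CUTOFFS:
        if p < cutoff:
            return mark
    return ""


@dataclass(frozen=True)
class TrendResult:
    """Pearson correlation of retention ratio against day since seeding."""

    taxon: str
    reactor: str
    n: int
    r: float = math.nan
    p_value: float = math.nan
    stars: str = ""
    not_computable: str | None = None


def pearson_trend(series: RetentionSeries, *, log_scale: bool = False) -> TrendResult:
    """Pearson r and two-sided p of (day, ratio) over the defined points.

    Uses all defined points across both phases.  With fewer than 3 points or
    zero variance in either variable the result is flagged not-computable.
    """
    pts = series.defined()
    n = len(pts)
    if n < 3:
        return TrendResult(series.taxon, series.reactor, n, not_computable="too_few_points")
    day = pts["day"].to_numpy(dtype=float)
    ratio = pts["ratio"].to_numpy(dtype=float)
    if log_scale:
        ratio = np.log(ratio)
    if np.ptp(day) == 0.0 or np.ptp(ratio) == 0.0:
        return TrendResult(series.taxon, series.reactor, n, not_computable="constant")
    res = stats.pearsonr(day, ratio)
    p = max(float(res.pvalue), np.nextafter(0.0, 1.0))
    return TrendResult(series.taxon, series.reactor, n, float(res.statistic), p, significance_stars(p))


# ---------------------------------------------------------------------------
# One-sample Wilcoxon signed-rank test against a hypothesized value
# ---------------------------------------------------------------------------

EXACT_MAX_N = 25


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the null distribution of W+.

    Conditions on the observed |difference| ranks (midranks under ties) and
    sums over all 2^n equiprobable sign assignments via a rank-sum
    convolution; ranks are doubled so midranks become integers.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_test(
    values: np.ndarray,
    null_value: float = 1.0,
    *,
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> tuple[float, float, int, str | None]:
    """One-sample two-sided Wilcoxon signed-rank test.

    Differences equal to zero are dropped before ranking (the Wilcoxon
    convention); ties in |difference| get midranks.  The null distribution is
    exact (sign-assignment enumeration) for n <= 25, otherwise a
    tie-corrected normal approximation without continuity correction.

    Returns ``(statistic, p_value, n_used, not_computable_reason)`` where the
    statistic is min(W+, W-).
    """
    d = np.asarray(values, dtype=float) - null_value
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return math.nan, math.nan, 0, "degenerate"
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    statistic = min(w_plus, w_minus)
    if mode == "exact" or (mode == "auto" and n <= EXACT_MAX_N):
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return statistic, math.nan, n, "degenerate"
        z = (w_plus - mean) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return statistic, min(p, 1.0), n, None


@dataclass(frozen=True)
class PhaseTest:
    """Wilcoxon-vs-1 summary of one taxon's ratios within one phase."""

    taxon: str
    reactor: str
    phase: str
    n: int
    median_ratio: float = math.nan
    wilcoxon_statistic: float = math.nan
    p_value: float = math.nan
    direction: str = "none"  # above_1 | below_1 | none
    not_computable: str | None = None


def wilcoxon_vs_one(
    series: RetentionSeries,
    phase: str,
    *,
    alpha: float = 0.05,
    mode: Literal["auto", "exact", "normal"] = "auto",
    log_scale: bool = False,
) -> PhaseTest:
    """Test whether a taxon's retention ratios in a phase differ from 1.

    Two-sided one-sample Wilcoxon signed-rank on the defined ratios of the
    phase.  Direction is ``above_1``/``below_1`` only when the median is on
    that side of 1 and p < ``alpha``.  ``log_scale`` tests log-ratios against
    0, which symmetrizes reciprocal deviations; the default is raw ratios
    against 1.
    """
    pts = series.defined(phase)
    ratios = pts["ratio"].to_numpy(dtype=float)
    if ratios.size == 0:
        return PhaseTest(series.taxon, series.reactor, phase, 0, not_computable="no_defined_points")
    median = float(np.median(ratios))
    if log_scale:
        stat, p, n, reason = signed_rank_test(np.log(ratios), 0.0, mode=mode)
    else:
        stat, p, n, reason = signed_rank_test(ratios, 1.0, mode=mode)
    if reason is not None:
        return PhaseTest(
            series.taxon, series.reactor, phase, n, median, not_computable=reason
        )
    direction = "none"
    if p < alpha:
        if median > 1.0:
            direction = "above_1"
        elif median < 1.0:
            direction = "below_1"
    return PhaseTest(series.taxon, series.reactor, phase, n, median, stat, p, direction)


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def summarize_boxplot(series: RetentionSeries, phase: str | None = None) -> BoxplotSummary:
    """Tukey five-number summary of the defined ratios (1.5 x IQR whiskers).

    Quartiles use the linear-interpolation quantile rule; whiskers sit at the
    most extreme data points within 1.5 IQR of the quartiles.
    """
    values = series.defined(phase)["ratio"].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("no defined points to summarize")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(sorted(values[(values < lo_fence) | (values > hi_fence)]))
    return BoxplotSummary(float(med), float(q1), float(q3), float(inside.min()), float(inside.max()), outliers)


# ---------------------------------------------------------------------------
# Tabular summaries
# ---------------------------------------------------------------------------


def trend_table(results: Iterable[TrendResult], *, bh_column: bool = True) -> pd.DataFrame:
    """Trend correlations as a tidy frame (taxon, reactor, n, r, p, stars).

    ``p_bh`` is a Benjamini-Hochberg adjusted p-value column added for
    convenience; the stars are based on the raw p-values.
    """
    rows = [
        {
            "taxon": t.taxon,
            "reactor": t.reactor,
            "n": t.n,
            "r": t.r,
            "p": t.p_value,
            "stars": t.stars,
            "not_computable": t.not_computable or "",
        }
        for t in results
    ]
    df = pd.DataFrame(rows)
    if bh_column and len(df) and df["p"].notna().any():
        mask = df["p"].notna()
        df.loc[mask, "p_bh"] = stats.false_discovery_control(df.loc[mask, "p"], method="bh")
    return df


def phase_test_table(results: Iterable[PhaseTest]) -> pd.DataFrame:
    rows = [
        {
            "taxon": t.taxon,
            "reactor": t.reactor,
            "phase": t.phase,
            "n": t.n,
            "median_ratio": t.median_ratio,
            "W": t.wilcoxon_statistic,
            "p": t.p_value,
            "direction": t.direction,
            "not_computable": t.not_computable or "",
        }
        for t in results
    ]
    return pd.DataFrame(rows)
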