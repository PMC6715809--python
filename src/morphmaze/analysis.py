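"""Score-method concordance and reaction-time distribution statistics.

Concordance between two scoring methods is assessed by linear regression of
per-animal-per-phase mean scores with a single outlier-rejection pass: fit
once, compute the standard deviation of the *absolute* residuals, mark
points more than 3 of those SDs from the fit as outliers, and refit through
the remainder.  Exactly two fits, no iteration.

Reaction times are analysed only for the full task (phases 5-7) and never
include timed-out trials (those sit at the timeout ceiling and say nothing
about the animal).  Distributions are summarised by their mode (peak of a
100 ms histogram) and interquartile range, and compared between correct and
incorrect trials with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "RTSummary",
    "concordance",
    "phase_means",
    "rt_summaries",
    "rt_compare",
    "ANALYSIS_PHASES",
]

ANALYSIS_PHASES = (5, 6, 7)


class DegenerateFitError(ValueError):
    """All points rejected, or too few points left to refit."""


@dataclass(frozen=True)
class ConcordanceResult:
    slope: float
    intercept: float  # percent units
    r_squared: float
    p_value: float
    outlier_mask: np.ndarray  # True where the point was excluded
    n_points: int

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())


def concordance(
    x: Sequence[float], y: Sequence[float], n_sd: float = 3.0
) -> ConcordanceResult:
    """Two-pass robust regression of method-2 scores on method-1 scores.

    Pass 1 fits ordinary least squares and computes s = SD (ddof=1) of the
    absolute residuals; points with |residual| > ``n_sd`` * s are flagged.
    Pass 2 refits through the remaining points and is what the result
    reports, together with the outlier mask.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    first = stats.linregress(x, y)
    abs_resid = np.abs(y - (first.intercept + first.slope * x))
    sd = float(np.std(abs_resid, ddof=1))
    mask = abs_resid > n_sd * sd if sd > 0 else np.zeros(len(x), dtype=bool)
    keep = ~mask
    if keep.sum() < 3:
        raise DegenerateFitError(
            f"only {int(keep.sum())} points survive outlier rejection"
        )
    fit = stats.linregress(x[keep], y[keep])
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        outlier_mask=mask,
        n_points=len(x),
    )


def phase_means(
    daily_a: pd.DataFrame, daily_b: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Align two daily score frames into per-animal-per-phase mean pairs.

    The concordance scatter has one point per animal per phase (the mean of
    that animal's daily percent correct within the phase), matching the
    presentation convention for method comparisons.
    """
    def collapse(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby(["animal", "phase"], as_index=False)["pct_correct"].mean()

    merged = collapse(daily_a).merge(
        collapse(daily_b), on=["animal", "phase"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("no overlapping animal/phase cells")
    return (
        merged["pct_correct_a"].to_numpy(),
        merged["pct_correct_b"].to_numpy(),
        merged,
    )


@dataclass(frozen=True)
class RTSummary:
    phase: int | None  # None = pooled over analysis phases
    outcome_class: str  # "CORRECT" | "INCORRECT"
    n_trials: int
    mode_ms: float
    iqr_ms: float
    samples: np.ndarray


def _histogram_mode(samples: np.ndarray, bin_ms: float, upper: float) -> float:
    edges = np.arange(0.0, upper + bin_ms, bin_ms)
    counts, edges = np.histogram(samples, bins=edges)
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2.0)


def rt_summaries(
    df: pd.DataFrame,
    phases: Sequence[int] = ANALYSIS_PHASES,
    bin_ms: float = 100.0,
    include_pooled: bool = True,
) -> list[RTSummary]:
    """Mode and IQR of reaction times per phase x outcome, plus pooled rows.

    Input is a trial-level frame (see :func:`morphmaze.scoring.trials_frame`).
    Hint trials and timeouts are dropped; only ``phases`` (default 5-7, the
    full task) are summarised.  Quantiles use linear interpolation between
    order statistics.
    """
    data = df[
        df["phase"].isin(list(phases))
        & (df["outcome"] != "TIMEOUT")
        & df["rt_ms"].notna()
        & ~df["is_hint"]
    ]
    if data.empty:
        raise ValueError("no scoreable reaction times in the requested phases")
    upper = float(data["rt_ms"].max()) + bin_ms
    out: list[RTSummary] = []
    groups: list[tuple[int | None, pd.DataFrame]] = [
        (p, data[data["phase"] == p]) for p in phases
    ]
    if include_pooled:
        groups.append((None, data))
    for phase, g in groups:
        for outcome in ("CORRECT", "INCORRECT"):
            samples = g.loc[g["outcome"] == outcome, "rt_ms"].to_numpy(float)
            if samples.size == 0:
                continue
            q25, q75 = np.percentile(samples, [25, 75])
            out.append(
                RTSummary(
                    phase=phase,
                    outcome_class=outcome,
                    n_trials=int(samples.size),
                    mode_ms=_histogram_mode(samples, bin_ms, upper),
                    iqr_ms=float(q75 - q25),
                    samples=samples,
                )
            )
    return out


def rt_compare(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test on RT samples.

    Uses the exact null distribution for small samples (either n < 30) and
    the asymptotic one otherwise.  Returns (statistic, p value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    method = "exact" if min(len(a), len(b)) < 30 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
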