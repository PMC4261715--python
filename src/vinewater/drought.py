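"""Drought-day statistics and monotone-trend testing for FTSW series.

A *drought day* is a day within the growing-season window (1 May to
30 September) whose fraction of transpirable soil water is at or below a
severity threshold (default 0.15, the soil-moisture equivalent of a predawn
leaf water potential of about -0.6 MPa, the conventional mark of severe
water stress in grapevine).  Annual counts are smoothed with 30-year
running means and tested for monotone trends with the Mann-Kendall test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class DroughtConfig:
    """Severity threshold and counting window.

    ``psi_pd_equivalent`` documents the predawn-water-potential meaning of
    the FTSW threshold; it is not used in any computation.
    """

    threshold: float = 0.15
    window_start: tuple[int, int] = (5, 1)
    window_end: tuple[int, int] = (9, 30)
    psi_pd_equivalent: float = -0.6  # MPa

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("drought threshold must lie in (0, 1)")


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test summary: the S statistic, Kendall's tau and the
    two-sided normal-approximation p-value."""

    s: int
    tau: float
    p_value: float


def drought_days(
    ftsw: pd.Series, year: int, cfg: DroughtConfig = DroughtConfig()
) -> int:
    """Number of growing-season days with FTSW at or below the threshold.

    The comparison is inclusive (FTSW <= threshold counts).  Raises if the
    window is not fully covered by the series.
    """
    start = pd.Timestamp(year, *cfg.window_start)
    end = pd.Timestamp(year, *cfg.window_end)
    window = pd.date_range(start, end, freq="D")
    missing = window.difference(pd.DatetimeIndex(ftsw.index))
    if len(missing):
        raise ValueError(
            f"FTSW series does not cover the {year} window; missing "
            f"{[d.strftime('%Y-%m-%d') for d in missing[:5]]} ..."
        )
    values = ftsw.loc[window]
    return int((values <= cfg.threshold).sum())


def annual_drought_days(
    ftsw: pd.Series, cfg: DroughtConfig = DroughtConfig()
) -> pd.Series:
    """Drought-day counts for every year fully covering the window."""
    years = []
    counts = []
    for year in sorted(set(ftsw.index.year)):
        try:
            counts.append(drought_days(ftsw, year, cfg))
        except ValueError:
            continue
        years.append(year)
    return pd.Series(counts, index=pd.Index(years, name="year"), name="drought_days")


def running_mean(series: pd.Series, width: int = 30) -> pd.Series:
    """Centred running mean; the output is shortened to full windows only."""
    if len(series) < width:
        raise ValueError(f"need at least {width} values for a {width}-wide window")
    out = series.rolling(width, center=True).mean().dropna()
    return out


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall test for a monotone trend.

    ``S`` is the sum of signs over all ordered pairs; its variance uses the
    standard tie correction, and the z score applies a continuity
    correction.  Kendall's tau is the tie-adjusted (tau-b) ratio.  A
    constant series returns S = 0, p = 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a trend test")

    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.sum(np.triu(diff_sign, k=1)))

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    n_pairs = n * (n - 1) / 2
    tie_term = np.sum(ties * (ties - 1)) / 2
    denom = np.sqrt((n_pairs - tie_term) * n_pairs)
    tau = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        return TrendResult(s=s, tau=float(tau), p_value=1.0)
    z = (s - np.sign(s)) / np.sqrt(var_s)
    p = 2.0 * sps.norm.sf(abs(z))
    return TrendResult(s=s, tau=float(tau), p_value=float(min(p, 1.0)))


def risk_report(
    runs: dict[str, pd.Series],
    cfg: DroughtConfig = DroughtConfig(),
    smooth_width: int = 30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summarise drought risk for a set of named daily FTSW runs
    (site x scenario combinations).

    Returns one row per run with the mean annual drought-day count, the
    Mann-Kendall statistics of the annual counts and a significance flag.
    Annual counts and smoothed curves are attached in ``DataFrame.attrs``
    for plotting or export.
    """
    rows = []
    annual = {}
    smoothed = {}
    for name, ftsw in runs.items():
        counts = annual_drought_days(ftsw, cfg)
        if counts.empty:
            raise ValueError(f"run '{name}' covers no complete counting window")
        annual[name] = counts
        if len(counts) >= smooth_width:
            smoothed[name] = running_mean(counts, smooth_width)
        if len(counts) >= 4:
            trend = mann_kendall(counts.to_numpy())
        else:  # too short for a trend test
            trend = TrendResult(s=0, tau=float("nan"), p_value=float("nan"))
        rows.append(
            {
                "run": name,
                "years": len(counts),
                "mean_drought_days": counts.mean(),
                "max_drought_days": int(counts.max()),
                "mk_s": trend.s,
                "mk_tau": trend.tau,
                "mk_p": trend.p_value,
                "significant": bool(trend.p_value < alpha),
            }
        )
    report = pd.DataFrame(rows).set_index("run")
    report.attrs["annual_counts"] = annual
    report.attrs["smoothed"] = smoothed
    return report


def plot_risk(report: pd.DataFrame, ax=None):
    """Plot smoothed drought-day trajectories from a risk report."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, series in report.attrs.get("smoothed", {}).items():
        ax.plot(series.index, series.values, label=name)
    ax.set_xlabel("year")
    ax.set_ylabel("drought days (30-yr running mean)")
    ax.legend(fontsize=8)
    return ax
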