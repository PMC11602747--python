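"""Mean annual yield and the Sustainable Yield Index (SYI).

For a multi-year yield series y₁…yₙ,

    SYI = (Ȳ − σ) / Ymax

where Ȳ is the mean yield, σ its standard deviation over the years and
Ymax the highest yield observed.  A high, stable series gives SYI near 1
(exactly 1 iff the series is constant and positive); a volatile series can
push SYI negative when σ > Ȳ, and such values are reported as-is with a
warning rather than clipped.  SYI is invariant to rescaling the whole
series by any k > 0.

σ defaults to the sample (n−1) convention; ``sd_mode="population"``
selects the n denominator.  Sample-σ SYI ≤ population-σ SYI always.

SYI is computed per plot over that plot's own year series, so each
treatment has one SYI value per replicate block and the index can enter a
one-way ANOVA; a per-treatment granularity (SYI of the treatment-mean
series) is also exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .trial import TrialTable

__all__ = ["SYIValue", "SYIResult", "compute_syi", "per_treatment_syi",
           "mean_annual_yield"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SYIValue:
    """One SYI with its audit components."""

    syi: float
    mean: float
    sd: float
    max: float
    n_years: int
    sd_mode: str


@dataclass
class SYIResult:
    """Replicate-level SYI plus per-treatment aggregation."""

    per_plot: pd.DataFrame       # plot_id, treatment, syi, mean, sd, max, n_years
    per_treatment: pd.DataFrame  # treatment, mean, se, n
    sd_mode: str


def compute_syi(values, sd_mode: str = "sample") -> SYIValue:
    """SYI of one yield series.

    Requires ≥ 2 observations and a positive maximum; an all-zero series
    makes the ratio undefined and raises
    :class:`~soiltrial.errors.DegenerateDataError`.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise DegenerateDataError("a yield series must be one-dimensional")
    if y.size < 2:
        raise DegenerateDataError("SYI needs at least 2 years of yield")
    if np.any(y < 0):
        raise DegenerateDataError("yields must be ≥ 0")
    ymax = float(y.max())
    if ymax == 0:
        raise DegenerateDataError("all-zero yield series: SYI undefined (division by zero)")
    if sd_mode == "sample":
        sd = float(y.std(ddof=1))
    elif sd_mode == "population":
        sd = float(y.std(ddof=0))
    else:
        raise DegenerateDataError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    mean = float(y.mean())
    syi = (mean - sd) / ymax
    if syi < 0:
        log.warning("negative SYI %.4f (sd %.4f exceeds mean %.4f)", syi, sd, mean)
    return SYIValue(syi, mean, sd, ymax, y.size, sd_mode)


def _series_by_plot(table: TrialTable) -> pd.core.groupby.DataFrameGroupBy:
    y = table.yields.sort_values(["plot_id", "year"], kind="stable")
    return y.groupby("plot_id", sort=False)


def per_treatment_syi(table: TrialTable, sd_mode: str = "sample") -> SYIResult:
    """SYI per plot (over its own years), aggregated by treatment mean ± SE.

    Replicate-level values are retained in ``per_plot`` so that SYI can be
    analyzed with the same one-way ANOVA / letter machinery as any other
    response.
    """
    rows = []
    for pid, grp in _series_by_plot(table):
        try:
            v = compute_syi(grp["yield"].to_numpy(), sd_mode)
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"plot {pid}: {exc}") from exc
        rows.append((pid, grp["treatment"].iloc[0], v.syi, v.mean, v.sd, v.max, v.n_years))
    per_plot = pd.DataFrame(
        rows, columns=["plot_id", "treatment", "syi", "mean", "sd", "max", "n_years"])
    grp = per_plot.groupby("treatment", sort=False)["syi"]
    per_treatment = pd.DataFrame({
        "mean": grp.mean(),
        "se": grp.std(ddof=1) / np.sqrt(grp.count()),
        "n": grp.count(),
    }).reset_index()
    return SYIResult(per_plot, per_treatment, sd_mode)


def treatment_series_syi(table: TrialTable, sd_mode: str = "sample") -> pd.DataFrame:
    """Alternative granularity: SYI of each treatment's year-mean series."""
    y = table.yields
    means = y.groupby(["treatment", "year"], sort=False)["yield"].mean().reset_index()
    rows = []
    for t, grp in means.groupby("treatment", sort=False):
        v = compute_syi(grp.sort_values("year")["yield"].to_numpy(), sd_mode)
        rows.append((t, v.syi, v.mean, v.sd, v.max, v.n_years))
    return pd.DataFrame(rows, columns=["treatment", "syi", "mean", "sd", "max", "n_years"])


def mean_annual_yield(table: TrialTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot multi-year mean yield and its per-treatment mean ± SE.

    Returns ``(per_plot, per_treatment)``; replicate-level means feed the
    yield ANOVA.
    """
    if table.yields.empty:
        raise DegenerateDataError("no yield records")
    per_plot = (
        table.yields.groupby(["plot_id", "treatment"], sort=False)["yield"]
        .mean()
        .reset_index()
        .rename(columns={"yield": "mean_yield"})
    )
    grp = per_plot.groupby("treatment", sort=False)["mean_yield"]
    per_treatment = pd.DataFrame({
        "mean": grp.mean(),
        "se": grp.std(ddof=1) / np.sqrt(grp.count()),
        "n": grp.count(),
    }).reset_index()
    return per_plot, per_treatment
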