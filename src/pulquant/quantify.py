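"""%NSAF and RPKM quantification, grouping, and trailing-average smoothing.

%NSAF (percent normalised spectral abundance factor) for protein *i* in one
replicate is 100 * v_i / sum_j v_j, where v is the size-adjusted spectral
count ("quantitative value"); when raw spectral counts are supplied the
length adjustment v_i = c_i / L_i is applied first.  Replicate averaging
always divides by the designed replicate count (three biological replicates),
counting proteins missing from a replicate as zero.

RPKM (reads per kilobase per million) for a gene or MAG is
1,000,000 * ((reads mapped / length in kbp) / library size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import SampleDesign


@dataclass
class AbundanceMatrix:
    """Protein x replicate abundance values with protein lengths and design.

    ``values`` may contain NaN for protein/replicate cells where the protein
    was not identified in that replicate; those count as zero when replicates
    are averaged.  ``mode`` records whether values are already size-adjusted
    ("quantitative") or raw spectral counts ("raw_counts").
    """

    values: pd.DataFrame
    lengths: pd.Series
    design: list[SampleDesign]
    mode: str = "quantitative"

    def __post_init__(self) -> None:
        if self.mode not in ("quantitative", "raw_counts"):
            raise ValueError(f"unknown abundance mode {self.mode!r}")
        if (self.values.fillna(0.0) < 0).any().any():
            raise ValueError("abundance values must be nonnegative")
        missing_len = self.values.index.difference(self.lengths.index)
        if len(missing_len):
            raise ValueError(f"proteins without lengths: {list(missing_len)[:5]}")
        rep_owner: dict[str, str] = {}
        for d in self.design:
            for rep in d.replicate_ids:
                if rep in rep_owner:
                    raise ValueError(f"replicate {rep} in two samples")
                rep_owner[rep] = d.sample_id
        stray = [c for c in self.values.columns if c not in rep_owner]
        if stray:
            raise ValueError(f"replicate columns absent from design: {stray[:5]}")


@dataclass
class ReadCountTable:
    """Feature x sample mapped-read counts with lengths (kbp) and library sizes."""

    counts: pd.DataFrame
    feature_len_kbp: pd.Series
    library_size: pd.Series

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("read counts must be nonnegative")
        lens = self.feature_len_kbp.reindex(self.counts.index)
        if lens.isna().any() or (lens <= 0).any():
            raise ValueError("every feature needs a positive length in kbp")
        libs = self.library_size.reindex(self.counts.columns)
        if libs.isna().any() or (libs <= 0).any():
            raise ValueError("every sample needs a positive library size")
        short = self.counts.sum(axis=0) > libs
        if short.any():
            raise ValueError(
                f"library size smaller than mapped reads for: {list(libs.index[short])}"
            )


@dataclass
class TimeSeriesTable:
    """Group x sample values plus per-group cross-sample mean and sd (n-1)."""

    values: pd.DataFrame
    group_key: str
    mean: pd.Series | None = None
    sd: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = self.values.mean(axis=1)
        if self.sd is None:
            self.sd = self.values.std(axis=1, ddof=1)

    def to_long(self, day_of: Mapping[str, int] | None = None) -> pd.DataFrame:
        long = (
            self.values.rename_axis(index=self.group_key, columns="sample_id")
            .stack()
            .rename("value")
            .reset_index()
        )
        if day_of is not None:
            long["julian_day"] = long["sample_id"].map(day_of)
        return long


def nsaf_percent(m: AbundanceMatrix) -> pd.DataFrame:
    """Per-replicate %NSAF: each column scaled to sum to 100.

    In raw-count mode values are first divided by protein length (aa).  An
    all-zero replicate column cannot be normalised and raises, naming the
    replicate.
    """
    values = m.values.astype(float)
    if m.mode == "raw_counts":
        values = values.div(m.lengths.reindex(values.index), axis=0)
    totals = values.sum(axis=0, skipna=True)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"replicate column(s) with zero total: {list(dead.index)}")
    return 100.0 * values.div(totals, axis=1)


def average_replicates(
    nsaf: pd.DataFrame, design: Sequence[SampleDesign]
) -> pd.DataFrame:
    """Mean %NSAF per sample, dividing by the designed replicate count.

    Proteins not identified in a replicate (NaN cells, or replicate columns
    absent from the matrix) contribute zero; the divisor is always the
    number of designed replicates, not the number with detections.
    """
    known = {rep for d in design for rep in d.replicate_ids}
    stray = [c for c in nsaf.columns if c not in known]
    if stray:
        raise ValueError(f"replicate columns absent from design: {stray[:5]}")
    out = {}
    for d in design:
        present = [r for r in d.replicate_ids if r in nsaf.columns]
        total = nsaf[present].fillna(0.0).sum(axis=1) if present else pd.Series(
            0.0, index=nsaf.index
        )
        out[d.sample_id] = total / len(d.replicate_ids)
    return pd.DataFrame(out, index=nsaf.index)


def rpkm(t: ReadCountTable) -> pd.DataFrame:
    """RPKM = 1e6 * ((reads mapped / length in kbp) / library size)."""
    per_kbp = t.counts.div(t.feature_len_kbp.reindex(t.counts.index), axis=0)
    return 1_000_000.0 * per_kbp.div(t.library_size.reindex(t.counts.columns), axis=1)


def aggregate(
    values: pd.DataFrame,
    key: Mapping[str, str],
    group_key: str = "group",
    fallback: str = "other",
) -> TimeSeriesTable:
    """Sum per-sample values by group (ids without a group fall back to 'other').

    Also carries each group's cross-sample mean and sample (n-1) standard
    deviation.  Summation conserves column totals over any partition.
    """
    groups = pd.Series(
        [key.get(i, fallback) for i in values.index], index=values.index, name=group_key
    )
    summed = values.fillna(0.0).groupby(groups).sum()
    summed = summed.sort_index()
    return TimeSeriesTable(values=summed, group_key=group_key)


def trailing_average(
    series: Iterable[tuple[int, float | None]], k: int = 5
) -> list[tuple[int, float]]:
    """k-sample trailing average over collected dates only.

    Dates with no sample (value ``None``/NaN) produce no output point and do
    not reset the window: at each collected date the mean is over the most
    recent ``k`` collected values (fewer near the start of the series).
    """
    if k < 1:
        raise ValueError("window k must be >= 1")
    ordered = list(series)
    days = [d for d, _ in ordered]
    if days != sorted(days):
        raise ValueError("series must be ordered by day")
    collected: list[float] = []
    out: list[tuple[int, float]] = []
    for day, value in ordered:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        collected.append(float(value))
        window = collected[-k:]
        out.append((day, sum(window) / len(window)))
    return out


def spearman_trend(values: Sequence[float], days: Sequence[int]) -> float:
    """Spearman rank correlation of a series against collection day."""
    from scipy.stats import spearmanr

    rho = spearmanr(days, values).statistic
    return float(rho)


def max_abs_spearman_null(
    n_points: int,
    n_series: int,
    rng: np.random.Generator,
    n_mc: int = 2000,
    quantile: float = 0.95,
) -> float:
    """Monte-Carlo null quantile of max |Spearman rho| over trend-free series.

    For ``n_series`` independent series of ``n_points`` exchangeable values,
    the null distribution of each |rho| is the permutation distribution of
    ranks; this returns the requested quantile of the maximum across series,
    the joint test statistic for "no class shows a trend".
    """
    from scipy.stats import spearmanr

    days = np.arange(n_points)
    maxima = np.empty(n_mc)
    for i in range(n_mc):
        worst = 0.0
        for _ in range(n_series):
            perm = rng.permutation(n_points)
            worst = max(worst, abs(spearmanr(days, perm).statistic))
        maxima[i] = worst
    return float(np.quantile(maxima, quantile))
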