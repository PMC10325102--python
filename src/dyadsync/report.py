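"""Group-level coupling and variability reports.

Two descriptive complements to the classification analysis:

- per-couple mean log10 |CPSD| within frequency sub-bands, compared
  between couples who separated and couples who stayed together
  (bootstrapped histograms and a bootstrap interval on the group-mean
  difference);
- point-biserial correlations between each person's emotion variance
  and the separation outcome, per partner role and interaction context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DyadSeries
from .spectral import DEFAULT_BANDS_CPM, SpectralFeature, subband_log_magnitude

GROUP_SEPARATED = "separated"
GROUP_STAYED = "stayed"


@dataclass(frozen=True)
class PointBiserialResult:
    """Point-biserial correlation with its two-sided t-test p-value."""

    r: float
    p_value: float
    n: int


def point_biserial(
    values: Sequence[float], labels: Sequence[bool]
) -> PointBiserialResult:
    """Correlation between a continuous variable and a binary outcome.

    Equals the Pearson correlation with the 0/1-coded labels; the
    two-sided p-value comes from t = r·sqrt((n−2)/(1−r²)) on n−2
    degrees of freedom.  Requires n >= 3, both classes present and
    non-constant values.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length vectors")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if y.all() or not y.any():
        raise ValueError("both label classes must be present")
    if np.ptp(v) == 0.0:
        raise ValueError("values are constant; correlation undefined")
    res = stats.pointbiserialr(y.astype(int), v)
    return PointBiserialResult(r=float(res.statistic), p_value=float(res.pvalue), n=v.size)


def subband_summaries(
    features: Sequence[SpectralFeature],
    labels: dict[str, bool],
    bands_cpm: Sequence[tuple[float, float]] = DEFAULT_BANDS_CPM,
) -> pd.DataFrame:
    """Per-couple mean log10 |CPSD| per sub-band, tagged by outcome group.

    Returns one row per couple × band with columns ``couple_id,
    band_low, band_high, mean_log_mag, group``.
    """
    rows = []
    for sf in features:
        vals = subband_log_magnitude(sf, bands_cpm)
        group = GROUP_SEPARATED if labels[sf.couple_id] else GROUP_STAYED
        for (low, high), v in zip(bands_cpm, vals):
            if not np.isfinite(v):
                raise ValueError("non-finite sub-band summary")
            rows.append(
                {
                    "couple_id": sf.couple_id,
                    "band_low": low,
                    "band_high": high,
                    "mean_log_mag": float(v),
                    "group": group,
                }
            )
    return pd.DataFrame(
        rows, columns=["couple_id", "band_low", "band_high", "mean_log_mag", "group"]
    )


@dataclass
class GroupHistograms:
    """Bootstrap comparison of sub-band coupling magnitude by group.

    ``histograms``: binned counts of the pooled bootstrap-resampled
    per-couple values (counts per band × group sum to n_boot × group
    size), with bin edges shared across the two groups within a band.
    ``boot_means``: the bootstrap distribution of each group's mean.
    ``differences``: per-band stayed − separated mean difference with a
    95% bootstrap percentile interval.
    """

    histograms: pd.DataFrame
    boot_means: pd.DataFrame
    differences: pd.DataFrame


def _fd_edges(pooled: np.ndarray, max_bins: int = 60) -> np.ndarray:
    """Freedman–Diaconis bin edges on pooled data (fallback for ties)."""
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2.0 * iqr / np.cbrt(pooled.size) if iqr > 0 else 0.0
    n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else 10
    n_bins = min(max(n_bins, 1), max_bins)
    return np.linspace(lo, hi, n_bins + 1)


def group_histograms(
    summaries: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> GroupHistograms:
    """Bootstrap the per-band group comparison of coupling magnitude.

    Couples are resampled with replacement within group; each resample
    contributes its values to the pooled histogram and its mean to the
    group-mean bootstrap distribution.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    groups = set(summaries["group"])
    if groups != {GROUP_SEPARATED, GROUP_STAYED}:
        raise ValueError("both outcome groups must be non-empty")
    hist_rows, mean_rows, diff_rows = [], [], []
    for (low, high), band_df in summaries.groupby(
        ["band_low", "band_high"], sort=True
    ):
        values = {
            g: band_df.loc[band_df["group"] == g, "mean_log_mag"].to_numpy()
            for g in (GROUP_STAYED, GROUP_SEPARATED)
        }
        pooled_samples = {}
        means = {}
        for g, v in values.items():
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            resampled = v[idx]
            pooled_samples[g] = resampled.ravel()
            means[g] = resampled.mean(axis=1)
        edges = _fd_edges(np.concatenate(list(pooled_samples.values())))
        for g in (GROUP_STAYED, GROUP_SEPARATED):
            counts, _ = np.histogram(pooled_samples[g], bins=edges)
            for j, c in enumerate(counts):
                hist_rows.append(
                    {
                        "band_low": low,
                        "band_high": high,
                        "group": g,
                        "bin_left": edges[j],
                        "bin_right": edges[j + 1],
                        "count": int(c),
                    }
                )
            for rep, m in enumerate(means[g]):
                mean_rows.append(
                    {
                        "band_low": low,
                        "band_high": high,
                        "group": g,
                        "replicate": rep,
                        "mean": float(m),
                    }
                )
        diff = means[GROUP_STAYED] - means[GROUP_SEPARATED]
        diff_rows.append(
            {
                "band_low": low,
                "band_high": high,
                "observed_diff": float(
                    values[GROUP_STAYED].mean() - values[GROUP_SEPARATED].mean()
                ),
                "boot_diff_mean": float(diff.mean()),
                "ci_low": float(np.percentile(diff, 2.5)),
                "ci_high": float(np.percentile(diff, 97.5)),
            }
        )
    return GroupHistograms(
        histograms=pd.DataFrame(hist_rows),
        boot_means=pd.DataFrame(mean_rows),
        differences=pd.DataFrame(diff_rows),
    )


def variance_outcome_table(
    dyads_by_context: dict[str, Sequence[DyadSeries]],
    labels: dict[str, bool],
    role_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Point-biserial correlations of per-person variance vs separation.

    One row per partner role × context (the classic four-row layout);
    roles default to the generic A/B when no role metadata exists.
    """
    rows = []
    for context, dyads in dyads_by_context.items():
        y = [labels[d.couple_id] for d in dyads]
        for role, attr in zip(role_names, ("series_a", "series_b")):
            variances = [float(np.var(getattr(d, attr))) for d in dyads]
            res = point_biserial(variances, y)
            rows.append(
                {
                    "role": role,
                    "context": context,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows, columns=["role", "context", "r", "p_value", "n"])
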