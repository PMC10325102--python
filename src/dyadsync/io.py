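"""Reading, writing and validating dyadic valence time series.

The canonical on-disk representation is a long-format CSV with one
observation per row (``couple_id, partner, context, t, valence``):
self-describing and robust to row order.  Couple-level outcome labels
live in a separate CSV (``couple_id, separated, excluded,
exclusion_reason``).

Valence is a continuous self-report of momentary emotional pleasantness,
bounded on [-1, +1] (joystick scale: far left = very negative, far right
= very positive), sampled at 1 Hz while partners re-watch their recorded
interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Interaction contexts used throughout: a positively themed conversation
#: and a conflict conversation.
CONTEXTS = ("positive", "conflict")

#: Longest run of missing seconds repaired by forward-fill; longer gaps
#: drop the couple-context (spectral features need gapless series).
MAX_FFILL_GAP = 2

SERIES_COLUMNS = ["couple_id", "partner", "context", "t", "valence"]
LABEL_COLUMNS = ["couple_id", "separated", "excluded", "exclusion_reason"]


@dataclass(frozen=True)
class DyadSeries:
    """One couple's paired valence series for one interaction context.

    Parameters
    ----------
    couple_id : str
        Opaque couple identifier.
    context : str
        Interaction context label (e.g. ``"positive"`` or ``"conflict"``).
    series_a, series_b : ndarray
        Per-second valence of partner A and partner B, equal length >= 4.
    sample_rate : float
        Sampling rate in Hz (1.0 for per-second joystick ratings).
    bounded : bool
        Whether values are constrained to [-1, +1].  Surrogate transforms
        (centering/standardization) relax the bound and set this False.
    """

    couple_id: str
    context: str
    series_a: np.ndarray
    series_b: np.ndarray
    sample_rate: float = 1.0
    bounded: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.series_a, dtype=np.float64)
        b = np.asarray(self.series_b, dtype=np.float64)
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if a.size != b.size:
            raise ValueError(
                f"partner series lengths differ ({a.size} vs {b.size})"
            )
        if a.size < 4:
            raise ValueError("series must contain at least 4 samples")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("series contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.bounded and (
            np.abs(a).max() > 1.0 + 1e-9 or np.abs(b).max() > 1.0 + 1e-9
        ):
            raise ValueError("valence values outside [-1, +1]")

    @property
    def n_samples(self) -> int:
        return int(self.series_a.size)


@dataclass(frozen=True)
class CoupleLabel:
    """Couple-level outcome: separated within the two-year follow-up."""

    couple_id: str
    separated: bool
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded couples must carry an exclusion reason")


@dataclass
class ValidationReport:
    """Structural validation outcome of a long-format series file."""

    n_rows: int = 0
    n_series: int = 0
    dropped: list[dict] = field(default_factory=list)

    def drop(self, couple_id: str, context: str, reason: str) -> None:
        self.dropped.append(
            {"couple_id": str(couple_id), "context": str(context), "reason": reason}
        )
        logger.warning("dropping %s/%s: %s", couple_id, context, reason)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_series": self.n_series,
            "dropped": list(self.dropped),
        }


def dyads_to_frame(dyads: Iterable[DyadSeries]) -> pd.DataFrame:
    """Flatten DyadSeries objects into the long format."""
    parts = []
    for d in dyads:
        t = np.arange(d.n_samples)
        for partner, series in (("A", d.series_a), ("B", d.series_b)):
            parts.append(
                pd.DataFrame(
                    {
                        "couple_id": d.couple_id,
                        "partner": partner,
                        "context": d.context,
                        "t": t,
                        "valence": series,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=SERIES_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_dyads(dyads: Iterable[DyadSeries], path: str | Path) -> None:
    """Write series to a long-format CSV (full float precision)."""
    # %.17g guarantees binary round-trip of float64 valence values
    dyads_to_frame(dyads).to_csv(path, index=False, float_format="%.17g")


def _repair_gaps(t: np.ndarray, v: np.ndarray, n_expected: int | None):
    """Forward-fill missing seconds up to MAX_FFILL_GAP; None if impossible."""
    t = t.astype(int)
    full = np.arange(t.max() + 1 if n_expected is None else n_expected)
    s = pd.Series(v, index=t).reindex(full)
    gap = s.isna()
    if not gap.any():
        return s.to_numpy()
    # longest run of consecutive NaNs
    runs = gap.astype(int).groupby((~gap).cumsum()).sum()
    if runs.max() > MAX_FFILL_GAP or gap.iloc[0]:
        return None
    return s.ffill().to_numpy()


def read_dyads(
    path: str | Path, sample_rate: float = 1.0
) -> tuple[list[DyadSeries], ValidationReport]:
    """Read a long-format CSV into DyadSeries, validating structure.

    Structural faults (missing partner, ragged lengths, duplicated
    timestamps, out-of-range valence, unrepairable gaps) drop the
    offending couple-context with a logged reason; they never raise.

    Returns the retained series and a :class:`ValidationReport`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series file lacks columns: {sorted(missing)}")
    report = ValidationReport(n_rows=len(df))
    out: list[DyadSeries] = []
    for (cid, ctx), grp in df.groupby(["couple_id", "context"], sort=True):
        partners = {}
        ok = True
        for p in ("A", "B"):
            sub = grp[grp["partner"] == p].sort_values("t")
            if sub.empty:
                report.drop(cid, ctx, f"missing partner {p}")
                ok = False
                break
            if sub["t"].duplicated().any():
                report.drop(cid, ctx, f"duplicated timestamps for partner {p}")
                ok = False
                break
            v = sub["valence"].to_numpy(dtype=float)
            if np.nanmax(np.abs(v)) > 1.0 + 1e-9:
                report.drop(cid, ctx, f"valence outside [-1,+1] for partner {p}")
                ok = False
                break
            partners[p] = (sub["t"].to_numpy(), v)
        if not ok:
            continue
        if partners["A"][0].max() != partners["B"][0].max():
            report.drop(cid, ctx, "ragged lengths")
            continue
        n = max(partners["A"][0].max(), partners["B"][0].max()) + 1
        series = {}
        for p, (t, v) in partners.items():
            repaired = _repair_gaps(t, v, int(n))
            if repaired is None or np.isnan(repaired).any():
                report.drop(cid, ctx, f"gap > {MAX_FFILL_GAP}s for partner {p}")
                ok = False
                break
            series[p] = repaired
        if not ok:
            continue
        if series["A"].size != series["B"].size:
            report.drop(cid, ctx, "ragged lengths")
            continue
        try:
            out.append(
                DyadSeries(
                    couple_id=str(cid),
                    context=str(ctx),
                    series_a=series["A"],
                    series_b=series["B"],
                    sample_rate=sample_rate,
                )
            )
        except ValueError as exc:
            report.drop(cid, ctx, str(exc))
    report.n_series = len(out)
    return out, report


def write_labels(labels: Iterable[CoupleLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "couple_id": l.couple_id,
                "separated": int(l.separated),
                "excluded": int(l.excluded),
                "exclusion_reason": l.exclusion_reason,
            }
            for l in labels
        ],
        columns=LABEL_COLUMNS,
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[CoupleLabel]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label file lacks columns: {sorted(missing)}")
    return [
        CoupleLabel(
            couple_id=str(r.couple_id),
            separated=bool(int(r.separated)),
            excluded=bool(int(r.excluded)),
            exclusion_reason=str(r.exclusion_reason),
        )
        for r in df.itertuples()
    ]


def apply_exclusions(
    labels: Sequence[CoupleLabel],
) -> tuple[list[CoupleLabel], dict]:
    """Remove excluded couples and account for the retained sample.

    Returns the retained labels plus a summary dict with the input,
    excluded and retained counts and the retained separation prevalence.
    """
    retained = [l for l in labels if not l.excluded]
    n_pos = sum(l.separated for l in retained)
    summary = {
        "n_input": len(labels),
        "n_excluded": len(labels) - len(retained),
        "n_retained": len(retained),
        "n_separated": n_pos,
        "prevalence": (n_pos / len(retained)) if retained else float("nan"),
        "exclusion_reasons": sorted(
            {l.exclusion_reason for l in labels if l.excluded}
        ),
    }
    if not retained:
        logger.warning("all couples excluded; empty retained set")
    return retained, summary


def relabel(label: CoupleLabel, **changes) -> CoupleLabel:
    """Convenience wrapper around dataclasses.replace."""
    return replace(label, **changes)
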