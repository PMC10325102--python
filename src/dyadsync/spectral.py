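"""Cross-power spectral density features for dyadic valence series.

The coupling construct — two partners' emotions fluctuating at shared
rates — is operationalized as the cross-power spectral density (CPSD) of
the two per-second valence series.  A peak in |CPSD| at frequency *f*
means both partners carry fluctuation energy at rate *f*, regardless of
the lag between them: the cross-spectrum accounts for all lags at once.

The estimator is a single full-length cross-periodogram (boxcar window,
constant detrend, no zero padding, one-sided with the usual doubling of
interior bins).  A T-sample series therefore yields floor(T/2)+1
frequency bins — 301 for a 10-minute series at 1 Hz — and no averaging
across segments discards information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .io import DyadSeries

#: Sub-band partition of the 0–30 cycles-per-minute range (at 1 Hz
#: sampling the Nyquist rate is 30 cpm): six equal 5-cpm bands.
DEFAULT_BANDS_CPM: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),
    (5.0, 10.0),
    (10.0, 15.0),
    (15.0, 20.0),
    (20.0, 25.0),
    (25.0, 30.0),
)

#: Floor added inside log10 so zero-magnitude bins stay finite.
LOG_EPS = 1e-12


@dataclass(frozen=True)
class SpectralFeature:
    """Per-couple CPSD plus each partner's raw mean and variance."""

    couple_id: str
    context: str
    freqs: np.ndarray  # Hz, ascending, freqs[0]=0, freqs[-1]=Nyquist
    cpsd: np.ndarray  # complex, valence^2/Hz, len == len(freqs)
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.cpsd):
            raise ValueError("freqs and cpsd lengths differ")

    @property
    def n_bins(self) -> int:
        return int(len(self.freqs))


def cross_spectral_density(
    series_a: np.ndarray,
    series_b: np.ndarray,
    sample_rate: float = 1.0,
    window: str = "boxcar",
    detrend: str = "constant",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided cross-periodogram of two equal-length series.

    Computed on one full-length segment so the T time samples map to
    exactly ``floor(T/2)+1`` frequency bins spanning 0..Nyquist.
    Returns ``(freqs, cpsd)`` with complex ``cpsd`` in density scaling
    (units valence²/Hz); ``cpsd(x, x)`` is the real, nonnegative
    periodogram of ``x`` whose integral over frequency equals the
    variance of the detrended series.

    Raises ``ValueError`` on unequal lengths, fewer than 4 samples, or
    non-finite values.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be one-dimensional and equal-length")
    if a.size < 4:
        raise ValueError("series must contain at least 4 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain non-finite values")
    freqs, pxy = signal.csd(
        a,
        b,
        fs=sample_rate,
        window=window,
        nperseg=a.size,
        noverlap=0,
        detrend=detrend,
        scaling="density",
        return_onesided=True,
    )
    return freqs, pxy


def extract_features(dyad: DyadSeries) -> SpectralFeature:
    """CPSD of the dyad plus per-partner raw means and variances.

    Means and variances are computed on the raw (pre-detrend) series
    with the population denominator *n*.
    """
    freqs, cpsd = cross_spectral_density(
        dyad.series_a, dyad.series_b, dyad.sample_rate
    )
    return SpectralFeature(
        couple_id=dyad.couple_id,
        context=dyad.context,
        freqs=freqs,
        cpsd=cpsd,
        mean_a=float(np.mean(dyad.series_a)),
        mean_b=float(np.mean(dyad.series_b)),
        var_a=float(np.var(dyad.series_a)),
        var_b=float(np.var(dyad.series_b)),
    )


def feature_vector(sf: SpectralFeature, include_phase: bool = False) -> np.ndarray:
    """Classifier input: spectral bins followed by the four moment features.

    By default the magnitude of the complex CPSD is used (F + 4 values);
    with ``include_phase`` the real and imaginary parts are concatenated
    instead (2F + 4 values), preserving phase/lag information.
    """
    if include_phase:
        spec = np.concatenate([np.real(sf.cpsd), np.imag(sf.cpsd)])
    else:
        spec = np.abs(sf.cpsd)
    vec = np.concatenate(
        [spec, [sf.mean_a, sf.mean_b, sf.var_a, sf.var_b]]
    )
    if not np.isfinite(vec).all():
        raise ValueError("non-finite entries in feature vector")
    return vec


def feature_matrix(
    features: Sequence[SpectralFeature],
    labels: dict[str, bool],
    include_phase: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack feature vectors into (X, y, couple_ids), label-aligned."""
    ids = [sf.couple_id for sf in features]
    X = np.vstack([feature_vector(sf, include_phase) for sf in features])
    y = np.array([bool(labels[cid]) for cid in ids])
    return X, y, ids


def subband_log_magnitude(
    sf: SpectralFeature,
    bands_cpm: Sequence[tuple[float, float]] = DEFAULT_BANDS_CPM,
) -> np.ndarray:
    """Mean log10 |CPSD| within each frequency sub-band.

    Bands are given in cycles per minute (cpm = 60 × Hz) and must be
    ascending and non-overlapping within [0, Nyquist·60].  Bins are
    assigned half-open (``low <= 60 f < high``) except that the last
    band includes its upper edge so a partition ending at the Nyquist
    rate covers every bin.
    """
    nyq_cpm = 60.0 * float(sf.freqs[-1])
    prev_high = -np.inf
    for low, high in bands_cpm:
        if not (0.0 <= low < high <= nyq_cpm + 1e-9):
            raise ValueError(
                f"band ({low}, {high}) cpm outside representable range "
                f"[0, {nyq_cpm}]"
            )
        if low < prev_high:
            raise ValueError("bands must be ascending and non-overlapping")
        prev_high = high
    cpm = 60.0 * sf.freqs
    logmag = np.log10(np.abs(sf.cpsd) + LOG_EPS)
    out = np.empty(len(bands_cpm))
    for i, (low, high) in enumerate(bands_cpm):
        if i == len(bands_cpm) - 1:
            mask = (cpm >= low) & (cpm <= high + 1e-9)
        else:
            mask = (cpm >= low) & (cpm < high)
        if not mask.any():
            raise ValueError(f"band ({low}, {high}) cpm contains no bins")
        out[i] = logmag[mask].mean()
    return out
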