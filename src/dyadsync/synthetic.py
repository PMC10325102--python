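"""Synthetic cohorts of coupled dyadic valence series.

The generator emulates the structure the analysis assumes: per couple
and interaction context, two bounded 1 Hz valence series that share a
band-limited fluctuation component whose strength (the *coupling*)
differs between couples that later separate and couples that stay
together, plus per-person baseline (mean) and amplitude (variability)
differences and a rare positive outcome (~17% separation prevalence).

Each partner's series is

    y_i(t) = mu_i + sigma_i * ( sqrt(c) * s(t) + sqrt(1-c) * e_i(t) )

hard-clipped to [-1, +1], where ``s(t)`` is one shared band-limited
signal (unit variance, shared by both partners), ``e_i(t)`` are
independent unit-variance AR(1) noise streams, and ``c`` is the
shared-variance fraction.  A coupling of ``c`` produces an expected
lag-0 cross-correlation of ``c`` between partners.

The shared signal is a sum of sinusoids at the Fourier frequencies of
the series, with independent uniform phases and amplitudes shaped as
the AR(1) noise spectrum *capped* above a knee frequency (plus extra
weight below 5 cpm), restricted to ``shared_band``.  The cap matters:
because a single-segment cross-periodogram magnitude factorizes into
the two partners' marginal spectral magnitudes, the spectral *shape*
contrast between shared and individual components is the only channel
through which coupling reaches |CPSD|.  Capping reallocates shared
power away from the noise-dominated lowest frequencies so the
shared-to-noise density ratio exceeds one across the whole band, which
(i) gives strongly coupled couples higher expected log |CPSD| in every
sub-band and (ii) leaves a spectral signature that survives
per-partner standardization — the two regularities the downstream
analysis is designed to detect.

Separation labels are drawn from a logistic link on each couple's
coupling (couples coupled like the separated-group target are most at
risk), with the intercept calibrated so the expected prevalence matches
the configured separation rate; labels are therefore noisy rather than
deterministic functions of coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io import CoupleLabel, DyadSeries

logger = logging.getLogger(__name__)

_MAX_COHORT_ATTEMPTS = 10


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the coupled-dyad cohort generator.

    Defaults emulate the target study design: 98 couples, two partners,
    two interaction contexts, 600 samples at 1 Hz, ~17.3% separation
    prevalence, with separated couples more weakly coupled than couples
    who stay together.
    """

    n_couples: int = 98
    series_length: int = 600
    sample_rate: float = 1.0  # Hz
    coupling_stay: float = 0.8  # shared-variance fraction, stay-together
    coupling_sep: float = 0.1  # shared-variance fraction, separated
    shared_band: tuple[float, float] = (0.1, 30.0)  # cycles per minute
    mean_range: tuple[float, float] = (-0.2, 0.6)  # per-person baseline
    sd_range: tuple[float, float] = (0.1, 0.35)  # per-person amplitude
    ar_coefficient: float = 0.85  # persistence of individual noise
    separation_rate: float = 17 / 98  # target label prevalence
    contexts: tuple[str, ...] = ("positive", "conflict")
    seed: int = 0
    # secondary knobs
    coupling_jitter: float = 0.03  # SD of per-couple coupling around its group target
    label_steepness: float = 6.0  # logit range across the coupling gap
    mean_shift_sep: float = 0.0  # baseline shift for separation-prone couples
    sd_scale_sep: float = 1.0  # amplitude scale for separation-prone couples
    shared_knee_cpm: float = 4.0  # cap the shared spectrum above this rate
    shared_lowband_boost: float = 1.0  # extra shared weight below 5 cpm
    clip: bool = True  # hard-clip output to [-1, +1]

    def __post_init__(self) -> None:
        if self.n_couples < 1:
            raise ValueError("n_couples must be positive")
        if self.series_length < 4:
            raise ValueError("series_length must be >= 4")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("coupling_stay", "coupling_sep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.separation_rate < 1.0:
            raise ValueError("separation_rate must lie in (0, 1)")
        nyq_cpm = self.sample_rate * 60.0 / 2.0
        low, high = self.shared_band
        if not (0.0 < low < high <= nyq_cpm + 1e-9):
            raise ValueError(
                f"shared_band must lie within (0, {nyq_cpm}] cycles per minute"
            )
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if not self.contexts:
            raise ValueError("at least one context required")


@dataclass
class Cohort:
    """A generated cohort: per-context dyads, labels, and provenance."""

    dyads: dict[str, list[DyadSeries]]  # context -> per-couple series
    labels: list[CoupleLabel]
    coupling: np.ndarray  # realized per-couple coupling fractions
    groups: np.ndarray  # latent separation-prone indicator (bool)
    config: GeneratorConfig

    @property
    def couple_ids(self) -> list[str]:
        return [l.couple_id for l in self.labels]

    @property
    def n_values(self) -> int:
        """Total valence samples: couples × 2 partners × contexts × T."""
        return sum(2 * d.n_samples for ds in self.dyads.values() for d in ds)

    def label_map(self) -> dict[str, bool]:
        return {l.couple_id: l.separated for l in self.labels}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        raise RuntimeError("degenerate zero-variance component")
    return (x - x.mean()) / sd


def _ar1_density(freqs: np.ndarray, sample_rate: float, phi: float) -> np.ndarray:
    """Unit-variance AR(1) spectral density on the given frequency grid."""
    w = 2.0 * np.pi * freqs / sample_rate
    return (1.0 - phi**2) / (1.0 + phi**2 - 2.0 * phi * np.cos(w))


def shared_spectrum(config: GeneratorConfig, freqs: np.ndarray) -> np.ndarray:
    """Target spectral weights of the shared component (unnormalized).

    AR(1) noise shape capped at its value at ``shared_knee_cpm``, with
    ``shared_lowband_boost`` extra weight below 5 cpm, zero outside
    ``shared_band`` and at DC.
    """
    cpm = 60.0 * freqs
    dens = _ar1_density(freqs, config.sample_rate, config.ar_coefficient)
    kappa = _ar1_density(
        np.array([config.shared_knee_cpm / 60.0]),
        config.sample_rate,
        config.ar_coefficient,
    )[0]
    spec = np.minimum(dens, kappa) * (1.0 + config.shared_lowband_boost * (cpm < 5.0))
    low, high = config.shared_band
    spec[(cpm < low) | (cpm > high)] = 0.0
    spec[0] = 0.0
    if not spec.any():
        raise ValueError("shared_band leaves no representable frequencies")
    return spec


def _shared_signal(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited signal: Fourier-frequency sinusoids.

    Deterministic amplitudes from :func:`shared_spectrum`, independent
    uniform phases (classic random-phase synthesis via the inverse FFT).
    """
    T = config.series_length
    freqs = np.fft.rfftfreq(T, d=1.0 / config.sample_rate)
    amp = np.sqrt(shared_spectrum(config, freqs))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    coeffs = amp * np.exp(1j * phases)
    coeffs[0] = 0.0
    if T % 2 == 0:
        coeffs[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    return _standardize(np.fft.irfft(coeffs, n=T))


def _ar1_noise(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) stream (100-sample burn-in)."""
    phi = config.ar_coefficient
    n = config.series_length + 100
    w = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = w[0] / np.sqrt(1.0 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + w[i]
    return _standardize(x[100:])


def generate_dyad(
    config: GeneratorConfig,
    coupling: float,
    rng: np.random.Generator,
    couple_id: str = "couple_000",
    context: str | None = None,
    mean_shift: float = 0.0,
    sd_scale: float = 1.0,
) -> DyadSeries:
    """One couple's paired series at the given shared-variance fraction.

    Both partners mix the same shared signal with independent AR(1)
    noise; per-person baselines and amplitudes are drawn from the
    configured ranges (optionally shifted/scaled for separation-prone
    couples).  Output is hard-clipped to [-1, +1] unless ``config.clip``
    is disabled.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    s = _shared_signal(config, rng)
    series = []
    for _ in range(2):
        e = _ar1_noise(config, rng)
        mu = rng.uniform(*config.mean_range) + mean_shift
        sigma = rng.uniform(*config.sd_range) * sd_scale
        y = mu + sigma * (np.sqrt(coupling) * s + np.sqrt(1.0 - coupling) * e)
        if config.clip:
            y = np.clip(y, -1.0, 1.0)
        series.append(y)
    return DyadSeries(
        couple_id=couple_id,
        context=context if context is not None else config.contexts[0],
        series_a=series[0],
        series_b=series[1],
        sample_rate=config.sample_rate,
        bounded=config.clip,
    )


def draw_couple_assignments(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent groups, per-couple couplings, and separation labels.

    Couples are first assigned a latent separation-prone group with
    probability ``separation_rate``; their coupling is drawn near the
    group's target (``coupling_sep`` vs ``coupling_stay``).  The label
    is then a Bernoulli draw from a logistic link on the coupling's
    normalized distance below the stay-together target, with intercept
    calibrated so the cohort's expected prevalence equals
    ``separation_rate``.  With equal group targets the coupling carries
    no label information and the propensity falls back to the latent
    group itself, so mean- or variance-only effect cohorts remain
    constructible.
    """
    n = config.n_couples
    groups = rng.random(n) < config.separation_rate
    target = np.where(groups, config.coupling_sep, config.coupling_stay)
    coupling = np.clip(
        target + rng.normal(0.0, config.coupling_jitter, size=n), 0.0, 1.0
    )
    gap = config.coupling_stay - config.coupling_sep
    if abs(gap) > 1e-9:
        # 1 at the separated-group target, 0 at the stay-together target
        risk = (config.coupling_stay - coupling) / gap
    else:
        risk = groups.astype(float)
    steep = config.label_steepness

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + steep * (risk - 0.5)))) - config.separation_rate

    b0 = brentq(excess, -60.0, 60.0)
    labels = rng.random(n) < expit(b0 + steep * (risk - 0.5))
    return groups, coupling, labels


def generate_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> Cohort:
    """A full cohort: one DyadSeries per couple and context, plus labels.

    Labels are context-independent.  A degenerate draw (zero or all
    positive labels) is regenerated from the next substream, up to 10
    attempts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for attempt in range(_MAX_COHORT_ATTEMPTS):
        groups, coupling, labels = draw_couple_assignments(config, rng)
        n_pos = int(labels.sum())
        if 0 < n_pos < config.n_couples:
            break
        logger.warning(
            "degenerate label draw (%d/%d positives), attempt %d; redrawing",
            n_pos,
            config.n_couples,
            attempt + 1,
        )
    else:
        raise RuntimeError(
            f"no non-degenerate label draw in {_MAX_COHORT_ATTEMPTS} attempts"
        )
    width = max(3, len(str(config.n_couples - 1)))
    ids = [f"couple_{i:0{width}d}" for i in range(config.n_couples)]
    dyads: dict[str, list[DyadSeries]] = {}
    for context in config.contexts:
        dyads[context] = [
            generate_dyad(
                config,
                float(coupling[i]),
                rng,
                couple_id=ids[i],
                context=context,
                mean_shift=config.mean_shift_sep if groups[i] else 0.0,
                sd_scale=config.sd_scale_sep if groups[i] else 1.0,
            )
            for i in range(config.n_couples)
        ]
    couple_labels = [
        CoupleLabel(couple_id=ids[i], separated=bool(labels[i]))
        for i in range(config.n_couples)
    ]
    return Cohort(
        dyads=dyads,
        labels=couple_labels,
        coupling=coupling,
        groups=groups,
        config=config,
    )


def null_config(base: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A no-signal configuration: equal couplings, no mean/SD effects.

    Labels are then independent of every observable feature — useful for
    type-I-error checks of the attribution logic.
    """
    base = base or GeneratorConfig()
    mid = 0.5 * (base.coupling_stay + base.coupling_sep)
    cfg = replace(
        base,
        coupling_stay=mid,
        coupling_sep=mid,
        mean_shift_sep=0.0,
        sd_scale_sep=1.0,
    )
    return replace(cfg, **overrides) if overrides else cfg
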