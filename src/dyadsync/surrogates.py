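"""Information-removal surrogate transforms of dyadic series.

Each surrogate removes one kind of information from the raw series
before spectral features are derived, so that the drop in downstream
classification performance attributes predictive value to what was
removed:

- ``a``  mean-centering: removes each person's average emotion level;
- ``b``  standardization: additionally removes each person's variability
  (divide by the standard deviation);
- ``c``  time randomization: an independent permutation of each
  partner's series, destroying all auto- and cross-correlation — hence
  the couple's temporal coupling — while preserving the value
  distribution (mean and variance unchanged);
- ``a+c`` and ``b+c`` combine them.

Together with the untransformed original that yields six variants, five
of which are surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import DyadSeries

logger = logging.getLogger(__name__)

VARIANT_ORDER = ("original", "a", "b", "c", "a+c", "b+c")


def _variant_id(mean_center: bool, standardize: bool, time_permute: bool) -> str:
    if standardize:
        base = "b"
    elif mean_center:
        base = "a"
    else:
        base = ""
    if time_permute:
        return f"{base}+c" if base else "c"
    return base or "original"


@dataclass(frozen=True)
class SurrogateSpec:
    """Which information-removal transforms to apply, and in what name.

    ``standardize`` subsumes ``mean_center`` (a standardized series is
    centered by construction); only the six enumerated flag combinations
    are valid.
    """

    mean_center: bool
    standardize: bool
    time_permute: bool
    variant_id: str

    def __post_init__(self) -> None:
        if self.standardize and not self.mean_center:
            raise ValueError("standardize implies mean_center")
        expected = _variant_id(self.mean_center, self.standardize, self.time_permute)
        if self.variant_id != expected:
            raise ValueError(
                f"variant_id {self.variant_id!r} inconsistent with flags "
                f"(expected {expected!r})"
            )

    @classmethod
    def from_variant_id(cls, variant_id: str) -> "SurrogateSpec":
        if variant_id not in VARIANT_ORDER:
            raise ValueError(
                f"unknown variant {variant_id!r}; one of {VARIANT_ORDER}"
            )
        std = variant_id.startswith("b")
        center = std or variant_id.startswith("a")
        permute = variant_id.endswith("c")
        return cls(center, std, permute, variant_id)

    @property
    def is_surrogate(self) -> bool:
        return self.variant_id != "original"


def enumerate_variants() -> list[SurrogateSpec]:
    """The original plus the five surrogates, in fixed reporting order."""
    return [SurrogateSpec.from_variant_id(v) for v in VARIANT_ORDER]


def _transform_one(
    x: np.ndarray,
    spec: SurrogateSpec,
    rng: np.random.Generator,
    divide_by_variance: bool,
) -> np.ndarray:
    x = x.astype(np.float64, copy=True)
    if spec.mean_center:
        x -= x.mean()
    if spec.standardize:
        scale = x.var() if divide_by_variance else x.std()
        if scale == 0.0:
            logger.warning("zero-variance series: standardized surrogate set to zeros")
            x[:] = 0.0
        else:
            x /= scale
    if spec.time_permute:
        x = rng.permutation(x)
    return x


def apply_surrogate(
    dyad: DyadSeries,
    spec: SurrogateSpec,
    rng: np.random.Generator | None = None,
    divide_by_variance: bool = False,
) -> DyadSeries:
    """Apply the surrogate transforms per partner, independently.

    Order is center → scale → permute; partner A's and partner B's
    permutations are drawn independently from ``rng``.  Transformed
    output is no longer constrained to [-1, +1] (``bounded`` is False).

    ``divide_by_variance`` switches the scaling step from the
    conventional divide-by-SD to a literal divide-by-variance.
    """
    if spec.time_permute and rng is None:
        raise ValueError("time_permute requires a random generator")
    if rng is None:
        rng = np.random.default_rng(0)  # unused by deterministic variants
    a = _transform_one(dyad.series_a, spec, rng, divide_by_variance)
    b = _transform_one(dyad.series_b, spec, rng, divide_by_variance)
    bounded = dyad.bounded and not (spec.mean_center or spec.standardize)
    return DyadSeries(
        couple_id=dyad.couple_id,
        context=dyad.context,
        series_a=a,
        series_b=b,
        sample_rate=dyad.sample_rate,
        bounded=bounded,
    )
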