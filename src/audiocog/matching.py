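"""Auditory working-memory matching task and its precision statistic.

A trial presents a target drawn uniformly from the feature's stimulus range —
pure-tone frequency (440–880 Hz) or sinusoidal amplitude-modulation rate
(5–20 Hz) — and the participant reproduces it on a horizontal slider.  The
slider spans the stimulus range plus 10% padding at either end; both the
target and the response therefore live on a normalized [0, 1] scale
coordinate, and the per-trial error is ``response - target`` in scale units.

A block interleaves 16 frequency and 16 AM-rate trials (32 scored trials,
with a break after 16) preceded by 2 excluded practice trials per feature.

Memory precision is the inverse of the standard deviation of a Gaussian
fitted to the per-feature errors by maximum likelihood (the mean is left free
so a constant response bias is absorbed by the location parameter, not the
scale).  Downstream analysis uses the natural log of precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSampleError, InsufficientDataError, InvalidParameterError

__all__ = [
    "MatchingConfig",
    "MatchingListener",
    "MatchingResult",
    "PrecisionEstimate",
    "map_param_to_scale",
    "map_scale_to_param",
    "simulate_matching_block",
    "estimate_precision",
]


@dataclass(frozen=True)
class MatchingConfig:
    """Design of one matching block (defaults are the instrument's published values)."""

    n_trials: int = 32
    freq_range: tuple = (440.0, 880.0)
    am_range: tuple = (5.0, 20.0)
    scale_padding: float = 0.10
    break_after: int = 16
    practice_per_feature: int = 2

    def __post_init__(self) -> None:
        for low, high in (self.freq_range, self.am_range):
            if not (0 < low < high):
                raise InvalidParameterError(
                    f"ranges must be positive with low < high, got ({low}, {high})"
                )
        if self.scale_padding < 0:
            raise InvalidParameterError("scale_padding must be >= 0")
        if self.n_trials < 2 or self.n_trials % 2:
            raise InvalidParameterError("n_trials must be even and >= 2 (interleaved design)")

    def feature_range(self, feature: str) -> tuple:
        if feature == "F":
            return self.freq_range
        if feature == "A":
            return self.am_range
        raise InvalidParameterError(f"unknown feature {feature!r} (expected 'F' or 'A')")


@dataclass(frozen=True)
class MatchingListener:
    """Response model for the matching task.

    ``sigma_f`` / ``sigma_a`` are the SDs of zero-mean Gaussian response noise
    on the normalized scale for the frequency and AM-rate features; ``bias``
    is a constant shift added to every response.  Zero sigmas are allowed
    (noiseless responder); negative sigmas are invalid.
    """

    sigma_f: float
    sigma_a: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_f < 0 or self.sigma_a < 0:
            raise InvalidParameterError(
                f"sigmas must be >= 0, got ({self.sigma_f}, {self.sigma_a})"
            )

    def sigma(self, feature: str) -> float:
        return self.sigma_f if feature == "F" else self.sigma_a


@dataclass(frozen=True)
class PrecisionEstimate:
    """Gaussian-ML fit of an error sample: scale SD, precision = 1/SD, log precision."""

    sd: float
    precision: float
    log_precision: float


@dataclass
class MatchingResult:
    """Per-trial record of one block plus the per-feature precision estimates.

    ``precision_f`` / ``precision_a`` are ``None`` when the error sample for
    that feature was degenerate (e.g. a noiseless responder).
    """

    features: list = field(default_factory=list)
    targets_scale: list = field(default_factory=list)
    responses_scale: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    practice_features: list = field(default_factory=list)
    practice_errors: list = field(default_factory=list)
    precision_f: PrecisionEstimate | None = None
    precision_a: PrecisionEstimate | None = None

    def feature_errors(self, feature: str) -> np.ndarray:
        mask = np.asarray(self.features) == feature
        return np.asarray(self.errors, dtype=float)[mask]


def _padded_interval(value_range: tuple, padding: float) -> tuple:
    low, high = value_range
    span = high - low
    return low - padding * span, span * (1.0 + 2.0 * padding)


def map_param_to_scale(value: float, value_range: tuple, padding: float = 0.10) -> float:
    """Affine map from the padded stimulus range onto the [0, 1] slider coordinate."""
    low, high = value_range
    if not low < high:
        raise InvalidParameterError(f"range must have low < high, got ({low}, {high})")
    if padding < 0:
        raise InvalidParameterError("padding must be >= 0")
    lo_pad, width = _padded_interval(value_range, padding)
    scale = (value - lo_pad) / width
    if not -1e-12 <= scale <= 1.0 + 1e-12:
        raise InvalidParameterError(
            f"value {value} outside padded range [{lo_pad}, {lo_pad + width}]"
        )
    return float(min(max(scale, 0.0), 1.0))


def map_scale_to_param(scale: float, value_range: tuple, padding: float = 0.10) -> float:
    """Inverse of :func:`map_param_to_scale`."""
    low, high = value_range
    if not low < high:
        raise InvalidParameterError(f"range must have low < high, got ({low}, {high})")
    if padding < 0:
        raise InvalidParameterError("padding must be >= 0")
    if not -1e-12 <= scale <= 1.0 + 1e-12:
        raise InvalidParameterError(f"scale coordinate {scale} outside [0, 1]")
    lo_pad, width = _padded_interval(value_range, padding)
    return float(lo_pad + scale * width)


def estimate_precision(errors, fix_mean_zero: bool = False) -> PrecisionEstimate:
    """Fit a Gaussian to an error sample and return the precision (1/SD).

    Maximum-likelihood fit: the location is the sample mean (free, absorbing
    response bias) unless ``fix_mean_zero``; the scale is the ML standard
    deviation (1/n divisor).  Note that 1/SD_hat is biased upward in small
    samples (by ~7% in median at n=16 for a true Gaussian); the simulator's
    cohort calibration accounts for this.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 errors.
    DegenerateSampleError
        All errors identical (zero scale; precision undefined, not infinite).
    """
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise InsufficientDataError(f"need >= 2 errors, got {e.size}")
    mu = 0.0 if fix_mean_zero else float(np.mean(e))
    sd = float(np.sqrt(np.mean((e - mu) ** 2)))
    if sd == 0.0:
        raise DegenerateSampleError("all errors identical; precision undefined")
    return PrecisionEstimate(sd=sd, precision=1.0 / sd, log_precision=float(-np.log(sd)))


def simulate_matching_block(
    listener: MatchingListener, config: MatchingConfig | None = None, rng=None
) -> MatchingResult:
    """Simulate one interleaved matching block against a virtual responder.

    Targets are drawn uniformly over the *unpadded* stimulus range and mapped
    to the slider scale; the response is the target scale coordinate plus the
    listener's bias and Gaussian noise, clipped to [0, 1] (the slider cannot
    leave the screen).  Practice trials (2 per feature) are simulated first
    and excluded from the error sample.
    """
    if config is None:
        config = MatchingConfig()
    if rng is None:
        raise InvalidParameterError("simulate_matching_block requires a seeded rng")

    result = MatchingResult()

    def one_trial(feature: str) -> tuple:
        low, high = config.feature_range(feature)
        target = rng.uniform(low, high)
        t_scale = map_param_to_scale(target, (low, high), config.scale_padding)
        noise = rng.normal(0.0, listener.sigma(feature)) if listener.sigma(feature) > 0 else 0.0
        r_scale = float(np.clip(t_scale + listener.bias + noise, 0.0, 1.0))
        return t_scale, r_scale

    for feature in ("F", "A"):
        for _ in range(config.practice_per_feature):
            t_scale, r_scale = one_trial(feature)
            result.practice_features.append(feature)
            result.practice_errors.append(r_scale - t_scale)

    half = config.n_trials // 2
    order = ["F", "A"] * half  # strict interleaving, frequency first
    for feature in order:
        t_scale, r_scale = one_trial(feature)
        result.features.append(feature)
        result.targets_scale.append(t_scale)
        result.responses_scale.append(r_scale)
        result.errors.append(r_scale - t_scale)

    for feature, attr in (("F", "precision_f"), ("A", "precision_a")):
        try:
            est = estimate_precision(result.feature_errors(feature))
        except DegenerateSampleError:
            est = None
        setattr(result, attr, est)
    return result
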