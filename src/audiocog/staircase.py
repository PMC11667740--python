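"""Adaptive 1-up/1-down staircase for speech-in-noise thresholds.

Implements the adaptive track used by both speech-in-noise instruments
(digits-in-noise, DIN, and speech-in-babble, SIB): starting SNR 0 dB, step
size 5 dB reduced to 2 dB after the 3rd reversal and to 0.5 dB after the 6th,
termination after 10 reversals, threshold = mean SNR of the last 5 reversals.
Lower thresholds indicate better performance.

Conventions (fixed so that deterministic runs are enumerable):

* the first trial's response defines the initial direction of movement and is
  never a reversal;
* a reversal is logged at the SNR of the trial whose response flips the
  direction of movement;
* the reduced step size takes effect for the first movement *after* the 3rd
  (respectively 6th) reversal has been logged.

Two practice trials at +10 dB SNR are simulated before the track and excluded
from all scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, ThresholdUndefinedError

__all__ = ["StaircaseConfig", "StaircaseTrack", "simulate_staircase", "staircase_threshold"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive track.

    Defaults are the instrument's published operating parameters; ``max_trials``
    is a safety cap for degenerate listeners (a perfect or chance performer
    never produces 10 reversals).
    """

    start_snr: float = 0.0
    practice_snr: float = 10.0
    practice_trials: int = 2
    initial_step: float = 5.0
    mid_step: float = 2.0
    final_step: float = 0.5
    mid_after_reversals: int = 3
    final_after_reversals: int = 6
    stop_reversals: int = 10
    threshold_last_k: int = 5
    max_trials: int = 150

    def __post_init__(self) -> None:
        if not (self.initial_step > self.mid_step > self.final_step > 0):
            raise InvalidParameterError(
                "step sizes must strictly decrease and be positive: "
                f"{self.initial_step}, {self.mid_step}, {self.final_step}"
            )
        if not (0 < self.mid_after_reversals < self.final_after_reversals < self.stop_reversals):
            raise InvalidParameterError("reversal schedule must be increasing")
        if self.stop_reversals < self.threshold_last_k:
            raise InvalidParameterError(
                "stop_reversals must be >= threshold_last_k "
                f"({self.stop_reversals} < {self.threshold_last_k})"
            )
        if self.max_trials < 1 or self.practice_trials < 0:
            raise InvalidParameterError("max_trials >= 1 and practice_trials >= 0 required")

    def step_in_force(self, n_reversals: int) -> float:
        """Step size used for the movement after ``n_reversals`` have been logged."""
        if n_reversals < self.mid_after_reversals:
            return self.initial_step
        if n_reversals < self.final_after_reversals:
            return self.mid_step
        return self.final_step


@dataclass
class StaircaseTrack:
    """Result of one adaptive run.

    ``threshold`` is the mean SNR of the final ``threshold_last_k`` reversals,
    or ``None`` when the run hit ``max_trials`` before the required number of
    reversals (``converged`` is then False).
    """

    trial_snrs: list = field(default_factory=list)
    responses: list = field(default_factory=list)
    reversal_snrs: list = field(default_factory=list)
    practice_snrs: list = field(default_factory=list)
    practice_responses: list = field(default_factory=list)
    threshold: float | None = None
    converged: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trial_snrs)


def simulate_staircase(listener, config: StaircaseConfig | None = None, rng=None) -> StaircaseTrack:
    """Run a 1-up/1-down adaptive track against a virtual listener.

    Parameters
    ----------
    listener
        Any object with a ``p_correct(snr) -> float`` method.
    config
        Track parameters; defaults to :class:`StaircaseConfig`.
    rng
        A seeded :class:`numpy.random.Generator`.  Required: every trial draws
        one uniform variate, including deterministic listeners, so that the
        stream layout does not depend on listener type.
    """
    if config is None:
        config = StaircaseConfig()
    if rng is None:
        raise InvalidParameterError("simulate_staircase requires a seeded rng")

    track = StaircaseTrack()

    for _ in range(config.practice_trials):
        p = listener.p_correct(config.practice_snr)
        track.practice_snrs.append(config.practice_snr)
        track.practice_responses.append(bool(rng.random() < p))

    snr = config.start_snr
    prev_direction = 0  # -1 down (after correct), +1 up (after incorrect)
    while len(track.reversal_snrs) < config.stop_reversals and track.n_trials < config.max_trials:
        correct = bool(rng.random() < listener.p_correct(snr))
        track.trial_snrs.append(snr)
        track.responses.append(correct)
        direction = -1 if correct else 1
        if prev_direction != 0 and direction != prev_direction:
            track.reversal_snrs.append(snr)
        prev_direction = direction
        snr += direction * config.step_in_force(len(track.reversal_snrs))

    track.converged = len(track.reversal_snrs) >= config.stop_reversals
    if track.converged:
        track.threshold = float(
            np.mean(track.reversal_snrs[-config.threshold_last_k:])
        )
    return track


def staircase_threshold(track: StaircaseTrack, config: StaircaseConfig | None = None) -> float:
    """Threshold of a converged track: mean of its last ``threshold_last_k`` reversal SNRs.

    Raises
    ------
    ThresholdUndefinedError
        If the track did not converge (fewer reversals than required).
    """
    if config is None:
        config = StaircaseConfig()
    if not track.converged or len(track.reversal_snrs) < config.threshold_last_k:
        raise ThresholdUndefinedError(
            f"track has {len(track.reversal_snrs)} reversals; "
            f"{config.threshold_last_k} required for a threshold"
        )
    return float(np.mean(track.reversal_snrs[-config.threshold_last_k:]))
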