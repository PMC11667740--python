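"""Virtual listener models for adaptive psychophysics.

The study battery was run on human participants; here each participant is
replaced by a *virtual listener*: a psychometric function mapping stimulus SNR
(dB) to the probability of a correct response.  The standard four-parameter
logistic is used,

    p(correct | snr) = gamma + (1 - gamma - lambda) * F((snr - t50) / s)

with guess rate ``gamma``, lapse rate ``lambda``, 50%-point ``t50`` (dB SNR),
spread ``s`` (dB) and ``F`` the standard logistic sigmoid.  A 1-up/1-down
staircase run against such a listener converges to the 50%-correct point,
which is what makes the simulated thresholds interpretable.

Degenerate listeners (:class:`ThresholdListener`, :class:`ConstantListener`,
:class:`ReplayListener`) exist for exact, enumerable tests of the staircase
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import expit

from .errors import InvalidParameterError

__all__ = [
    "PsychometricListener",
    "ThresholdListener",
    "ConstantListener",
    "ReplayListener",
    "psychometric_p_correct",
]


@dataclass(frozen=True)
class PsychometricListener:
    """Logistic psychometric listener.

    Parameters
    ----------
    threshold50
        SNR (dB) at which the underlying sigmoid crosses its midpoint; for
        ``guess_rate = lapse_rate = 0`` this is the 50%-correct point.
    slope
        Spread of the logistic in dB; must be strictly positive.  Smaller
        values give a steeper psychometric function.
    lapse_rate
        Probability of an error independent of SNR, in [0, 0.1].
    guess_rate
        Probability of a correct response by guessing, in [0, 0.5].
    """

    threshold50: float
    slope: float
    lapse_rate: float = 0.0
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InvalidParameterError(f"slope must be > 0, got {self.slope}")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise InvalidParameterError(
                f"lapse_rate must be in [0, 0.1], got {self.lapse_rate}"
            )
        if not 0.0 <= self.guess_rate <= 0.5:
            raise InvalidParameterError(
                f"guess_rate must be in [0, 0.5], got {self.guess_rate}"
            )

    def p_correct(self, snr: float) -> float:
        """Probability of a correct response at ``snr`` dB."""
        span = 1.0 - self.guess_rate - self.lapse_rate
        return self.guess_rate + span * float(
            expit((snr - self.threshold50) / self.slope)
        )


@dataclass(frozen=True)
class ThresholdListener:
    """Deterministic step listener: correct iff ``snr >= boundary``.

    The zero-slope limit of the psychometric function; used for exact
    trial-by-trial enumeration of staircase behaviour.
    """

    boundary: float

    def p_correct(self, snr: float) -> float:
        return 1.0 if snr >= self.boundary else 0.0


@dataclass(frozen=True)
class ConstantListener:
    """Listener with an SNR-independent probability of success."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must be in [0, 1], got {self.p}")

    def p_correct(self, snr: float) -> float:
        return self.p


class ReplayListener:
    """Replays a fixed response sequence, ignoring SNR.

    Each call to :meth:`p_correct` returns 0 or 1 according to the next
    element of ``responses``, so a staircase driven by this listener follows
    the given response script exactly.  Intended for property tests of the
    staircase bookkeeping.
    """

    def __init__(self, responses) -> None:
        self._responses = [bool(r) for r in responses]
        self._i = 0

    def p_correct(self, snr: float) -> float:
        if self._i >= len(self._responses):
            raise InvalidParameterError("ReplayListener ran out of responses")
        r = self._responses[self._i]
        self._i += 1
        return 1.0 if r else 0.0


def psychometric_p_correct(listener, snr: float) -> float:
    """Probability of a correct response from ``listener`` at ``snr`` dB.

    Thin functional wrapper over ``listener.p_correct`` accepting any object
    implementing that method.
    """
    return listener.p_correct(snr)
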