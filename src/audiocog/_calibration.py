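"""Factory calibration of the task engines.

The cohort generator must produce *observed* scores (staircase thresholds,
matching precisions, questionnaire totals) whose means, SDs and test–retest
correlations match the per-measure calibration table.  The task engines add
their own measurement noise (staircase estimation error, finite-trial
precision estimation, small-sample bias of 1/SD), so the latent "true"
parameters fed to the engines must be shrunk and shifted accordingly.

This module holds (a) the frozen engine-noise constants, measured once by
Monte Carlo at the default engine settings (scratch calibration runs of
200k staircases / matching blocks; see docs/methods.md), and (b) the
variance-budget solver that turns a measure calibration row into the affine
trait→parameter maps.

Model per measure m with calibration (mu_in, s_in, mu_web, s_web, r):

    X_in  = mu_in_eff  + a * z + engine noise,   a^2 = s_in^2 - v_task_in
    X_web = mu_web_eff + b * z + N(0, tau^2) + engine noise
    b     = gain_b * r * s_in * s_web / a
    tau^2 = s_web^2 - v_task_web - b^2

where z is the participant's latent trait (standard normal).  With unit gain
and exact constants this reproduces the target means/SDs and Corr(X_in, X_web)
= r; ``gain_b`` absorbs the small covariance compression introduced by
nonlinear engine stages (response clipping) for the matching task.
``bias_*`` constants absorb engine estimation bias (e.g. E[-log SD_hat] >
-log SD at 16 trials): mu_eff = mu_target - bias.

The constants are valid at the default engine configurations (staircase
schedule and listener slope 1.0 dB, 32-trial matching blocks).  Changing
those engine settings degrades the calibration gracefully (documented
limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError

__all__ = ["EngineNoise", "ENGINE_NOISE", "AffineMap", "solve_affine_map"]


@dataclass(frozen=True)
class EngineNoise:
    """Frozen Monte-Carlo engine-noise constants for one measure (analysis scale)."""

    v_task_in: float = 0.0
    v_task_web: float = 0.0
    bias_in: float = 0.0
    bias_web: float = 0.0
    gain_b: float = 1.0


# Fixed-point Monte-Carlo estimates at the default engine settings (see module
# docstring and docs/methods.md).  Staircase constants absorb the threshold
# estimation noise and the approach-from-0-dB transient bias of slope-1.0
# listeners; matching constants absorb precision-estimation noise at 16 trials
# (including the ~+0.066 small-sample bias of -log SD_hat) and the variance
# compression from response clipping — compression makes some effective
# v_task values *negative* (the latent spread must be inflated before the
# engine squashes it).  GMSI totals are exact by construction (no constants).
ENGINE_NOISE = {
    "GMSI": EngineNoise(),
    "DIN": EngineNoise(
        v_task_in=0.45215, v_task_web=-0.02122,
        bias_in=-0.51307, bias_web=-0.46507, gain_b=1.04587,
    ),
    "SIB": EngineNoise(
        v_task_in=-0.79146, v_task_web=-0.22266,
        bias_in=-0.33188, bias_web=-0.32496, gain_b=1.23596,
    ),
    "AUM_F": EngineNoise(
        v_task_in=-0.36731, v_task_web=-1.14058,
        bias_in=0.37077, bias_web=0.75496, gain_b=2.91454,
    ),
    "AUM_A": EngineNoise(
        v_task_in=0.02124, v_task_web=0.01818,
        bias_in=0.08636, bias_web=0.09308, gain_b=1.11387,
    ),
}


@dataclass(frozen=True)
class AffineMap:
    """Trait→parameter map for one measure: latent value per setting."""

    mu_in_eff: float
    mu_web_eff: float
    a: float
    b: float
    tau: float

    def true_value(self, setting: str, z: float, rng) -> float:
        """Latent engine parameter (analysis scale) for one session."""
        if setting == "inperson":
            return self.mu_in_eff + self.a * z
        if setting == "web":
            extra = rng.normal(0.0, self.tau) if self.tau > 0 else 0.0
            return self.mu_web_eff + self.b * z + extra
        raise CalibrationError(f"unknown setting {setting!r}")


def solve_affine_map(calibration, noise: EngineNoise) -> AffineMap:
    """Solve the variance budget for one measure.

    Parameters
    ----------
    calibration
        Object with ``mean_inperson, sd_inperson, mean_web, sd_web, retest_r``.
    noise
        Engine-noise constants for the measure.

    Raises
    ------
    CalibrationError
        If the target SD is smaller than the engine noise, or the requested
        retest correlation is too high to be reachable once engine noise is
        accounted for (tau^2 < 0).
    """
    s_in2 = calibration.sd_inperson**2 - noise.v_task_in
    if s_in2 <= 0:
        raise CalibrationError(
            f"in-person SD {calibration.sd_inperson} below engine noise "
            f"(v_task={noise.v_task_in})"
        )
    a = float(np.sqrt(s_in2))
    b = noise.gain_b * calibration.retest_r * calibration.sd_inperson * calibration.sd_web / a
    tau2 = calibration.sd_web**2 - noise.v_task_web - b**2
    if tau2 < -1e-9:
        raise CalibrationError(
            f"retest r={calibration.retest_r} infeasible for web SD "
            f"{calibration.sd_web} given engine noise"
        )
    return AffineMap(
        mu_in_eff=calibration.mean_inperson - noise.bias_in,
        mu_web_eff=calibration.mean_web - noise.bias_web,
        a=a,
        b=float(b),
        tau=float(np.sqrt(max(tau2, 0.0))),
    )
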