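"""Synthetic participant cohort for the auditory test battery.

Generates older-adult virtual participants with demographics (ages 50–86,
mean 67, SD 10), pure-tone audiograms summarized as best-ear high-frequency
averages (4–8 kHz), hearing-loss categories, hearing-aid use, and a latent
multivariate-Gaussian trait layer (musical sophistication, speech-in-noise
ability, auditory-memory ability for frequency and AM rate) whose affine maps
into task parameters are calibrated so that the *simulated* battery scores
reproduce the target means/SDs and test–retest correlations per measure and
setting.  A selection model flags which participants return for the web-based
follow-up (nobody above 75; older, severely hearing-impaired and hearing-aid
participants under-sampled), and an optional add-on cohort contributes
web-only participants without audiograms.

The five measures, in analysis units:

=========  ======================================================
GMSI       questionnaire total score (38–266)
DIN        digits-in-noise SNR threshold, dB (lower = better)
SIB        speech-in-babble SNR threshold, dB (lower = better)
AUM_F      log precision of frequency matching (scale units)
AUM_A      log precision of AM-rate matching (scale units)
=========  ======================================================

The measures table stores raw precisions for the two memory measures (the log
transform is an analysis step); their calibration targets are on the log
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._calibration import ENGINE_NOISE, AffineMap, solve_affine_map
from .errors import CalibrationError, ValidationError
from .gmsi import items_with_total, score_gmsi
from .matching import MatchingConfig, MatchingListener, simulate_matching_block
from .listeners import PsychometricListener
from .staircase import StaircaseConfig, simulate_staircase

__all__ = [
    "MEASURES",
    "TRAITS",
    "SETTINGS",
    "AUDIOGRAM_FREQS",
    "MeasureCalibration",
    "SelectionModel",
    "CohortConfig",
    "ListenerProfile",
    "generate_cohort",
    "compute_pta_hf",
    "assign_hearing_category",
    "apply_selection",
    "simulate_session",
    "simulate_study",
    "response_rate",
    "task_rng",
]

MEASURES = ("GMSI", "DIN", "SIB", "AUM_F", "AUM_A")
#: latent dimensions; DIN and SIB share the single speech-in-noise trait "sin"
TRAITS = ("gmsi", "sin", "aum_f", "aum_a", "age", "pta")
SETTINGS = ("inperson", "web")
AUDIOGRAM_FREQS = (250, 500, 1000, 2000, 4000, 8000)
CEILING_DB_HL = 100.0

_MEASURE_TRAIT = {"GMSI": "gmsi", "DIN": "sin", "SIB": "sin", "AUM_F": "aum_f", "AUM_A": "aum_a"}

# fixed sub-stream codes so adding a task never perturbs another task's draws
_STREAM = {"traits": 101, "audiogram": 102, "selection": 103, "session": 104}
_TASK_CODE = {"DIN": 1, "SIB": 2, "AUM": 3, "GMSI": 4, "param": 5}
_SETTING_CODE = {"inperson": 0, "web": 1}


@dataclass(frozen=True)
class MeasureCalibration:
    """Per-measure targets: mean/SD per setting plus the test–retest correlation."""

    mean_inperson: float
    sd_inperson: float
    mean_web: float
    sd_web: float
    retest_r: float

    def __post_init__(self) -> None:
        if self.sd_inperson <= 0 or self.sd_web <= 0:
            raise ValidationError("calibration SDs must be positive")
        if not -1.0 <= self.retest_r <= 1.0:
            raise ValidationError("retest_r must be in [-1, 1]")


#: Default calibration: the published battery values at n=58 (memory measures
#: on the log-precision scale).
DEFAULT_MEASURE_CALIBRATION = {
    "GMSI": MeasureCalibration(156.0, 36.0, 151.0, 23.0, 0.82),
    "DIN": MeasureCalibration(6.35, 2.8, 5.42, 3.2, 0.55),
    "SIB": MeasureCalibration(2.45, 2.8, 2.01, 2.1, 0.55),
    "AUM_F": MeasureCalibration(1.52, 0.6, 1.34, 0.7, 0.75),
    "AUM_A": MeasureCalibration(2.52, 0.4, 2.42, 0.4, 0.44),
}


def _default_latent_corr() -> np.ndarray:
    """Default latent correlation matrix over (gmsi, sin, aum_f, aum_a, age, pta).

    The off-diagonals are chosen so that the *observed* cross-measure
    correlations, after attenuation by setting-specific noise, land near the
    published associations (speech-in-babble ~ AM-rate memory 0.46 in person /
    0.18 on the web; musical sophistication ~ frequency memory ~0.5 in both
    settings), with age and high-frequency hearing loss moderately related to
    the auditory traits.  "sin" is oriented in the threshold direction
    (higher = worse speech-in-noise performance).
    """
    corr = {
        ("gmsi", "sin"): -0.20,
        ("gmsi", "aum_f"): 0.56,
        ("gmsi", "aum_a"): 0.25,
        ("gmsi", "age"): -0.05,
        ("gmsi", "pta"): -0.05,
        ("sin", "aum_f"): -0.10,
        ("sin", "aum_a"): 0.58,
        ("sin", "age"): 0.40,
        ("sin", "pta"): 0.50,
        ("aum_f", "aum_a"): 0.35,
        ("aum_f", "age"): -0.25,
        ("aum_f", "pta"): -0.15,
        ("aum_a", "age"): 0.10,
        ("aum_a", "pta"): 0.15,
        ("age", "pta"): 0.50,
    }
    m = np.eye(len(TRAITS))
    idx = {t: i for i, t in enumerate(TRAITS)}
    for (a, b), v in corr.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return m


@dataclass(frozen=True)
class SelectionModel:
    """Probability model for returning to the web-based follow-up.

    The per-participant return probability is ``base_rate`` multiplied by a
    penalty for age above ``soft_age_cutoff``, severe hearing loss and
    hearing-aid use, and forced to zero above ``hard_age_cutoff``.  Defaults
    are tuned so that a default cohort of 153 yields about 58 returners
    (37.9%) with no returner older than 75.
    """

    base_rate: float = 0.656
    soft_age_cutoff: float = 70.0
    hard_age_cutoff: float = 75.0
    age_penalty: float = 0.45
    severe_penalty: float = 0.35
    hearing_aid_penalty: float = 0.35

    def __post_init__(self) -> None:
        for name in ("base_rate", "age_penalty", "severe_penalty", "hearing_aid_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.soft_age_cutoff > self.hard_age_cutoff:
            raise ValidationError("soft_age_cutoff must be <= hard_age_cutoff")

    def return_probability(self, profile: "ListenerProfile") -> float:
        if profile.age > self.hard_age_cutoff:
            return 0.0
        p = self.base_rate
        if profile.age > self.soft_age_cutoff:
            p *= self.age_penalty
        if profile.hearing_category == "severe":
            p *= self.severe_penalty
        if profile.hearing_aid_user:
            p *= self.hearing_aid_penalty
        return p


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, latent structure and per-measure calibration."""

    n_inperson: int = 153
    n_addon_web: int = 89  # web-only add-on cohort (no audiogram)
    age_mean: float = 67.0
    age_sd: float = 10.0
    age_range: tuple = (50.0, 86.0)
    addon_age_mean: float = 65.0
    addon_age_sd: float = 8.0
    hearing_mix: dict = field(
        default_factory=lambda: {"normal": 0.111, "mild": 0.189, "moderate": 0.543, "severe": 0.157}
    )
    latent_corr: np.ndarray = field(default_factory=_default_latent_corr)
    measure_calibration: dict = field(
        default_factory=lambda: dict(DEFAULT_MEASURE_CALIBRATION)
    )
    selection_model: SelectionModel = field(default_factory=SelectionModel)
    sin_slope: float = 1.0  # psychometric spread (dB) of the virtual listeners
    gmsi_item_sd: float = 1.0
    sigma_cap: float = 1.0  # upper bound on matching response noise (guessing regime)

    def __post_init__(self) -> None:
        if self.n_inperson < 0 or self.n_addon_web < 0:
            raise ValidationError("cohort sizes must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range must have low < high")
        mix_sum = sum(self.hearing_mix.values())
        if abs(mix_sum - 1.0) > 1e-6:
            raise ValidationError(f"hearing_mix must sum to 1, sums to {mix_sum}")
        if set(self.hearing_mix) != {"normal", "mild", "moderate", "severe"}:
            raise ValidationError("hearing_mix must have the four category keys")
        m = np.asarray(self.latent_corr, dtype=float)
        if m.shape != (len(TRAITS), len(TRAITS)):
            raise ValidationError(f"latent_corr must be {len(TRAITS)}x{len(TRAITS)}")
        if not np.allclose(m, m.T, atol=1e-10) or not np.allclose(np.diag(m), 1.0):
            raise ValidationError("latent_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValidationError("latent_corr is not positive semi-definite")
        if set(self.measure_calibration) != set(MEASURES):
            raise ValidationError(f"measure_calibration must have keys {MEASURES}")
        if self.sin_slope <= 0:
            raise ValidationError("sin_slope must be positive")

    def affine_maps(self) -> dict:
        """Solved trait→parameter maps for every measure (may raise CalibrationError)."""
        return {
            m: solve_affine_map(self.measure_calibration[m], ENGINE_NOISE[m])
            for m in MEASURES
        }


@dataclass
class ListenerProfile:
    """One virtual participant."""

    participant_id: str
    cohort: str  # "main" (in-person + possible web return) or "addon" (web only)
    age: float
    traits: dict
    audiogram: dict | None = None  # {"left"/"right": {freq_hz: dB HL}}
    pta_hf: float | None = None
    hearing_category: str | None = None
    hearing_aid_user: bool = False
    web_returner: bool | None = None


def response_rate(responders: int, invited: int) -> float:
    """Response rate as a percentage (e.g. 153 of 300 → 51.0)."""
    if invited <= 0:
        raise ValidationError("invited must be positive")
    return 100.0 * responders / invited


def compute_pta_hf(audiogram: dict) -> float:
    """Best-ear high-frequency pure-tone average: mean of 4 and 8 kHz, better ear.

    Each ear's 4 kHz and 8 kHz thresholds (dB HL, ceiling 100 allowed) are
    averaged; the smaller (better-ear) mean is returned.
    """
    means = {}
    for ear in ("left", "right"):
        if ear not in audiogram:
            raise ValidationError(f"audiogram missing ear {ear!r}")
        thresholds = audiogram[ear]
        for freq in (4000, 8000):
            if freq not in thresholds:
                raise ValidationError(f"audiogram {ear} missing {freq} Hz")
        means[ear] = (thresholds[4000] + thresholds[8000]) / 2.0
    return float(min(means.values()))


def assign_hearing_category(pta_hf: float) -> str:
    """Hearing-loss category from the best-ear 4–8 kHz average.

    normal < 20, mild [20, 40), moderate [40, 80), severe >= 80 dB HL.  The
    published band definitions leave 60–80 unassigned; that gap is closed into
    "moderate".
    """
    if pta_hf < 0:
        raise ValidationError(f"pta_hf must be >= 0, got {pta_hf}")
    if pta_hf < 20:
        return "normal"
    if pta_hf < 40:
        return "mild"
    if pta_hf < 80:
        return "moderate"
    return "severe"


def _truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float) -> tuple:
    """Parent (mu, sigma) of a truncated normal whose truncated moments match.

    Solved numerically so that sampling from TruncNormal(mu, sigma; [lo, hi])
    has the requested mean and SD after truncation.
    """

    def moments(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(moments, x0=[mean, math.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(math.exp(sol[1]))
    return mu, sigma


def _trunc_dist(mean: float, sd: float, lo: float, hi: float):
    mu, sigma = _truncnorm_parent_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def _pta_quantile(u: np.ndarray, hearing_mix: dict) -> np.ndarray:
    """Quantile function of the hearing-loss marginal implied by the category mix.

    Piecewise-uniform over the category bands [0,20), [20,40), [40,80),
    [80,100] with masses from ``hearing_mix``; composing it with a Gaussian
    copula preserves the mix while inheriting the latent correlation with age.
    """
    edges = np.array([0.0, 20.0, 40.0, 80.0, 100.0])
    masses = np.array([hearing_mix[k] for k in ("normal", "mild", "moderate", "severe")])
    cum = np.concatenate([[0.0], np.cumsum(masses)])
    cum[-1] = 1.0
    return np.interp(u, cum, edges)


def _round5(x) -> np.ndarray:
    return np.clip(np.rint(np.asarray(x) / 5.0) * 5.0, 0.0, CEILING_DB_HL)


def _make_audiogram(pta_target: float, rng) -> dict:
    """Two-ear audiogram consistent with a target best-ear 4–8 kHz average.

    Thresholds are on the audiometer's 5 dB grid with a 100 dB HL ceiling.
    The better ear straddles the target at 4/8 kHz (high-frequency sloping
    loss); lower frequencies improve toward 250 Hz; the other ear is uniformly
    worse, so the constructed ear remains the best ear.
    """
    delta = float(rng.uniform(5.0, 15.0))
    delta = min(delta, pta_target, CEILING_DB_HL - pta_target)
    best = {4000: pta_target - delta, 8000: pta_target + delta}
    drops = {250: 35.0, 500: 30.0, 1000: 22.0, 2000: 12.0}
    for freq, drop in drops.items():
        best[freq] = max(0.0, pta_target - drop + rng.normal(0.0, 5.0))
    worse_offset = abs(rng.normal(8.0, 5.0))
    worse = {f: min(v + worse_offset, CEILING_DB_HL) for f, v in best.items()}
    best_rounded = {f: float(v) for f, v in zip(best, _round5(list(best.values())))}
    worse_rounded = {f: float(v) for f, v in zip(worse, _round5(list(worse.values())))}
    if rng.random() < 0.5:
        return {"left": best_rounded, "right": worse_rounded}
    return {"left": worse_rounded, "right": best_rounded}


def task_rng(seed: int, participant_index: int, stream: str, setting: str | None = None, task: str | None = None):
    """Derived RNG stream keyed on (seed, participant, stream, setting, task).

    Keyed (rather than sequentially spawned) streams mean that adding a task
    or participant never perturbs any other stream's draws.
    """
    key = [int(seed), int(participant_index), _STREAM[stream]]
    if setting is not None:
        key.append(_SETTING_CODE[setting])
    if task is not None:
        key.append(_TASK_CODE[task])
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_cohort(config: CohortConfig, rng) -> list:
    """Generate the virtual participant population.

    Ages follow a truncated Gaussian on ``age_range`` whose post-truncation
    mean/SD equal the configured targets; latent traits follow the configured
    multivariate Gaussian, with age and hearing loss attached through a
    Gaussian copula (hearing loss additionally matching the category mix).
    The add-on cohort (web-only participants) has its own age distribution and
    no audiogram.
    """
    n_main, n_addon = config.n_inperson, config.n_addon_web
    n_total = n_main + n_addon
    if n_total == 0:
        return []

    chol = np.linalg.cholesky(
        np.asarray(config.latent_corr, dtype=float) + 1e-12 * np.eye(len(TRAITS))
    )
    z = rng.standard_normal((n_total, len(TRAITS))) @ chol.T
    traits = {t: z[:, i] for i, t in enumerate(TRAITS)}

    lo, hi = config.age_range
    main_age_dist = _trunc_dist(config.age_mean, config.age_sd, lo, hi)
    addon_age_dist = _trunc_dist(config.addon_age_mean, config.addon_age_sd, lo, hi)
    u_age = stats.norm.cdf(traits["age"])
    u_pta = stats.norm.cdf(traits["pta"])

    profiles = []
    for i in range(n_total):
        is_main = i < n_main
        age_dist = main_age_dist if is_main else addon_age_dist
        age = float(age_dist.ppf(u_age[i]))
        profile = ListenerProfile(
            participant_id=f"{'P' if is_main else 'X'}{i:04d}",
            cohort="main" if is_main else "addon",
            age=age,
            traits={t: float(traits[t][i]) for t in TRAITS},
        )
        if is_main:
            pta_target = float(_pta_quantile(np.array([u_pta[i]]), config.hearing_mix)[0])
            profile.audiogram = _make_audiogram(pta_target, rng)
            profile.pta_hf = compute_pta_hf(profile.audiogram)
            profile.hearing_category = assign_hearing_category(profile.pta_hf)
            p_aid = float(np.clip((profile.pta_hf - 35.0) / 140.0, 0.0, 0.6))
            profile.hearing_aid_user = bool(rng.random() < p_aid)
        else:
            profile.web_returner = True  # add-on participants are web-only
        profiles.append(profile)
    return profiles


def apply_selection(cohort: list, selection_model: SelectionModel, rng) -> list:
    """Flag which main-cohort participants return for the web follow-up.

    Returns the same profile objects with ``web_returner`` set.  Add-on
    participants keep their web-only flag.
    """
    for profile in cohort:
        if profile.cohort != "main":
            continue
        p = selection_model.return_probability(profile)
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"return probability {p} outside [0, 1]")
        profile.web_returner = bool(rng.random() < p)
    return cohort


def _sigma_from_log_precision(log_precision: float, cap: float) -> float:
    # precision = 1/sigma on the normalized response scale
    return float(min(np.exp(-log_precision), cap))


def simulate_session(
    profile: ListenerProfile,
    setting: str,
    maps: dict,
    config: CohortConfig,
    staircase_config: StaircaseConfig,
    matching_config: MatchingConfig,
    rng_for_task,
    collect_trials: list | None = None,
) -> dict:
    """Simulate one full battery session for one participant.

    Runs the staircase engine twice (DIN, SIB), one interleaved matching block
    (both memory features) and the questionnaire, all at stimulus-parameter
    level, and returns one measures row.  A non-converged staircase or a
    degenerate matching sample yields a missing value (NaN), never an imputed
    one.

    ``rng_for_task(task)`` must return an independent seeded generator per
    task; ``maps`` are the solved trait→parameter affine maps.
    """
    if setting not in SETTINGS:
        raise ValidationError(f"unknown setting {setting!r}")
    row = {
        "participant_id": profile.participant_id,
        "setting": setting,
        "cohort": profile.cohort,
        "age": profile.age,
        "pta_hf": profile.pta_hf if profile.pta_hf is not None else np.nan,
        "hearing_category": profile.hearing_category,
    }
    param_rng = rng_for_task("param")

    # --- speech-in-noise staircases -------------------------------------
    for task in ("DIN", "SIB"):
        t50 = maps[task].true_value(setting, profile.traits[_MEASURE_TRAIT[task]], param_rng)
        listener = PsychometricListener(threshold50=t50, slope=config.sin_slope)
        track = simulate_staircase(listener, staircase_config, rng_for_task(task))
        row[task] = track.threshold if track.converged else np.nan
        if collect_trials is not None:
            for idx, (snr, resp) in enumerate(zip(track.trial_snrs, track.responses)):
                collect_trials.append(
                    {
                        "participant_id": profile.participant_id,
                        "setting": setting,
                        "task": task,
                        "trial_index": idx,
                        "stimulus_value": np.nan,
                        "response_value": np.nan,
                        "correct": int(resp),
                        "snr_db": snr,
                    }
                )

    # --- auditory memory matching (one interleaved block) ----------------
    lp_f = maps["AUM_F"].true_value(setting, profile.traits["aum_f"], param_rng)
    lp_a = maps["AUM_A"].true_value(setting, profile.traits["aum_a"], param_rng)
    listener_m = MatchingListener(
        sigma_f=_sigma_from_log_precision(lp_f, config.sigma_cap),
        sigma_a=_sigma_from_log_precision(lp_a, config.sigma_cap),
    )
    block = simulate_matching_block(listener_m, matching_config, rng_for_task("AUM"))
    row["AUM_F"] = block.precision_f.precision if block.precision_f else np.nan
    row["AUM_A"] = block.precision_a.precision if block.precision_a else np.nan
    if collect_trials is not None:
        for idx, (feat, tgt, resp) in enumerate(
            zip(block.features, block.targets_scale, block.responses_scale)
        ):
            collect_trials.append(
                {
                    "participant_id": profile.participant_id,
                    "setting": setting,
                    "task": f"AUM_{feat}",
                    "trial_index": idx,
                    "stimulus_value": tgt,
                    "response_value": resp,
                    "correct": np.nan,
                    "snr_db": np.nan,
                }
            )

    # --- questionnaire ----------------------------------------------------
    total_latent = maps["GMSI"].true_value(setting, profile.traits["gmsi"], param_rng)
    items = items_with_total(total_latent, config.gmsi_item_sd, rng_for_task("GMSI"))
    row["GMSI"] = float(score_gmsi(items).total)
    return row


def simulate_study(
    config: CohortConfig,
    seed: int,
    staircase_config: StaircaseConfig | None = None,
    matching_config: MatchingConfig | None = None,
    collect_trials: bool = False,
):
    """Generate a cohort, apply web selection and simulate every session.

    Returns ``(cohort, measures_rows, trial_rows)`` where ``measures_rows`` is
    a list of per-session dicts (one row per participant × setting attended).
    All randomness derives from ``seed`` through keyed sub-streams, so the
    output is reproducible and stable against re-ordering of tasks.
    """
    staircase_config = staircase_config or StaircaseConfig()
    matching_config = matching_config or MatchingConfig()
    maps = config.affine_maps()

    cohort = generate_cohort(config, task_rng(seed, 0, "traits"))
    apply_selection(cohort, config.selection_model, task_rng(seed, 0, "selection"))

    trial_rows: list | None = [] if collect_trials else None
    measures_rows = []
    for i, profile in enumerate(cohort):
        settings = []
        if profile.cohort == "main":
            settings.append("inperson")
        if profile.web_returner:
            settings.append("web")
        for setting in settings:
            def rng_for_task(task, _i=i, _s=setting):
                return task_rng(seed, _i, "session", setting=_s, task=task)

            measures_rows.append(
                simulate_session(
                    profile,
                    setting,
                    maps,
                    config,
                    staircase_config,
                    matching_config,
                    rng_for_task,
                    collect_trials=trial_rows,
                )
            )
    return cohort, measures_rows, trial_rows
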