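"""Synthetic cohort: audiometry summaries, generation, selection, calibration."""

import numpy as np
import pytest

from audiocog import (
    CohortConfig,
    DEFAULT_MEASURE_CALIBRATION,
    MeasureCalibration,
    SelectionModel,
    ValidationError,
    apply_selection,
    assign_hearing_category,
    compute_pta_hf,
    generate_cohort,
    response_rate,
    simulate_study,
)
from audiocog.cohort import MEASURES, task_rng


class TestPta:
    def test_best_ear_hand_example(self):
        audiogram = {
            "left": {4000: 30.0, 8000: 50.0},
            "right": {4000: 60.0, 8000: 80.0},
        }
        assert compute_pta_hf(audiogram) == 40.0  # left ear mean is smaller

    def test_constant_audiogram(self):
        flat = {ear: {4000: 20.0, 8000: 20.0} for ear in ("left", "right")}
        assert compute_pta_hf(flat) == 20.0

    def test_ceiling_propagates(self):
        capped = {ear: {4000: 100.0, 8000: 100.0} for ear in ("left", "right")}
        assert compute_pta_hf(capped) == 100.0

    def test_missing_frequency_rejected(self):
        with pytest.raises(ValidationError):
            compute_pta_hf({"left": {4000: 30.0}, "right": {4000: 30.0, 8000: 40.0}})


class TestHearingCategory:
    @pytest.mark.parametrize(
        "pta,expected",
        [
            (15.0, "normal"),
            (19.9, "normal"),
            (20.0, "mild"),
            (39.9, "mild"),
            (40.0, "moderate"),
            (70.0, "moderate"),  # 60-80 gap closed into moderate
            (79.9, "moderate"),
            (80.0, "severe"),
            (85.0, "severe"),
        ],
    )
    def test_bands(self, pta, expected):
        assert assign_hearing_category(pta) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            assign_hearing_category(-1.0)


class TestGeneration:
    def test_same_seed_identical_cohorts(self):
        config = CohortConfig(n_inperson=60, n_addon_web=10)
        a = generate_cohort(config, np.random.default_rng(5))
        b = generate_cohort(config, np.random.default_rng(5))
        for pa, pb in zip(a, b):
            assert pa.age == pb.age
            assert pa.traits == pb.traits
            assert pa.audiogram == pb.audiogram

    def test_age_distribution_truncation_corrected(self, big_study):
        cohort, _ = big_study
        ages = np.array([p.age for p in cohort])
        assert ages.min() >= 50.0 and ages.max() <= 86.0
        assert ages.mean() == pytest.approx(67.0, abs=0.3)
        assert ages.std(ddof=1) == pytest.approx(10.0, abs=0.3)

    def test_profile_internal_consistency(self, big_study):
        cohort, _ = big_study
        for p in cohort[:500]:
            assert p.pta_hf == compute_pta_hf(p.audiogram)
            assert p.hearing_category == assign_hearing_category(p.pta_hf)

    def test_hearing_mix_approximately_met(self, big_study):
        cohort, _ = big_study
        config = CohortConfig()
        for cat, target in config.hearing_mix.items():
            frac = np.mean([p.hearing_category == cat for p in cohort])
            assert frac == pytest.approx(target, abs=0.05)

    def test_identity_latent_corr_gives_independent_measures(self):
        import pandas as pd

        config = CohortConfig(
            n_inperson=3000, n_addon_web=0, latent_corr=np.eye(6),
            selection_model=SelectionModel(base_rate=0.0),
        )
        _, rows, _ = simulate_study(config, seed=19)
        df = pd.DataFrame(rows)
        r = np.corrcoef(df["GMSI"], df["DIN"])[0, 1]
        assert abs(r) < 0.05

    def test_non_psd_latent_corr_rejected(self):
        bad = np.eye(6)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValidationError):
            CohortConfig(latent_corr=bad)

    def test_infeasible_calibration_rejected(self):
        cal = dict(DEFAULT_MEASURE_CALIBRATION)
        # in-person SD below the engine's own measurement noise
        cal["AUM_A"] = MeasureCalibration(2.52, 0.1, 2.42, 0.4, 0.44)
        config = CohortConfig(measure_calibration=cal)
        from audiocog import CalibrationError

        with pytest.raises(CalibrationError):
            config.affine_maps()


class TestSelection:
    def test_nobody_above_hard_cutoff_returns(self, big_study):
        cohort, _ = big_study
        assert all(not p.web_returner for p in cohort if p.age > 75 and p.cohort == "main")

    def test_degenerate_selection_everyone_under_cutoff_returns(self):
        config = CohortConfig(n_inperson=200, n_addon_web=0)
        cohort = generate_cohort(config, np.random.default_rng(3))
        model = SelectionModel(
            base_rate=1.0, age_penalty=1.0, severe_penalty=1.0, hearing_aid_penalty=1.0
        )
        apply_selection(cohort, model, np.random.default_rng(4))
        for p in cohort:
            assert p.web_returner == (p.age <= 75)

    def test_mean_returner_count_matches_study(self):
        """Default selection yields about 58 of 153 returners (37.9%)."""
        config = CohortConfig(n_addon_web=0)
        counts = []
        for rep in range(200):
            cohort = generate_cohort(config, np.random.default_rng(1000 + rep))
            apply_selection(cohort, config.selection_model, np.random.default_rng(5000 + rep))
            counts.append(sum(bool(p.web_returner) for p in cohort))
        assert np.mean(counts) == pytest.approx(58.0, abs=4.0)

    def test_severe_hearing_loss_underrepresented_on_web(self, big_study):
        cohort, _ = big_study
        severe_all = np.mean([p.hearing_category == "severe" for p in cohort])
        returners = [p for p in cohort if p.web_returner]
        severe_web = np.mean([p.hearing_category == "severe" for p in returners])
        assert severe_web < severe_all


class TestSessionCalibration:
    def test_inperson_moments_match_calibration(self, big_study):
        """Simulated battery scores reproduce the calibrated means/SDs at n=10,000.

        Tolerances reflect factory-calibration accuracy (about 5% of an SD on
        the mean, 5% relative on the SD) on top of Monte-Carlo error.
        """
        _, measures = big_study
        inperson = measures[measures["setting"] == "inperson"]
        for m in MEASURES:
            cal = DEFAULT_MEASURE_CALIBRATION[m]
            vals = inperson[m].dropna()
            assert vals.mean() == pytest.approx(
                cal.mean_inperson, abs=0.05 * cal.sd_inperson
            ), m
            assert vals.std(ddof=1) == pytest.approx(
                cal.sd_inperson, rel=0.05
            ), m

    def test_no_web_noise_and_shared_trait_gives_perfect_gmsi_retest(self):
        """With web calibration equal to in-person and retest r=1, the exact
        questionnaire chain reproduces identical totals across settings."""
        import pandas as pd

        cal = dict(DEFAULT_MEASURE_CALIBRATION)
        cal["GMSI"] = MeasureCalibration(156.0, 36.0, 156.0, 36.0, 1.0)
        config = CohortConfig(
            n_inperson=150, n_addon_web=0, measure_calibration=cal,
            selection_model=SelectionModel(base_rate=1.0, age_penalty=1.0,
                                           severe_penalty=1.0, hearing_aid_penalty=1.0),
        )
        _, rows, _ = simulate_study(config, seed=23)
        df = pd.DataFrame(rows)
        wide = df.pivot(index="participant_id", columns="setting", values="GMSI").dropna()
        assert np.corrcoef(wide["inperson"], wide["web"])[0, 1] == pytest.approx(1.0)

    def test_web_attenuation_monotone_in_retest_target(self):
        """Lowering the calibrated retest correlation (more web noise) lowers
        the realized cross-setting correlation."""
        import pandas as pd

        realized = []
        for r_target in (0.9, 0.4):
            cal = dict(DEFAULT_MEASURE_CALIBRATION)
            cal["GMSI"] = MeasureCalibration(156.0, 36.0, 156.0, 36.0, r_target)
            config = CohortConfig(
                n_inperson=800, n_addon_web=0, measure_calibration=cal,
                selection_model=SelectionModel(base_rate=1.0, age_penalty=1.0,
                                               severe_penalty=1.0, hearing_aid_penalty=1.0),
            )
            _, rows, _ = simulate_study(config, seed=29)
            df = pd.DataFrame(rows)
            wide = df.pivot(index="participant_id", columns="setting", values="GMSI").dropna()
            realized.append(np.corrcoef(wide["inperson"], wide["web"])[0, 1])
        assert realized[0] > realized[1]

    def test_missing_values_never_imputed(self, big_study):
        _, measures = big_study
        # non-converged staircases are rare but must stay NaN if they occur;
        # the add-on-free study has full in-person attendance
        assert measures["GMSI"].notna().all()


def test_response_rates_exact():
    assert response_rate(153, 300) == pytest.approx(51.0)
    assert response_rate(58, 153) == pytest.approx(37.908, abs=1e-3)
    assert response_rate(89, 500) == pytest.approx(17.8)
    with pytest.raises(ValidationError):
        response_rate(1, 0)


def test_task_rng_streams_are_stable_and_independent():
    a = task_rng(1, 5, "session", setting="web", task="DIN").random(3)
    b = task_rng(1, 5, "session", setting="web", task="DIN").random(3)
    c = task_rng(1, 5, "session", setting="web", task="SIB").random(3)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
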