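"""Synthetic cohort generator: covariates, ground truth, waveforms, I/O."""

import numpy as np
import pandas as pd
import pytest

from gaitpower.preprocess import FULL_GRID
from gaitpower.synthetic import (
    DECADE_REFERENCE,
    GaussianBump,
    GeneratorConfig,
    decade_of,
    export_dataset,
    load_dataset,
    make_ground_truth,
    simulate_covariates,
    simulate_dataset,
    simulate_waveforms,
)
from gaitpower.winter import default_definitions, extract


class TestGeneratorConfig:
    def test_invalid_age_range_rejected(self):
        with pytest.raises(ValueError, match="age_range"):
            GeneratorConfig(age_range=(1.0, 120.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            GeneratorConfig(noise_sd=-0.1)

    def test_unknown_effect_scale_rejected(self):
        with pytest.raises(ValueError, match="effect_scale"):
            GeneratorConfig(effect_scale={"bmi": 1.0})

    def test_effect_scale_filled_with_ones(self):
        cfg = GeneratorConfig(effect_scale={"speed": 2.0})
        assert cfg.effect_scale["speed"] == 2.0
        assert cfg.effect_scale["age"] == 1.0


class TestCovariates:
    def test_decade_stratification_exact(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=90, seed=1))
        decades = covs["age"].map(decade_of)
        assert decades.value_counts().eq(10).all()

    def test_decade3_mean_height_matches_reference(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=10000, seed=2))
        d3 = covs[covs["age"].map(decade_of) == 3]
        assert d3["height"].mean() == pytest.approx(1.75, abs=0.01)

    def test_decade1_mean_height_matches_reference(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=10000, seed=2))
        d1 = covs[covs["age"].map(decade_of) == 1]
        assert d1["height"].mean() == pytest.approx(1.04, abs=0.01)

    def test_same_seed_identical_tables(self):
        cfg = GeneratorConfig(n_participants=80, seed=33)
        pd.testing.assert_frame_equal(simulate_covariates(cfg), simulate_covariates(cfg))

    def test_speeds_within_truncation_bounds(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=2000, seed=3))
        assert covs["speed"].between(0.5, 2.0).all()
        assert covs["speed"].mean() == pytest.approx(1.2, abs=0.05)

    def test_every_study_populated(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=12, n_studies=6, seed=4))
        assert covs["study_id"].nunique() == 6

    def test_fewer_participants_than_studies_rejected(self):
        with pytest.raises(ValueError, match="every study is populated"):
            simulate_covariates(GeneratorConfig(n_participants=3, n_studies=6))

    def test_positivity_invariants(self):
        covs = simulate_covariates(GeneratorConfig(n_participants=2000, seed=5))
        for col in ("age", "speed", "stride_length", "height", "mass"):
            assert (covs[col] > 0).all(), col


class TestWaveforms:
    def test_same_seed_identical_waveforms(self):
        cfg = GeneratorConfig(n_participants=20, seed=9)
        _, w1, _ = simulate_dataset(cfg)
        _, w2, _ = simulate_dataset(cfg)
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_generator_returns_template(self):
        cfg = GeneratorConfig(
            n_participants=5, n_studies=2, seed=1, noise_sd=0.0, study_sd=0.0,
            effect_scale={k: 0.0 for k in ("age", "speed", "stride_length", "height", "age_speed")},
        )
        covs, waves, truth = simulate_dataset(cfg)
        for w in waves:
            expected = truth.template(w.joint, w.grid) + (
                truth.beta_sex[w.joint]
                if covs.set_index("participant_id").loc[w.participant_id, "sex"] == "male"
                else 0.0
            )
            np.testing.assert_allclose(w.values, expected, atol=1e-12)

    def test_noiseless_mean_structure_exact(self):
        """waveform - template == sum of effect terms + study curve + sex offset."""
        cfg = GeneratorConfig(n_participants=12, seed=21, noise_sd=0.0)
        covs, waves, truth = simulate_dataset(cfg)
        recs = covs.set_index("participant_id")
        for w in waves:
            rec = recs.loc[w.participant_id]
            sidx = int(rec["study_id"].removeprefix("study")) - 1
            expected = (
                truth.total_effect(rec, w.joint, w.grid)
                + truth.study_curve(w.joint, sidx, w.grid)
                + (truth.beta_sex[w.joint] if rec["sex"] == "male" else 0.0)
            )
            np.testing.assert_allclose(
                w.values - truth.template(w.joint, w.grid), expected, atol=1e-12
            )

    def test_template_sign_structure_in_index_windows(self):
        """Noiseless templates carry the canonical sign in every index window."""
        cfg = GeneratorConfig(
            n_participants=1, n_studies=1, seed=1, noise_sd=0.0, study_sd=0.0,
            effect_scale={k: 0.0 for k in ("age", "speed", "stride_length", "height", "age_speed")},
        )
        _, _, truth = simulate_dataset(cfg)
        for d in default_definitions():
            curve = truth.template(d.joint, FULL_GRID)
            lo, hi = d.window
            window_vals = curve[(FULL_GRID >= lo) & (FULL_GRID <= hi)]
            if d.polarity == "positive_max":
                assert window_vals.max() >= 0, d.label
            else:
                assert window_vals.min() <= 0, d.label

    def test_single_bump_template_gives_exact_a2(self):
        cfg = GeneratorConfig(
            n_participants=1, n_studies=1, seed=1, noise_sd=0.0, study_sd=0.0,
            effect_scale={k: 0.0 for k in ("age", "speed", "stride_length", "height", "age_speed")},
        )
        covs, waves, truth = simulate_dataset(
            cfg,
            joints=("ankle",),
            template_bumps={"ankle": (GaussianBump(55.0, 4.0, 2.0),)},
            beta_sex={"ankle": 0.0},
        )
        a2 = next(d for d in default_definitions() if d.label == "A2")
        v = extract(waves[0], a2)
        assert v.value == pytest.approx(2.0)
        assert v.cycle_location == 55

    def test_doubling_speed_effect_doubles_a2_response(self):
        """With a single-bump template aligned to the effect shape, the
        speed-induced change in extracted A2 scales exactly with the effect
        multiplier (closed-form bump arithmetic)."""
        a2 = next(d for d in default_definitions() if d.label == "A2")
        zero = {k: 0.0 for k in ("age", "stride_length", "height", "age_speed")}

        def a2_change(scale):
            cfg = GeneratorConfig(
                n_participants=2, n_studies=1, seed=6, noise_sd=0.0, study_sd=0.0,
                effect_scale={**zero, "speed": scale},
            )
            covs = simulate_covariates(cfg)
            covs["speed"] = [0.9, 1.5]
            truth = make_ground_truth(
                cfg,
                template_bumps={"ankle": (GaussianBump(55.0, 6.0, 2.3),)},
                beta_sex={"ankle": 0.0},
            )
            waves = simulate_waveforms(covs, truth, cfg, joints=("ankle",))
            vals = [extract(w, a2).value for w in waves]
            return vals[1] - vals[0]

        assert a2_change(2.0) == pytest.approx(2.0 * a2_change(1.0), rel=1e-9)

    def test_unknown_study_rejected(self):
        cfg = GeneratorConfig(n_participants=6, seed=2)
        covs = simulate_covariates(cfg)
        truth = make_ground_truth(cfg)
        covs.loc[0, "study_id"] = "study99"
        with pytest.raises(ValueError, match="unknown study_id"):
            simulate_waveforms(covs, truth, cfg)

    def test_covariate_outside_domain_rejected(self):
        cfg = GeneratorConfig(n_participants=6, seed=2)
        covs = simulate_covariates(cfg)
        truth = make_ground_truth(cfg)
        covs.loc[0, "speed"] = 3.5
        with pytest.raises(ValueError, match="outside truth domain"):
            simulate_waveforms(covs, truth, cfg)


class TestExportImport:
    def test_round_trip_full_precision(self, tmp_path):
        cfg = GeneratorConfig(n_participants=8, seed=11)
        covs, waves, truth = simulate_dataset(cfg)
        export_dataset(waves, covs, truth, tmp_path)
        waves2, covs2, truth2 = load_dataset(tmp_path)
        orig = {(w.participant_id, w.joint): w for w in waves}
        for w in waves2:
            np.testing.assert_array_equal(w.values, orig[(w.participant_id, w.joint)].values)
        pd.testing.assert_frame_equal(
            covs.sort_values("participant_id").reset_index(drop=True),
            covs2.sort_values("participant_id").reset_index(drop=True),
            check_dtype=False,
        )
        # truth round-trips through YAML
        np.testing.assert_allclose(
            truth.template("hip", FULL_GRID), truth2.template("hip", FULL_GRID)
        )
        for j in ("hip", "knee", "ankle"):
            np.testing.assert_allclose(truth.study_coefs[j], truth2.study_coefs[j])

    def test_row_count_arithmetic(self, tmp_path):
        cfg = GeneratorConfig(n_participants=7, seed=3)
        covs, waves, truth = simulate_dataset(cfg)
        export_dataset(waves, covs, truth, tmp_path)
        df = pd.read_csv(tmp_path / "waveforms.csv")
        assert len(df) == 7 * 3 * 101

    def test_missing_directory_error_names_path(self):
        cfg = GeneratorConfig(n_participants=6, seed=3)
        covs, waves, truth = simulate_dataset(cfg)
        with pytest.raises(FileNotFoundError, match="no/such/dir"):
            export_dataset(waves, covs, truth, "no/such/dir")

    def test_inconsistent_ids_rejected(self, tmp_path):
        cfg = GeneratorConfig(n_participants=6, seed=3)
        covs, waves, truth = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="unknown participants"):
            export_dataset(waves, covs.iloc[:3], truth, tmp_path)


def test_reference_decades_cover_lifespan():
    assert list(DECADE_REFERENCE["decade"]) == list(range(1, 10))
    assert list(DECADE_REFERENCE["age"]) == [5, 15, 25, 35, 45, 55, 65, 75, 85]
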