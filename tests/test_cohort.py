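"""Synthetic cohort generators: determinism, planted effects, ranges."""

import numpy as np
import pytest

from entropath import (
    CohortConfig,
    band_power,
    generate_behavior,
    generate_cohort,
    generate_eeg_recording,
    generate_outcome_changes,
    generate_parcel_timeseries,
    lzc_channel,
    preprocess,
)
from entropath.cohort import generate_latents


class TestConfigValidation:
    def test_defaults_are_study_conditions(self):
        cfg = CohortConfig()
        assert cfg.n_subjects == 28
        assert cfg.sampling_rate == 300.0
        assert cfg.recording_duration == 240.0
        assert len(cfg.channel_labels) == 19
        assert cfg.n_regions == 200

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 2},
            {"rho_within": 0.1, "rho_between": 0.3},
            {"modularity_wellbeing_r": -1.5},
            {"channel_labels": ("Fp1", "Fp1")},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_module_assignment_partitions_regions(self):
        cfg = CohortConfig(n_regions=202, n_modules=4)
        labels = cfg.module_assignment()
        assert labels.size == 202
        assert set(labels) == {0, 1, 2, 3}


class TestEegGeneration:
    def test_determinism(self, small_config):
        a = generate_eeg_recording(0.5, "25mg", "2h", small_config, seed=9)
        b = generate_eeg_recording(0.5, "25mg", "2h", small_config, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_unknown_labels_rejected(self, small_config):
        with pytest.raises(ValueError, match="condition"):
            generate_eeg_recording(0.0, "50mg", "2h", small_config, seed=0)
        with pytest.raises(ValueError, match="timepoint"):
            generate_eeg_recording(0.0, "25mg", "3h", small_config, seed=0)

    def test_baseline_is_alpha_dominated(self, small_config):
        rec = generate_eeg_recording(0.0, "1mg", "baseline", small_config, seed=1)
        bp = band_power(preprocess(rec))
        total = sum(v.sum() for v in bp.values())
        assert bp["alpha"].sum() / total > 0.5

    def test_active_dose_raises_entropy_and_lowers_alpha(self, small_config):
        """Same seed isolates the dose modulation: higher LZc, lower alpha."""
        lo = generate_eeg_recording(0.0, "1mg", "2h", small_config, seed=4)
        hi = generate_eeg_recording(0.0, "25mg", "2h", small_config, seed=4)
        ep_lo, ep_hi = preprocess(lo), preprocess(hi)
        assert lzc_channel(ep_hi, seed=0).mean() > lzc_channel(ep_lo, seed=0).mean()
        assert band_power(ep_hi)["alpha"].sum() < band_power(ep_lo)["alpha"].sum()

    def test_placebo_timepoints_unmodulated(self, small_config):
        base = generate_eeg_recording(1.0, "1mg", "baseline", small_config, seed=2)
        two_h = generate_eeg_recording(1.0, "1mg", "2h", small_config, seed=2)
        assert np.array_equal(base.data, two_h.data)


class TestBehavior:
    def test_slopes_recovered_by_ols_at_large_n(self):
        cfg = CohortConfig()
        z = np.random.default_rng(0).standard_normal(1000)
        df = generate_behavior(z, cfg, seed=1)
        truth = df.attrs["ground_truth"]
        ins, wb = truth["insight_std"], truth["wellbeing_change_std"]
        a_hat = np.polyfit(z, ins, 1)[0]
        X = np.column_stack([np.ones(1000), ins, z])
        beta = np.linalg.lstsq(X, wb, rcond=None)[0]
        assert abs(a_hat - cfg.entropy_effect_insight) < 0.05
        assert abs(beta[1] - cfg.insight_effect_wellbeing) < 0.05
        assert abs(beta[2] - cfg.direct_entropy_wellbeing) < 0.05

    def test_null_slopes_give_null_correlation(self):
        cfg = CohortConfig(
            entropy_effect_insight=0.0,
            insight_effect_wellbeing=0.0,
            direct_entropy_wellbeing=0.0,
        )
        n = 2000
        z = np.random.default_rng(1).standard_normal(n)
        df = generate_behavior(z, cfg, seed=2).query("condition=='25mg'")
        r = np.corrcoef(z, df["wellbeing_change"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_wellbeing_totals_within_instrument_range(self):
        cfg = CohortConfig()
        z = np.random.default_rng(2).standard_normal(500)
        df = generate_behavior(z, cfg, seed=3)
        for col in ("wellbeing_pre", "wellbeing_post"):
            assert df[col].between(14, 70).all()
        assert df["insight"].between(0, 600).all()

    def test_placebo_rows_carry_no_effect(self):
        cfg = CohortConfig()
        z = np.random.default_rng(3).standard_normal(2000)
        df = generate_behavior(z, cfg, seed=4).query("condition=='1mg'")
        assert abs(np.corrcoef(z, df["insight"])[0, 1]) < 0.07


class TestParcelTimeseries:
    def test_shape_and_determinism(self, small_config):
        ts = generate_parcel_timeseries(small_config, seed=5, n_samples=100)
        assert ts.shape == (60, 100)
        ts2 = generate_parcel_timeseries(small_config, seed=5, n_samples=100)
        assert np.array_equal(ts, ts2)

    def test_block_structure_in_sample_correlations(self):
        cfg = CohortConfig(n_regions=40, n_modules=4, rho_within=0.8, rho_between=0.1)
        ts = generate_parcel_timeseries(cfg, seed=6, n_samples=4000)
        r = np.corrcoef(ts)
        labels = cfg.module_assignment()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(40, dtype=bool)
        assert abs(r[same & off].mean() - 0.8) < 0.05
        assert abs(r[~same].mean() - 0.1) < 0.05

    def test_invalid_covariance_rejected(self):
        cfg = CohortConfig(n_regions=40, n_modules=4, rho_within=0.3, rho_between=0.05)
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_parcel_timeseries(cfg, modularity_shift=0.9, seed=0)

    def test_degenerate_two_samples_still_runs(self, small_config):
        from entropath import fc_matrix

        ts = generate_parcel_timeseries(small_config, seed=7, n_samples=2)
        w = fc_matrix(ts).w
        assert np.all(np.isfinite(w))


class TestOutcomeChanges:
    def test_shape_contract(self):
        cfg = CohortConfig()
        df = generate_outcome_changes(cfg, seed=8, n_subjects=25)
        assert df.shape == (25, 7)
        assert not df.isna().any().any()

    def test_cluster_members_correlate_nonmembers_do_not(self):
        cfg = CohortConfig()
        df = generate_outcome_changes(
            cfg, cluster_members=("wellbeing", "modularity", "DTI_AD", "insight"),
            cluster_r=0.6, seed=9, n_subjects=4000,
        )
        r = df.corr()
        assert abs(abs(r.loc["wellbeing", "modularity"]) - 0.6) < 0.05
        # planted signs: wellbeing up, modularity down
        assert r.loc["wellbeing", "modularity"] < 0
        assert abs(r.loc["EDS_errors", "amg_RSFC"]) < 0.05

    def test_invalid_inputs(self):
        cfg = CohortConfig()
        with pytest.raises(ValueError, match="cluster_r"):
            generate_outcome_changes(cfg, cluster_r=1.2, seed=0)
        with pytest.raises(ValueError, match="unknown outcomes"):
            generate_outcome_changes(cfg, cluster_members=("bogus",), seed=0)


class TestCohortAssembly:
    def test_latents_and_truth_align(self, small_config):
        coh = generate_cohort(small_config)
        assert coh.latents.shape == (28,)
        assert coh.truth.insight_std.shape == (28,)
        assert coh.truth.module_assignment.size == small_config.n_regions
        assert np.all(np.isfinite(coh.parcel_shifts))
        assert (coh.parcel_shifts >= 0).all()

    def test_lazy_recordings_are_reproducible(self, small_config):
        coh = generate_cohort(small_config)
        a = coh.eeg_recording(3, "25mg", "1h")
        b = coh.eeg_recording(3, "25mg", "1h")
        assert np.array_equal(a.data, b.data)

    def test_latents_deterministic_in_config_seed(self):
        cfg = CohortConfig(seed=77)
        assert np.array_equal(generate_latents(cfg), generate_latents(cfg))
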