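"""Synthetic-data generators: determinism, conservation, and calibration."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dynsurf.config import FARADAY, ConfigError, SimulationConfig
from dynsurf.echem import integrate_wave
from dynsurf.simulate import (
    gen_expression,
    gen_kinetics_series,
    gen_pattern_nuclei,
    gen_trajectories,
    gen_voltammogram,
    render_nuclei_images,
)


class TestPatternNuclei:
    def test_all_probability_one_labels_everything(self):
        c = SimulationConfig(
            seed=0,
            n_chips=2,
            nuclei_per_zone={0: 30, 1: 20},
            labeling_probability={0: 1.0, 1: 1.0},
        )
        rec = gen_pattern_nuclei(c)
        assert rec["labeled"].all()

    def test_deterministic_for_fixed_seed(self):
        c = SimulationConfig(seed=1, n_chips=2, nuclei_per_zone={0: 40, 1: 25})
        a = gen_pattern_nuclei(c)
        b = gen_pattern_nuclei(c)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        c = SimulationConfig(seed=1, n_chips=1, nuclei_per_zone={0: 40})
        d = c.with_seed(2)
        assert not gen_pattern_nuclei(c)[["x_um", "y_um"]].equals(
            gen_pattern_nuclei(d)[["x_um", "y_um"]]
        )

    def test_zone0_labeled_fraction_matches_bernoulli_mean(self, small_circle):
        """Pooled labeled fraction over 6 chips x >=200 zone-0 nuclei
        approximates the configured basal probability 0.275 (binomial
        expectation; exact Bernoulli mean is the oracle)."""
        from dynsurf.geometry import assign_zone

        rec = gen_pattern_nuclei(small_circle)
        zones = assign_zone(rec[["x_um", "y_um"]].to_numpy(), small_circle.pattern)
        zone0 = rec[zones == 0]
        assert zone0.groupby(rec["chip"]).size().min() >= 200
        assert zone0["labeled"].mean() == pytest.approx(0.275, abs=0.03)

    def test_minimum_separation_enforced(self):
        c = SimulationConfig(seed=3, n_chips=1, nuclei_per_zone={0: 50})
        rec = gen_pattern_nuclei(c, min_separation=6.0)
        xy = rec[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 6.0

    def test_undefined_zone_probability_is_config_error(self):
        c = SimulationConfig(seed=0, nuclei_per_zone={0: 10, 7: 5})
        with pytest.raises(ConfigError, match="zone"):
            gen_pattern_nuclei(c)


class TestRenderImages:
    def test_zero_nuclei_background_only(self):
        empty = pd.DataFrame(columns=["chip", "x_um", "y_um", "labeled"])
        img = render_nuclei_images(empty, noise_sd=0.0, background=100.0)
        assert np.all(img.dapi == 100.0) and np.all(img.brdu == 100.0)

    def test_single_nucleus_argmax_at_center(self):
        rec = pd.DataFrame({"chip": ["c"], "x_um": [32.0], "y_um": [32.0], "labeled": [True]})
        img = render_nuclei_images(
            rec, pixel_size=1.0, noise_sd=0.0, shape=(64, 64), origin=(0.0, 0.0)
        )
        r, c = np.unravel_index(np.argmax(img.dapi), img.dapi.shape)
        # position 32.0 um -> pixel center at index 31 or 32 (31.5 exactly between)
        assert abs((c + 0.5) - 32.0) <= 1.0 and abs((r + 0.5) - 32.0) <= 1.0

    def test_brdu_spots_subset_of_dapi(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "chip": "c",
                "x_um": rng.uniform(20, 200, 30),
                "y_um": rng.uniform(20, 200, 30),
                "labeled": rng.random(30) < 0.5,
            }
        )
        img = render_nuclei_images(rec, noise_sd=0.0, background=0.0)
        # everywhere, BrdU signal cannot exceed DAPI signal
        assert np.all(img.brdu <= img.dapi + 1e-9)

    def test_out_of_field_records_error_lists_offenders(self):
        rec = pd.DataFrame({"chip": ["c"], "x_um": [500.0], "y_um": [10.0], "labeled": [False]})
        with pytest.raises(ValueError, match="outside the field"):
            render_nuclei_images(rec, shape=(64, 64), origin=(0.0, 0.0))


class TestTrajectories:
    def test_zero_speed_stationary(self):
        c = SimulationConfig(seed=0, condition_speeds={"still": 0.0})
        (traj,) = gen_trajectories(c, "still", 1)
        assert np.all(traj.x == 0) and np.all(traj.y == 0)

    def test_high_persistence_near_straight_path(self):
        """With persistence -> 1 the path length approaches the net
        displacement (analytic straight-line oracle)."""
        c = SimulationConfig(seed=4, condition_speeds={"fast": 10.0}, persistence=0.999)
        (traj,) = gen_trajectories(c, "fast", 1)
        path = np.hypot(np.diff(traj.x), np.diff(traj.y)).sum()
        assert traj.net_displacement >= 0.95 * path

    def test_mean_step_matches_configured_speed(self, default_config):
        """Mean hourly displacement over >= 1000 steps within 2% of the
        configured speed (law of large numbers)."""
        c = replace(default_config, duration=100.0)
        trajs = gen_trajectories(c, "dynamic_linear", 12)
        steps = np.concatenate(
            [np.hypot(np.diff(t.x), np.diff(t.y)) for t in trajs]
        )
        assert len(steps) >= 1000
        assert steps.mean() == pytest.approx(12.3, rel=0.02)

    def test_unknown_condition_rejected(self, default_config):
        with pytest.raises(ConfigError, match="unknown condition"):
            gen_trajectories(default_config, "no_such_surface", 3)

    def test_deterministic_per_condition_and_cell(self, default_config):
        a = gen_trajectories(default_config, "dynamic_cyclic", 3)
        b = gen_trajectories(default_config, "dynamic_cyclic", 3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)


class TestVoltammogram:
    def test_zero_coverage_baseline_only(self):
        c = SimulationConfig(seed=0, coverage=0.0)
        vg = gen_voltammogram(c, "hydroquinone_quinone")
        ox = vg.segment("oxidation")
        # no faradaic peak: current is the linear capacitive baseline
        resid = ox.current_uA - np.polyval(
            np.polyfit(ox.potential_mV, ox.current_uA, 1), ox.potential_mV
        )
        assert np.abs(resid).max() < 1e-9

    def test_reductive_peak_at_320_mV(self, default_config):
        vg = gen_voltammogram(default_config, "hydroquinone_quinone")
        red = vg.segment("reduction")
        idx = np.argmin(red.current_uA)  # cathodic current is negative
        assert red.potential_mV[idx] == pytest.approx(320.0, abs=2.0)

    def test_reductive_charge_equals_nFA_coverage(self, default_config):
        """Trapezoid integration of the generated reductive wave after
        chord baseline subtraction reproduces Q = n F A Gamma within 0.5%."""
        vg = gen_voltammogram(default_config, "hydroquinone_quinone")
        q = integrate_wave(vg, (200.0, 440.0), "reduction")
        expected = 2 * FARADAY * 1.0 * 2.3e-10
        assert q == pytest.approx(expected, rel=0.005)
        assert expected == pytest.approx(4.439e-5, rel=1e-3)

    def test_missing_peak_definition_rejected(self, default_config):
        broken = replace(
            default_config,
            cv_peaks={"half": {"oxidation": default_config.cv_peaks["oxime"]["oxidation"]}},
        )
        with pytest.raises(ConfigError, match="reduction"):
            gen_voltammogram(broken, "half")
        with pytest.raises(ConfigError, match="unknown couple"):
            gen_voltammogram(default_config, "ferrocene")


class TestKinetics:
    def test_zero_time_zero_fraction(self, default_config):
        s = gen_kinetics_series(default_config, noise=0.0)
        assert s.fraction[0] == 0.0

    def test_half_life(self):
        """t1/2 = ln2 / k: at k = 0.04 min^-1 the series crosses 0.5 at
        17.33 min (closed form)."""
        c = SimulationConfig(seed=0, k_immob=0.04)
        s = gen_kinetics_series(c, timepoints=[np.log(2) / 0.04], noise=0.0)
        assert s.fraction[0] == pytest.approx(0.5, abs=1e-12)

    def test_negative_timepoints_rejected(self, default_config):
        with pytest.raises(ConfigError):
            gen_kinetics_series(default_config, timepoints=[-1.0, 0.0, 10.0])

    def test_noise_clipped_to_unit_interval(self):
        c = SimulationConfig(seed=5, k_immob=0.1)
        s = gen_kinetics_series(c, timepoints=np.linspace(0, 200, 40), noise=0.3)
        assert np.all((s.fraction >= 0) & (s.fraction <= 1))


class TestExpression:
    def test_null_generator_log_ratios_centered(self):
        c = SimulationConfig(seed=6, n_genes=400, de_fraction=0.0)
        m, truth = gen_expression(c)
        assert (truth["fold"] == 1.0).all()
        logratio = np.log2(m.sample.to_numpy() / m.reference.to_numpy())
        assert abs(logratio.mean()) < 0.02

    def test_deterministic(self):
        c = SimulationConfig(seed=7, n_genes=200)
        m1, t1 = gen_expression(c)
        m2, t2 = gen_expression(c)
        pd.testing.assert_frame_equal(m1.sample, m2.sample)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_truth_bookkeeping(self):
        c = SimulationConfig(seed=8, n_genes=1000, de_fraction=0.1)
        m, truth = gen_expression(c)
        planted = truth[truth["fold"] != 1.0]
        assert len(planted) == 100
        assert planted["condition"].isin(c.conditions).all()
        lo, hi = c.de_fold_range
        mag = np.maximum(planted["fold"], 1.0 / planted["fold"])
        assert ((mag >= lo) & (mag <= hi)).all()

    def test_bad_de_fraction_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            SimulationConfig(seed=0, de_fraction=1.5)
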