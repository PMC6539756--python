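"""Study drivers: geometries, signal synthesis, cube/tank/convergence runs."""

import numpy as np
import pandas as pd
import pytest

from braggloc.experiments import (
    TANK_GROUPS,
    cube_array,
    cube_sources_mm,
    run_convergence_study,
    run_cube_study,
    run_tank_study,
    run_timing_study,
    synthesize_received_signals,
    tank_array,
    tank_emitted_pulse,
    tank_source,
)
from braggloc.localization import SensorArray
from braggloc.tdoa import estimate_toa, gcc
from braggloc.thermoacoustic import WATER, PressureSignal

C = 1492.0
FS = 1.0e7


@pytest.fixture(scope="module")
def pulse():
    """The simulated emitted pulse (cached across the session)."""
    return tank_emitted_pulse(FS)


def _test_pulse(n=600, sigma_samples=10.0):
    k = np.arange(n)
    s = (k - n / 2) / sigma_samples
    return PressureSignal(samples=-s * np.exp(-0.5 * s * s), fs=FS)


class TestGeometries:
    def test_cube_layout_fractions(self):
        arr = cube_array(400.0)
        h = 0.4
        expected = np.array(
            [
                [h / 2, 0.0, 3 * h / 4],
                [0.0, h / 2, h / 2],
                [h / 2, h, h / 2],
                [h, h / 2, h / 4],
            ]
        )
        np.testing.assert_allclose(arr.positions, expected)

    def test_cube_sources(self):
        srcs = cube_sources_mm()
        np.testing.assert_array_equal(
            srcs, [[100, 100, 100], [100, 180, 150], [80, 100, 180]]
        )

    def test_tank_first_sensor(self):
        arr = tank_array()
        np.testing.assert_allclose(arr.positions[0], [0.705, 0.530, 0.310])
        assert arr.n_sensors == 12

    def test_tank_source(self):
        np.testing.assert_allclose(tank_source(), [0.54, 0.53, 0.38])

    def test_tank_groups_complete(self):
        assert set(TANK_GROUPS) == set(range(1, 11))
        assert TANK_GROUPS[10] == tuple(range(1, 13))
        assert all(len(v) >= 4 for v in TANK_GROUPS.values())

    def test_invalid_edge_rejected(self):
        with pytest.raises(ValueError):
            cube_array(-100.0)


class TestSynthesizeReceivedSignals:
    def test_geometric_delay_recovered(self):
        """Noiseless, distance 0.1 m: correlation delay 67.02 us +/- 1
        sample."""
        pulse = _test_pulse()
        pos = np.array(
            [[0.1, 0, 0], [0, 0.1, 0], [0, 0, 0.1], [0.1, 0.1, 0.0]]
        )
        arr = SensorArray(pos)
        sigs = synthesize_received_signals(
            pulse, np.zeros(3), arr, WATER, fs=FS, duration=500e-6,
            snr_db=None, seed=0,
        )
        toa = estimate_toa(pulse, sigs[0], subsample=False)
        assert toa == pytest.approx(0.1 / C, abs=1.0 / FS)

    def test_same_seed_bit_identical(self):
        pulse = _test_pulse()
        arr = cube_array(300.0)
        kw = dict(fs=FS, duration=500e-6, snr_db=10.0)
        s1 = synthesize_received_signals(pulse, np.array([0.1, 0.1, 0.1]),
                                         arr, WATER, seed=7, **kw)
        s2 = synthesize_received_signals(pulse, np.array([0.1, 0.1, 0.1]),
                                         arr, WATER, seed=7, **kw)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_snr_monotonicity(self, rng):
        """TOA RMS error strictly larger at 0 dB than at 40 dB."""
        pulse = _test_pulse()
        arr = cube_array(300.0)
        src = np.array([0.1, 0.1, 0.1])
        true_toas = np.linalg.norm(arr.positions - src, axis=1) / C
        rms = {}
        for snr in (0.0, 40.0):
            errs = []
            for rep in range(100):
                sigs = synthesize_received_signals(
                    pulse, src, arr, WATER, fs=FS, duration=500e-6,
                    snr_db=snr, seed=1000 + rep,
                )
                toa = estimate_toa(pulse, sigs[0])
                errs.append((toa - true_toas[0]) ** 2)
            rms[snr] = np.sqrt(np.mean(errs))
        assert rms[0.0] > rms[40.0]

    def test_amplitude_scales_inverse_distance(self):
        pulse = _test_pulse()
        pos = np.array(
            [[0.1, 0, 0], [0.2, 0, 0], [0, 0.1, 0], [0, 0, 0.1]]
        )
        arr = SensorArray(pos)
        sigs = synthesize_received_signals(
            pulse, np.zeros(3), arr, WATER, fs=FS, duration=500e-6,
            snr_db=None,
        )
        a1 = np.abs(sigs[0].samples).max()
        a2 = np.abs(sigs[1].samples).max()
        assert a1 / a2 == pytest.approx(2.0, rel=0.01)

    def test_duration_too_short_errors(self):
        pulse = _test_pulse()
        arr = cube_array(300.0)
        with pytest.raises(ValueError, match="us"):
            synthesize_received_signals(
                pulse, np.array([0.1, 0.1, 0.1]), arr, WATER, fs=FS,
                duration=1e-6, snr_db=None,
            )

    def test_fs_mismatch_errors(self):
        pulse = PressureSignal(samples=np.ones(100), fs=5e6)
        arr = cube_array(300.0)
        with pytest.raises(ValueError, match="Hz"):
            synthesize_received_signals(
                pulse, np.array([0.1, 0.1, 0.1]), arr, WATER, fs=FS,
                duration=500e-6,
            )


class TestConvergenceStudy:
    def test_start_at_truth_converges_immediately(self):
        src = np.array([0.1, 0.1, 0.1])
        arr = cube_array(400.0)
        from braggloc.localization import localize
        from braggloc.tdoa import tdoas_from_toas

        toas = np.linalg.norm(arr.positions - src, axis=1) / C
        res = localize(arr, tdoas_from_toas(toas), C, x0=src)
        assert res.converged
        assert res.iterations <= 2
        assert np.linalg.norm(res.position - src) < 1e-9

    def test_output_shape_and_determinism(self):
        r1 = run_convergence_study(n_sim=50, seed=5)
        r2 = run_convergence_study(n_sim=50, seed=5)
        assert len(r1.trials) == 50
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
        assert set(r1.trials.columns) >= {
            "start_dist_m", "final_error_m", "converged"
        }

    def test_fraction_non_increasing_with_bounds(self):
        arr = cube_array(400.0)
        src = np.array([0.1, 0.1, 0.1])
        span, cen = arr.span, arr.centroid
        fracs = []
        for k in (1.0, 4.0, 10.0):
            res = run_convergence_study(
                array=arr, source=src,
                bounds=(cen - k * span / 2, cen + k * span / 2),
                n_sim=400, seed=3,
            )
            fracs.append(res.summary["fraction_converged"][0])
        assert fracs[0] >= fracs[1] >= fracs[2]


class TestCubeStudy:
    def test_noiseless_exact(self):
        res = run_cube_study(
            h_list_mm=[400.0], toa_jitter_sigma=0.0, quantize=False,
            n_repeats=1, seed=0,
        )
        assert np.all(res.trials["error_mm"] < 1e-6)

    def test_noisy_within_five_mm(self):
        res = run_cube_study(n_repeats=5, seed=11)
        assert res.trials["error_mm"].max() <= 5.0
        assert res.trials["converged"].all()

    def test_summary_layout(self):
        res = run_cube_study(h_list_mm=[300.0, 400.0], n_repeats=3, seed=2)
        # one row per (source, H): 3 sources x 2 volumes
        assert len(res.summary) == 6
        for col in ("x_mean", "x_sd", "y_mean", "y_sd", "z_mean", "z_sd"):
            assert col in res.summary.columns

    def test_reproducible(self):
        r1 = run_cube_study(h_list_mm=[400.0], n_repeats=4, seed=9)
        r2 = run_cube_study(h_list_mm=[400.0], n_repeats=4, seed=9)
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
        assert r1.config.seed == 9

    def test_empty_h_list_rejected(self):
        with pytest.raises(ValueError):
            run_cube_study(h_list_mm=[])

    def test_source_outside_cube_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            run_cube_study(h_list_mm=[150.0], n_repeats=1, seed=0)


class TestTankStudy:
    def test_noiseless_recovery_sub_quantization(self, pulse):
        """Noiseless full chain recovers the source within 0.2 mm (one
        sample at 10 MS/s spans c/fs ~ 0.15 mm of range)."""
        res = run_tank_study(groups={10: TANK_GROUPS[10]}, snr_db=None,
                             n_repeats=1, seed=0)
        assert res.trials["error_mm"].max() < 0.2

    def test_twelve_sensors_sub_mm(self, pulse):
        res = run_tank_study(groups={10: TANK_GROUPS[10]}, snr_db=20.0,
                             n_repeats=10, seed=4)
        assert res.trials["error_mm"].median() < 1.0
        assert res.trials["error_mm"].max() < 5.0

    def test_one_sided_group_has_larger_offsets(self, pulse):
        """Group 3 (one-sided coverage) vs group 7 (surrounding)."""
        res = run_tank_study(
            groups={3: TANK_GROUPS[3], 7: TANK_GROUPS[7]},
            snr_db=20.0, n_repeats=15, seed=6,
        )
        t = res.trials
        src_z_cm = 38.0
        rms_z = t.groupby("group")["z_cm"].apply(
            lambda z: np.sqrt(np.mean((z - src_z_cm) ** 2))
        )
        assert rms_z[3] > rms_z[7]

    def test_small_group_rejected(self, pulse):
        with pytest.raises(ValueError, match="at least 4"):
            run_tank_study(groups={1: (1, 2, 3)}, n_repeats=1)

    def test_bad_index_rejected(self, pulse):
        with pytest.raises(ValueError, match="1..12"):
            run_tank_study(groups={1: (1, 2, 3, 13)}, n_repeats=1)

    def test_reproducible(self, pulse):
        r1 = run_tank_study(groups={7: TANK_GROUPS[7]}, n_repeats=2, seed=3)
        r2 = run_tank_study(groups={7: TANK_GROUPS[7]}, n_repeats=2, seed=3)
        pd.testing.assert_frame_equal(r1.trials, r2.trials)

    def test_summary_table4_layout(self, pulse):
        res = run_tank_study(
            groups={1: TANK_GROUPS[1], 10: TANK_GROUPS[10]},
            snr_db=20.0, n_repeats=3, seed=1,
        )
        assert list(res.summary["group"]) == [1, 10]
        assert list(res.summary["n_sensors"]) == [4, 12]
        for col in ("x_mean", "x_sd", "y_mean", "y_sd", "z_mean", "z_sd"):
            assert col in res.summary.columns


class TestTimingStudy:
    def test_shape_and_positive_times(self):
        table = run_timing_study(
            sensor_counts=(4, 6), h_list_mm=(300.0, 400.0), n_repeats=2
        )
        assert len(table) == 4  # one row per (count, H)
        assert (table["seconds"] > 0).all()

    def test_iteration_counts_deterministic(self):
        t1 = run_timing_study(sensor_counts=(4,), h_list_mm=(400.0,),
                              n_repeats=1, seed=2)
        t2 = run_timing_study(sensor_counts=(4,), h_list_mm=(400.0,),
                              n_repeats=1, seed=2)
        assert t1["iterations"].tolist() == t2["iterations"].tolist()


class TestEmittedPulse:
    def test_pulse_is_bipolar_and_arrives_on_time(self, pulse):
        p = pulse.samples
        imax, imin = int(np.argmax(p)), int(np.argmin(p))
        assert p[imax] > 0 > p[imin]
        assert imax < imin
        # arrival near 40 mm / 1492 m/s = 26.8 us
        assert pulse.times[imax] == pytest.approx(26.8e-6, abs=3e-6)

    def test_cached(self):
        assert tank_emitted_pulse(FS) is tank_emitted_pulse(FS)
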