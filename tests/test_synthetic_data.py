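"""Generator determinism, calibration, geometry and timing arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from synmorph.annotations_io import validate_dataset
from synmorph.classification import edge_distance_to_membrane
from synmorph.morphometry import aggregate_pools
from synmorph.synthetic_data import (
    FreezeTimingParams,
    GeneratorParams,
    aj_pit_mean,
    docked_mean,
    generate_dataset,
    generate_diameters,
    generate_paired_pulse,
    generate_profile,
    generate_profiles_dataset,
    generate_synapse,
    simulate_freeze_timing,
)


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        a = generate_dataset([None, 300.0], 3, seed=9)
        b = generate_dataset([None, 300.0], 3, seed=9)
        assert [d.model_dump() for d in a] == [d.model_dump() for d in b]

    def test_same_seed_same_profile(self):
        assert (generate_profile(50.0, seed=4).model_dump()
                == generate_profile(50.0, seed=4).model_dump())

    def test_same_seed_same_series_and_sample(self):
        pa, pb = generate_paired_pulse(seed=2), generate_paired_pulse(seed=2)
        assert np.array_equal(pa.y, pb.y)
        da = generate_diameters(50, seed=2)
        db = generate_diameters(50, seed=2)
        assert np.array_equal(da, db)


class TestCalibration:
    def test_refill_curve_anchors(self):
        assert docked_mean(None) == 2.5
        assert docked_mean(0.0) == pytest.approx(0.9)
        assert docked_mean(1e9) == pytest.approx(2.5)

    def test_unstimulated_docked_mean_near_reference(self):
        """1,000 unstimulated profiles: the normalized docked mean lands in
        the study's 2.5 ± 0.3 window."""
        ds = generate_profiles_dataset(None, 1000, seed=21)
        mean = aggregate_pools(ds).profile_summary.loc["docked_active_per_az", "mean"]
        assert 2.2 <= mean <= 2.8

    def test_depleted_docked_mean_near_reference(self):
        ds = generate_profiles_dataset(50.0, 1000, seed=22)
        mean = aggregate_pools(ds).profile_summary.loc["docked_active_per_az", "mean"]
        assert 0.7 <= mean <= 1.1

    def test_pit_time_course_peaks_at_300ms_and_decays(self):
        peak = aj_pit_mean(300.0)
        assert peak == pytest.approx(29 / 22)
        assert aj_pit_mean(100.0) < peak
        assert aj_pit_mean(300.0 + 1400.0) == pytest.approx(
            0.05 + (peak - 0.05) * np.exp(-1.0))

    def test_truncated_mixture_sample_mean_matches_numeric_oracle(self):
        """Sample mean of the >35 nm truncated 38/46 mixture vs the
        numerically integrated expectation."""
        d = generate_diameters(200, (38.0, 46.0), (3.0, 3.0), (0.5, 0.5),
                               seed=6, truncate_min=35.0)

        def density(x):
            return 0.5 * (stats.norm.pdf(x, 38, 3) + stats.norm.pdf(x, 46, 3))

        mass, _ = integrate.quad(density, 35, np.inf)
        mean_true, _ = integrate.quad(lambda x: x * density(x), 35, np.inf)
        mean_true /= mass
        assert 40.0 <= d.mean() <= 44.0
        assert d.mean() == pytest.approx(mean_true, abs=3 * d.std() / np.sqrt(len(d)))

    def test_zero_sd_collapses_to_mean(self):
        d = generate_diameters(20, (40.0,), (0.0,), seed=1)
        assert np.allclose(d, 40.0)


class TestGeometry:
    @pytest.mark.parametrize("timepoint", [None, 50.0])
    def test_membrane_pools_placed_at_consistent_distances(self, timepoint):
        """Docked vesicles touch the membrane (≤ 2 nm), tethered and 30-nm
        pool stay within 30 nm — so the generator is classifier-consistent."""
        syn = generate_synapse(timepoint, seed=31)
        for prof in syn.profiles:
            for v in prof.vesicles:
                prefix = v.id.split("-")[0]
                if prefix == "docked":
                    assert edge_distance_to_membrane(v, prof) <= 2.0
                elif prefix in ("tethered", "pool30"):
                    assert 2.0 < edge_distance_to_membrane(v, prof) <= 30.0
                elif prefix == "cytoplasmic":
                    assert edge_distance_to_membrane(v, prof) > 30.0

    def test_generated_datasets_validate(self):
        for ds in generate_dataset([None, 20.0, 300.0, 10000.0], 4, seed=17):
            assert validate_dataset(ds) == []
            for syn in ds.synapses:
                assert 4 <= len(syn.profiles) <= 6

    def test_zero_synapses_is_a_valid_empty_dataset(self):
        (ds,) = generate_dataset([300.0], 0, seed=1)
        assert ds.synapses == [] and validate_dataset(ds) == []


class TestPairedPulse:
    def test_full_recovery_limit_without_noise(self):
        params = GeneratorParams(pp_noise_sd=0.0)
        ts = generate_paired_pulse([50.0, 1000.0, 1e6], params, seed=0)
        assert ts.y[-1] == pytest.approx(1.0, abs=1e-4)
        assert np.all(np.diff(ts.y) > 0)

    def test_rejects_unsorted_intervals(self):
        with pytest.raises(ValueError):
            generate_paired_pulse([100.0, 50.0])


class TestFreezeTiming:
    def test_trigger_arithmetic_for_one_second(self):
        r = simulate_freeze_timing(1000.0, FreezeTimingParams(delay_jitter_halfwidth=0.0))
        assert r.trigger_offset == pytest.approx(822.0)
        assert r.realized_interval == pytest.approx(1000.0)

    def test_short_interval_triggers_before_the_light(self):
        r = simulate_freeze_timing(100.0, FreezeTimingParams(delay_jitter_halfwidth=0.0))
        assert r.trigger_offset == pytest.approx(-78.0)

    def test_jitter_spans_commanded_plus_minus_20ms_uniformly(self):
        rng = np.random.default_rng(3)
        realized = np.array([
            simulate_freeze_timing(100.0, seed=rng).realized_interval
            for _ in range(1000)
        ])
        dev = realized - 100.0
        assert dev.min() >= -20.0 and dev.max() <= 20.0
        assert dev.min() < -17.0 and dev.max() > 17.0
        # uniform spread: KS against U(-20, 20)
        ks = stats.kstest(dev, stats.uniform(loc=-20, scale=40).cdf)
        assert ks.pvalue > 0.01

    def test_negative_realized_interval_flagged(self):
        params = FreezeTimingParams(delay_jitter_halfwidth=0.0,
                                    command_to_pressure_delay=170.0)
        r = simulate_freeze_timing(1.0, params)
        assert not r.frozen_before_light  # exact timing: realized = commanded
        jittered = [simulate_freeze_timing(5.0, seed=s) for s in range(50)]
        assert any(r.frozen_before_light for r in jittered)
        assert all((r.realized_interval < 0) == r.frozen_before_light
                   for r in jittered)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            simulate_freeze_timing(0.0)
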