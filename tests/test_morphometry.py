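"""Distances, histograms, normalization, aggregation and group tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synmorph.morphometry import (
    NormalizationRefs,
    active_zone_length,
    aggregate_pools,
    bin_by_distance,
    compare_groups,
    distance_to_dense_projection_3d,
    normalize_count,
)

from conftest import make_dataset, make_profile, make_synapse, make_vesicle


class TestDenseProjectionDistance3D:
    def test_same_section_is_in_plane_distance(self, flat_synapse):
        v = make_vesicle(80.0, 20.0)  # 40 nm right of the DP edge, inside DP height
        flat_synapse.profiles[0].vesicles.append(v)
        assert distance_to_dense_projection_3d(v, flat_synapse) == pytest.approx(40.0)

    def test_three_sections_away_above_projection(self):
        profs = [make_profile(section_index=i, dp=(i == 0)) for i in range(4)]
        syn = make_synapse(profs)
        v = make_vesicle(0.0, 20.0)  # in-plane on top of the projected outline
        profs[3].vesicles.append(v)
        assert distance_to_dense_projection_3d(v, syn) == pytest.approx(99.0)

    def test_pythagorean_combination(self):
        profs = [make_profile(section_index=0), make_profile(section_index=1, dp=False)]
        syn = make_synapse(profs)
        v = make_vesicle(84.0, 20.0)  # 44 in-plane, 33 out-of-plane → 55
        profs[1].vesicles.append(v)
        assert distance_to_dense_projection_3d(v, syn) == pytest.approx(55.0)

    def test_never_below_in_plane_distance(self):
        rng = np.random.default_rng(2)
        profs = [make_profile(section_index=i) for i in range(3)]
        syn = make_synapse(profs)
        for _ in range(50):
            sec = int(rng.integers(3))
            v = make_vesicle(rng.uniform(-500, 500), rng.uniform(0, 300))
            profs[sec].vesicles.append(v)
            d3 = distance_to_dense_projection_3d(v, syn)
            d2 = distance_to_dense_projection_3d(v, make_synapse([profs[sec]]))
            assert d3 <= d2 + 1e-9  # the same-section outline is one candidate
            assert d3 >= 0


class TestDistanceBinning:
    def test_touching_goes_to_reserved_bin(self):
        h = bin_by_distance([10.0], touching=[True])
        assert h.counts[0] == 1 and h.n == 1

    def test_boundary_conventions(self):
        h = bin_by_distance([0.0, 32.999, 33.0], touching=[False, False, False])
        assert h.counts[0] == 0
        assert h.counts[1] == 2  # 0 and 32.999 share the first distance bin
        assert h.counts[2] == 1  # 33.0 starts the next half-open bin

    @given(st.lists(st.floats(0, 500), min_size=1, max_size=60),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_conserved(self, distances, seed):
        touching = np.random.default_rng(seed).random(len(distances)) < 0.3
        h = bin_by_distance(distances, touching)
        assert h.n == len(distances)

    def test_rejects_bad_bin_width(self):
        with pytest.raises(ValueError):
            bin_by_distance([1.0], bin_width=0.0)


class TestNormalization:
    @pytest.mark.parametrize("count,observed,expected",
                             [(5, 670.0, 5.0), (5, 335.0, 10.0), (0, 123.0, 0.0)])
    def test_reference_scaling(self, count, observed, expected):
        assert normalize_count(count, observed) == pytest.approx(expected)

    @given(st.floats(0, 50), st.floats(1, 5000), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_in_count_inverse_in_measure(self, count, observed, scale):
        base = normalize_count(count, observed)
        assert normalize_count(count * scale, observed) == pytest.approx(base * scale)
        assert normalize_count(count, observed * scale) == pytest.approx(base / scale)

    def test_rejects_nonpositive_measure(self):
        with pytest.raises(ValueError):
            normalize_count(1, 0.0)

    def test_active_zone_length_spans_projection_to_junctions(self, flat_profile):
        length, fallback = active_zone_length(flat_profile)
        assert length == pytest.approx((300 - 40) * 2)
        assert not fallback


class TestAggregation:
    def test_single_profile_mean_and_sem(self):
        vs = [make_vesicle(100.0 + i * 40, 14.0, vid=f"v{i}") for i in range(3)]
        ds = make_dataset([make_synapse([make_profile(vesicles=vs)])])
        counts = aggregate_pools(ds)
        row = counts.profile_summary.loc["docked_active"]
        assert row["mean"] == pytest.approx(3.0)
        assert row["sem"] == 0.0
        assert row["n"] == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pools(make_dataset([]))

    def test_invariant_to_profile_and_synapse_order(self, generated_unstimulated):
        import copy

        shuffled = copy.deepcopy(generated_unstimulated)
        rng = np.random.default_rng(0)
        rng.shuffle(shuffled.synapses)
        for syn in shuffled.synapses:
            rng.shuffle(syn.profiles)
        a = aggregate_pools(generated_unstimulated).profile_summary
        b = aggregate_pools(shuffled).profile_summary
        assert np.allclose(a["mean"], b["mean"], equal_nan=True)
        assert np.allclose(a["sem"], b["sem"], equal_nan=True)


def _enumeration_two_sided_p(a, b) -> float:
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating
    every assignment of the pooled sample to the two groups."""
    pooled = sorted(a) + sorted(b)
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y)
    u_lo = min(u_obs, len(a) * len(b) - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y)
        total += 1
        if min(u, n1 * len(b) - u) <= u_lo + 1e-12:
            count += 1
    return count / total


class TestGroupComparison:
    def test_separated_triplets_exact_p(self):
        rep = compare_groups([1, 2, 3], [4, 5, 6])
        assert rep.method == "exact"
        assert rep.p_value == pytest.approx(0.1)

    def test_bonferroni_threshold_for_seven_comparisons(self):
        rep = compare_groups([1, 2, 3], [4, 5, 6], n_comparisons=7, alpha=0.05)
        assert rep.adjusted_alpha == pytest.approx(0.05 / 7)
        assert round(rep.adjusted_alpha, 3) == 0.007

    def test_identical_samples_not_significant(self):
        rep = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.p_value >= 0.99
        assert not rep.significant

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (2, 5), (4, 4), (3, 6),
                                       (5, 5), (7, 3), (8, 8)])
    def test_exact_p_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = list(rng.normal(0, 1, n1))
        b = list(rng.normal(0.8, 1, n2))
        rep = compare_groups(a, b)
        assert rep.method == "exact"
        assert rep.p_value == pytest.approx(_enumeration_two_sided_p(a, b), abs=1e-9)

    def test_tied_small_samples_stay_exact(self):
        rep = compare_groups([1, 1, 2, 3], [2, 3, 3, 4])
        assert rep.method == "exact"
        assert rep.p_value == pytest.approx(
            _enumeration_two_sided_p([1, 1, 2, 3], [2, 3, 3, 4]), abs=1e-12)

    def test_single_observation_samples_supported(self):
        rep = compare_groups([1.0], [2.0, 2.0, 3.0])
        assert rep.method == "exact"
        assert 0.0 < rep.p_value <= 1.0

    def test_exact_agrees_with_scipy_on_untied_samples(self):
        from scipy import stats as ss
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = list(rng.normal(0, 1, int(rng.integers(2, 9))))
            b = list(rng.normal(0.5, 1, int(rng.integers(2, 9))))
            rep = compare_groups(a, b)
            ref = ss.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert rep.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(4)
        rep = compare_groups(rng.poisson(2.5, 100), rng.poisson(0.9, 100))
        assert rep.method == "asymptotic"
        assert rep.p_value < 1e-6 and rep.significant

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
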