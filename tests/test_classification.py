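"""Pool, zone, site and pit classification rules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from synmorph.annotations_io import Point
from synmorph.classification import (
    ClassificationParams,
    assign_site,
    assign_zone,
    classify_pit,
    classify_vesicle,
    edge_distance_to_membrane,
    pool_from_edge_distance,
)
from synmorph.synthetic_data import generate_synapse

from conftest import make_pit, make_profile, make_synapse, make_vesicle

PARAMS = ClassificationParams()


class TestEdgeDistance:
    def test_straight_membrane_offsets(self, flat_profile):
        assert edge_distance_to_membrane(
            make_vesicle(0.0, 50.0, diameter=30.0), flat_profile
        ) == pytest.approx(35.0)
        assert edge_distance_to_membrane(
            make_vesicle(0.0, 15.0, diameter=30.0), flat_profile
        ) == pytest.approx(0.0)

    def test_overlap_clamps_to_zero(self, flat_profile):
        assert edge_distance_to_membrane(
            make_vesicle(0.0, 5.0, diameter=30.0), flat_profile) == 0.0

    def test_agrees_with_point_sampled_brute_force(self):
        """Random circles vs a densely point-sampled polyline."""
        rng = np.random.default_rng(11)
        xs = np.linspace(-300, 300, 25)
        ys = 20 * np.sin(xs / 90.0)
        prof = make_profile()
        prof.membrane = [Point(x=float(x), y=float(y)) for x, y in zip(xs, ys)]
        # dense resampling of every segment
        seg = []
        for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
            t = np.linspace(0, 1, 400)
            seg.append(np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)]))
        dense = np.concatenate(seg)
        for _ in range(60):
            v = make_vesicle(rng.uniform(-280, 280), rng.uniform(-50, 150),
                             diameter=rng.uniform(20, 45))
            brute = max(
                np.min(np.hypot(dense[:, 0] - v.center.x, dense[:, 1] - v.center.y))
                - v.radius, 0.0)
            assert edge_distance_to_membrane(v, prof) == pytest.approx(brute, abs=0.1)


class TestPoolAndKind:
    @pytest.mark.parametrize(
        "diameter,y,core,tether,pool,kind",
        [
            (29.3, 29.3 / 2, "clear", False, "docked", "synaptic_vesicle"),
            (30.0, 35.0, "clear", True, "tethered", "synaptic_vesicle"),
            (30.0, 35.0, "clear", False, "pool30", "synaptic_vesicle"),
            (40.0, 220.0, "clear", False, "cytoplasmic", "large_vesicle"),
            (35.0, 220.0, "clear", False, "cytoplasmic", "synaptic_vesicle"),
            (40.0, 220.0, "dense", False, "cytoplasmic", "dense_core"),
        ],
    )
    def test_rule_table(self, flat_profile, diameter, y, core, tether, pool, kind):
        v = make_vesicle(100.0, y, diameter=diameter, core=core, tether=tether)
        label = classify_vesicle(v, flat_profile, PARAMS)
        assert (label.pool, label.kind) == (pool, kind)

    def test_every_vesicle_gets_exactly_one_pool(self, flat_profile):
        rng = np.random.default_rng(5)
        for _ in range(200):
            v = make_vesicle(rng.uniform(-900, 900), rng.uniform(10, 300),
                             diameter=rng.uniform(20, 45),
                             tether=bool(rng.integers(2)))
            label = classify_vesicle(v, flat_profile, PARAMS)
            assert label.pool in {"docked", "tethered", "pool30", "cytoplasmic"}

    def test_lowering_tether_threshold_never_creates_tethered(self):
        """Monotonicity: shrinking the 30 nm window can only lose members."""
        rng = np.random.default_rng(7)
        wide = ClassificationParams(tether_max_distance=30.0)
        narrow = ClassificationParams(tether_max_distance=12.0)
        for _ in range(300):
            d = rng.uniform(0, 60)
            if pool_from_edge_distance(d, True, wide) == "cytoplasmic":
                assert pool_from_edge_distance(d, True, narrow) == "cytoplasmic"

    def test_matches_brute_force_reimplementation(self, flat_profile):
        """1,000 random vesicles against an independent rule rewrite using
        point-sampled membrane distance."""
        rng = np.random.default_rng(13)
        xs = np.linspace(-1000, 1000, 40_001)  # 0.05 nm sampling of y = 0
        for _ in range(1000):
            v = make_vesicle(rng.uniform(-900, 900), rng.uniform(0, 120),
                             diameter=rng.uniform(18, 45),
                             core="dense" if rng.random() < 0.1 else "clear",
                             tether=bool(rng.integers(2)))
            d = max(np.min(np.hypot(xs - v.center.x, 0.0 - v.center.y)) - v.radius, 0.0)
            if v.core == "dense":
                kind = "dense_core"
            elif v.diameter > 35.0:
                kind = "large_vesicle"
            else:
                kind = "synaptic_vesicle"
            if d <= 2.0:
                pool = "docked"
            elif d <= 30.0:
                pool = "tethered" if v.tether_observed else "pool30"
            else:
                pool = "cytoplasmic"
            label = classify_vesicle(v, flat_profile, PARAMS)
            assert (label.pool, label.kind) == (pool, kind)


class TestZones:
    def test_between_dense_projection_and_junction_is_active(self, flat_profile):
        v = make_vesicle(170.0, 15.0)  # midway between DP edge (40) and AJ (300)
        assert assign_zone(v, flat_profile).zone == "active_zone"

    def test_beyond_junction_is_perisynaptic(self, flat_profile):
        v = make_vesicle(450.0, 15.0)
        assert assign_zone(v, flat_profile).zone == "perisynaptic"

    def test_boundary_assigned_inward(self, flat_profile):
        v = make_vesicle(300.0, 15.0)  # exactly at the junction mark
        assert assign_zone(v, flat_profile).zone == "active_zone"

    def test_missing_junction_flags_membrane_end(self):
        prof = make_profile(aj_x=(-300.0,))  # right side unmarked
        label = assign_zone(make_vesicle(600.0, 15.0), prof)
        assert label.zone == "active_zone"
        assert label.boundary_from_membrane_end

    def test_profile_without_dense_projection_borrows_nearest(self):
        bare = make_profile(section_index=1, dp=False)
        full = make_profile(section_index=0)
        syn = make_synapse([full, bare])
        assert assign_zone(make_vesicle(100.0, 15.0), bare, syn).zone == "active_zone"


class TestSites:
    def test_near_dense_projection(self, flat_synapse):
        v = make_vesicle(100.0, 20.0, diameter=40.0)  # 60 nm from the DP edge
        prof = flat_synapse.profiles[0]
        assert assign_site(v, flat_synapse, profile=prof).site == "dense_projection"

    def test_near_adherens_junction(self, flat_synapse):
        v = make_vesicle(300.0, 40.0, diameter=40.0)  # 40 from AJ, 260 from DP
        prof = flat_synapse.profiles[0]
        assert assign_site(v, flat_synapse, profile=prof).site == "adherens_junction"

    def test_far_from_both_is_interior(self, flat_synapse):
        v = make_vesicle(190.0, 150.0, diameter=40.0)
        prof = flat_synapse.profiles[0]
        assert assign_site(v, flat_synapse, profile=prof).site == "interior"

    def test_precedence_dense_projection_and_flagged(self):
        """A structure inside both radii is attributed to the dense
        projection (never double-counted) and the overlap is flagged."""
        prof = make_profile(aj_x=(-130.0, 130.0))
        syn = make_synapse([prof])
        v = make_vesicle(95.0, 20.0, diameter=40.0)  # 55 from DP edge, 41 from AJ
        label = assign_site(v, syn, profile=prof)
        assert label.site == "dense_projection"
        assert label.in_both_radii


class TestPits:
    def test_vesicle_sized_pit_in_active_zone_is_exocytic(self, flat_synapse):
        p = make_pit(150.0, width=28.4, depth=14.0)
        prof = flat_synapse.profiles[0]
        assert classify_pit(p, prof, flat_synapse) == "exocytic"

    def test_wide_shallow_pit_at_junction_is_shallow_endocytic(self, flat_synapse):
        p = make_pit(300.0, width=44.0, depth=10.0)
        prof = flat_synapse.profiles[0]
        assert classify_pit(p, prof, flat_synapse) == "shallow_endocytic"

    def test_hemisphere_depth_at_junction_is_deep_endocytic(self, flat_synapse):
        p = make_pit(300.0, width=44.0, depth=40.0)
        prof = flat_synapse.profiles[0]
        assert classify_pit(p, prof, flat_synapse) == "deep_endocytic"


class TestGeneratorAgreement:
    """The generator writes its intended label into each structure id; the
    classifier must reproduce every one of them."""

    @pytest.mark.parametrize("timepoint", [None, 20.0, 300.0, 3000.0])
    def test_labels_recovered_exactly(self, timepoint):
        expected_pools = {"docked", "tethered", "pool30", "cytoplasmic"}
        syn = generate_synapse(timepoint, seed=int(timepoint or 0) + 1)
        checked = 0
        for prof in syn.profiles:
            for v in prof.vesicles:
                prefix = v.id.split("-")[0]
                label = classify_vesicle(v, prof, PARAMS)
                if prefix in expected_pools:
                    assert label.pool == prefix, v.id
                    assert label.kind == "synaptic_vesicle"
                elif prefix == "cytoplasmic":
                    assert label.pool == "cytoplasmic"
                elif prefix == "dense_core":
                    assert label.kind == "dense_core"
                elif prefix in {"interior_lv", "dp_lv", "aj_lv"}:
                    assert label.kind == "large_vesicle", v.id
                    site = assign_site(v, syn, PARAMS, profile=prof).site
                    expected_site = {"interior_lv": "interior",
                                     "dp_lv": "dense_projection",
                                     "aj_lv": "adherens_junction"}[prefix]
                    assert site == expected_site, v.id
                else:
                    raise AssertionError(f"unknown generator id {v.id}")
                checked += 1
            for p in prof.pits:
                prefix = p.id.split("-")[0]
                cls = classify_pit(p, prof, syn, PARAMS)
                if prefix == "exo_pit":
                    assert cls == "exocytic", p.id
                elif prefix == "aj_pit":
                    assert cls == "shallow_endocytic", p.id
                checked += 1
        assert checked > 0
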