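"""Seeded generator of annotation datasets with the study's statistical
structure.

No public archive of the annotated serial-section data exists, so every
analysis here is exercised on synthetic datasets that emulate the printed
summary statistics of the flash-and-freeze experiment:

* docked vesicles per profile follow the refill curve
  ``m(t) = 2.5 − (2.5 − 0.9)·exp(−t / 2.4 s)`` (unstimulated mean 2.5);
* tethered vesicles dip from 3.1 to 2.6 and recover on the same time scale;
* dense-projection large vesicles peak at 50 ms; adherens-junction shallow
  pits peak at 300 ms and resolve with τ = 1.4 s;
* synaptic-vesicle diameters center on 29.3 nm; large-vesicle diameters are
  a 38 / 46 nm mixture;
* adherens junctions sit 250–350 nm from the dense projection on the near
  side, with a long muscle-facing side reaching ~1 µm; profile areas center
  on 60,700 nm².

Counts are Poisson around the timepoint means.  Zone counts scale with the
profile's actual active-zone length (and whole-profile counts with its
area), so both the raw and the geometry-normalized per-profile means equal
the configured values in expectation.  Generated structures are placed
geometrically so the classifier reproduces the generating label exactly —
the key cross-module invariant.

A small timing simulator reproduces the flash-and-freeze trigger
arithmetic: freezing starts ``delay + 8 ms`` after the freezer's start
signal, with the delay nominally 170 ms but jittered by ±20 ms, so the
realized stimulus-to-freeze interval must be reconstructed post hoc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .annotations_io import (
    ConditionDataset,
    PitAnnotation,
    Point,
    ProfileAnnotation,
    SynapseReconstruction,
    VesicleAnnotation,
)
from .kinetics import TimeSeries

Timepoint = Optional[float]  # ms; None = unstimulated


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _construct(cls, kw: dict):
    # hot path: bare pydantic instance, no validation or per-field loop
    m = cls.__new__(cls)
    object.__setattr__(m, "__dict__", kw)
    object.__setattr__(m, "__pydantic_fields_set__", set(kw))
    object.__setattr__(m, "__pydantic_extra__", {})
    object.__setattr__(m, "__pydantic_private__", None)
    return m


def _pt(x, y) -> Point:
    return _construct(Point, {"x": float(x), "y": float(y)})


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition defaults for the synthetic generator.

    Pool means are per profile (docked/tethered, geometry-calibrated) or per
    synapse (endocytic structures); times in ms, lengths nm, areas nm².
    """

    # docked-pool refill curve (per profile, active zone)
    docked_unstimulated: float = 2.5
    docked_depleted: float = 0.9
    docked_recovery_tau: float = 2400.0
    # tethered pool (per profile, active zone)
    tethered_unstimulated: float = 3.1
    tethered_depleted: float = 2.6
    # pools without printed anchors (documented choices)
    pool30_mean: float = 1.5
    perisynaptic_docked_mean: float = 0.5
    cytoplasmic_sv_mean: float = 20.0
    dense_core_mean: float = 0.5
    # endocytic-structure time courses (piecewise-linear anchors, ms → mean)
    dp_large_vesicle_anchors: tuple = (
        (0.0, 0.1), (20.0, 0.8), (30.0, 1.2), (50.0, 1.5), (100.0, 1.0),
        (300.0, 14 / 22), (1000.0, 25 / 23), (3000.0, 0.3), (10000.0, 0.1),
    )
    dp_large_vesicle_unstimulated: float = 0.1
    aj_pit_peak_time: float = 300.0
    aj_pit_peak_mean: float = 29 / 22
    aj_pit_decay_tau: float = 1400.0
    aj_pit_baseline: float = 0.05
    aj_pit_rise_anchors: tuple = ((0.0, 0.0), (50.0, 0.05), (100.0, 0.5))
    aj_large_vesicle_anchors: tuple = (
        (0.0, 0.02), (100.0, 0.05), (300.0, 0.1), (1000.0, 4 / 23),
        (3000.0, 0.6), (10000.0, 0.1),
    )
    aj_large_vesicle_unstimulated: float = 0.02
    interior_large_vesicle_anchors: tuple = (
        (0.0, 0.05), (50.0, 0.1), (100.0, 0.5), (300.0, 0.5),
        (1000.0, 0.3), (3000.0, 0.1), (10000.0, 0.3),
    )
    interior_large_vesicle_unstimulated: float = 0.05
    exocytic_pit_anchors: tuple = ((0.0, 0.0), (20.0, 17 / 50), (30.0, 0.1), (40.0, 0.0))
    # diameters (nm)
    sv_diameter_mean: float = 29.3
    sv_diameter_sd: float = 2.0
    diameter_floor: float = 15.0
    large_vesicle_means: tuple = (38.0, 46.0)
    large_vesicle_sds: tuple = (3.0, 3.0)
    large_vesicle_weights: tuple = (0.7, 0.3)
    large_vesicle_floor: float = 35.0
    dense_core_diameter_mean: float = 40.0
    dense_core_diameter_sd: float = 3.0
    exocytic_pit_width_mean: float = 28.4
    exocytic_pit_width_sd: float = 2.0
    # geometry (nm, nm²)
    aj_near_range: tuple = (250.0, 350.0)
    aj_far_extra_range: tuple = (350.0, 1000.0)
    aj_far_extra_prob: float = 0.4  # makes E[active-zone length] = 670 nm
    dp_half_width: float = 40.0
    dp_height: float = 40.0
    membrane_margin: float = 200.0
    membrane_vertex_spacing: float = 50.0
    membrane_wave_amplitude: float = 4.0
    membrane_wave_length: float = 600.0
    profile_area_mean: float = 60_700.0
    profile_area_sd: float = 12_000.0
    profile_area_floor: float = 30_000.0
    typical_active_zone_length: float = 670.0
    typical_profile_area: float = 60_700.0
    # paired-pulse recovery
    pp_amp_fast: float = 0.3
    pp_tau_fast: float = 100.0
    pp_amp_slow: float = 0.5
    pp_tau_slow: float = 2200.0
    pp_noise_sd: float = 0.05
    # reconstruction size
    profiles_per_synapse: tuple = (4, 6)


@dataclass(frozen=True)
class FreezeTimingParams:
    """Flash-and-freeze trigger timing (ms)."""

    command_to_pressure_delay: float = 170.0
    delay_jitter_halfwidth: float = 20.0
    pressure_to_freeze: float = 8.0

    def __post_init__(self) -> None:
        if min(self.command_to_pressure_delay, self.delay_jitter_halfwidth,
               self.pressure_to_freeze) < 0:
            raise ValueError("timing parameters must be ≥ 0")


#: Per-timepoint profile counts of the docked-pool recovery experiment
#: (ms → number of profiles), plus the unstimulated control.
RECOVERY_TIMEPOINT_PROFILES: dict[Optional[float], int] = {
    None: 102, 20.0: 50, 50.0: 104, 100.0: 83, 300.0: 89,
    1000.0: 111, 3000.0: 91, 10000.0: 121,
}

#: Per-timepoint synapse counts of the endocytic-structure time course
#: (ms → number of reconstructed synapses).
ENDOCYTOSIS_TIMEPOINT_SYNAPSES: dict[Optional[float], int] = {
    None: 26, 20.0: 12, 30.0: 12, 50.0: 24, 100.0: 19,
    300.0: 20, 1000.0: 23, 3000.0: 19, 10000.0: 26,
}

#: Inter-pulse intervals (ms) spanning the paired-pulse protocol's range.
PAIRED_PULSE_INTERVALS: tuple = (
    50.0, 100.0, 300.0, 500.0, 1000.0, 2000.0, 3000.0, 5000.0, 10000.0, 15000.0
)


# ---------------------------------------------------------------------------
# Mean time courses


def docked_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    """Docked vesicles per profile: the refill curve, or the unstimulated mean."""
    if timepoint is None:
        return params.docked_unstimulated
    y0, yinf, tau = (params.docked_depleted, params.docked_unstimulated,
                     params.docked_recovery_tau)
    return yinf - (yinf - y0) * math.exp(-timepoint / tau)


def tethered_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    if timepoint is None:
        return params.tethered_unstimulated
    y0, yinf, tau = (params.tethered_depleted, params.tethered_unstimulated,
                     params.docked_recovery_tau)
    return yinf - (yinf - y0) * math.exp(-timepoint / tau)


def _interp(anchors: tuple, t: float) -> float:
    ts = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    return float(np.interp(t, ts, ys))


def aj_pit_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    """Adherens-junction shallow pits per synapse: linear rise to the 300 ms
    peak, then exponential resolution with τ = 1.4 s toward the baseline."""
    if timepoint is None:
        return params.aj_pit_rise_anchors[0][1]
    if timepoint <= params.aj_pit_peak_time:
        anchors = params.aj_pit_rise_anchors + ((params.aj_pit_peak_time,
                                                 params.aj_pit_peak_mean),)
        return _interp(anchors, timepoint)
    b = params.aj_pit_baseline
    return b + (params.aj_pit_peak_mean - b) * math.exp(
        -(timepoint - params.aj_pit_peak_time) / params.aj_pit_decay_tau)


def dp_large_vesicle_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    if timepoint is None:
        return params.dp_large_vesicle_unstimulated
    return _interp(params.dp_large_vesicle_anchors, timepoint)


def aj_large_vesicle_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    if timepoint is None:
        return params.aj_large_vesicle_unstimulated
    return _interp(params.aj_large_vesicle_anchors, timepoint)


def interior_large_vesicle_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    if timepoint is None:
        return params.interior_large_vesicle_unstimulated
    return _interp(params.interior_large_vesicle_anchors, timepoint)


def exocytic_pit_mean(timepoint: Timepoint, params: GeneratorParams = GeneratorParams()) -> float:
    if timepoint is None:
        return 0.0
    return _interp(params.exocytic_pit_anchors, timepoint)


# ---------------------------------------------------------------------------
# Geometry helpers


@dataclass
class _SynapseGeometry:
    """Per-synapse layout shared by its profiles: adherens junctions at
    ±(near, far) from the dense projection at x = 0."""

    aj_left: float   # negative x
    aj_right: float  # positive x


def _sample_geometry(params: GeneratorParams, rng: np.random.Generator) -> _SynapseGeometry:
    near = rng.uniform(*params.aj_near_range)
    if rng.random() < params.aj_far_extra_prob:
        far = rng.uniform(*params.aj_far_extra_range)
    else:
        far = rng.uniform(*params.aj_near_range)
    if rng.random() < 0.5:
        near, far = far, near
    return _SynapseGeometry(aj_left=-near, aj_right=far)


class _Membrane:
    """A gently waving, cleft-facing membrane polyline with fast y(x) lookup."""

    def __init__(self, geom: _SynapseGeometry, params: GeneratorParams,
                 rng: np.random.Generator):
        x0 = geom.aj_left - params.membrane_margin
        x1 = geom.aj_right + params.membrane_margin
        n = max(int((x1 - x0) / params.membrane_vertex_spacing) + 1, 2)
        self.xs = np.linspace(x0, x1, n)
        phase = rng.uniform(0, 2 * math.pi)
        self.ys = params.membrane_wave_amplitude * np.sin(
            2 * math.pi * self.xs / params.membrane_wave_length + phase
        ) + rng.normal(0.0, 0.3, n)

    def y_at(self, x: float) -> float:
        return float(np.interp(x, self.xs, self.ys))

    def points(self) -> list[Point]:
        return [Point(x=float(x), y=float(y)) for x, y in zip(self.xs, self.ys)]


def _sv_diameter(params: GeneratorParams, rng: np.random.Generator) -> float:
    while True:
        d = rng.normal(params.sv_diameter_mean, params.sv_diameter_sd)
        if params.diameter_floor <= d <= params.large_vesicle_floor:
            return d


def _lv_diameter(params: GeneratorParams, rng: np.random.Generator) -> float:
    w = np.asarray(params.large_vesicle_weights, dtype=float)
    w = w / w.sum()
    while True:
        i = rng.choice(len(w), p=w)
        d = rng.normal(params.large_vesicle_means[i], params.large_vesicle_sds[i])
        if d > params.large_vesicle_floor:
            return d


# ---------------------------------------------------------------------------
# Profile / dataset generation


def generate_profile(
    timepoint: Timepoint,
    params: GeneratorParams = GeneratorParams(),
    seed: Union[int, np.random.Generator] = 0,
    section_index: int = 0,
    geometry: Optional[_SynapseGeometry] = None,
) -> ProfileAnnotation:
    """One synthetic section at the given post-stimulus timepoint.

    Vesicle counts are Poisson around the timepoint means; zone counts scale
    with the profile's active-zone length (area counts with its area) so
    normalized per-profile means hit the configured values exactly in
    expectation.  Docked vesicles are placed touching the membrane, tethered
    and 30-nm-pool vesicles within 30 nm, cytoplasmic ones well beyond — the
    classifier recovers the generating labels.
    """
    rng = _rng(seed)
    geom = geometry or _sample_geometry(params, rng)
    mem = _Membrane(geom, params, rng)
    hw, h = params.dp_half_width, params.dp_height

    dp = [
        Point(x=-hw, y=mem.y_at(-hw)),
        Point(x=hw, y=mem.y_at(hw)),
        Point(x=hw, y=mem.y_at(hw) + h),
        Point(x=-hw, y=mem.y_at(-hw) + h),
    ]
    ajs = [Point(x=geom.aj_left, y=mem.y_at(geom.aj_left)),
           Point(x=geom.aj_right, y=mem.y_at(geom.aj_right))]

    az_length = (-hw - geom.aj_left) + (geom.aj_right - hw)
    az_scale = az_length / params.typical_active_zone_length
    area = max(rng.normal(params.profile_area_mean, params.profile_area_sd),
               params.profile_area_floor)
    area_scale = area / params.typical_profile_area

    vesicles: list[VesicleAnnotation] = []
    pits: list[PitAnnotation] = []
    counter = 0

    def new_id(prefix: str) -> str:
        # id prefix records the generating label for recovery tests
        nonlocal counter
        counter += 1
        return f"{prefix}-{section_index}-{counter}"

    def az_foot_x() -> float:
        # membrane-proximal slot in the active zone, clear of the dense projection
        left = rng.random() < (-hw - geom.aj_left) / az_length
        if left:
            return rng.uniform(geom.aj_left + 5, -hw - 25)
        return rng.uniform(hw + 25, geom.aj_right - 5)

    def add_membrane_vesicle(pool: str, x: float) -> None:
        d = _sv_diameter(params, rng)
        if pool == "docked":
            edge = rng.uniform(0.2, 1.6)
        else:
            edge = rng.uniform(4.0, 28.0)
        vesicles.append(_construct(VesicleAnnotation, dict(
            id=new_id(pool),
            center=_pt(x, mem.y_at(x) + float(d) / 2 + edge),
            diameter=float(d), core="clear",
            tether_observed=(pool == "tethered"),
        )))

    for _ in range(rng.poisson(docked_mean(timepoint, params) * az_scale)):
        add_membrane_vesicle("docked", az_foot_x())
    for _ in range(rng.poisson(tethered_mean(timepoint, params) * az_scale)):
        add_membrane_vesicle("tethered", az_foot_x())
    for _ in range(rng.poisson(params.pool30_mean * az_scale)):
        add_membrane_vesicle("pool30", az_foot_x())
    for _ in range(rng.poisson(params.perisynaptic_docked_mean)):
        side = rng.random() < 0.5
        x = (rng.uniform(geom.aj_left - params.membrane_margin + 20, geom.aj_left - 10)
             if side else
             rng.uniform(geom.aj_right + 10, geom.aj_right + params.membrane_margin - 20))
        add_membrane_vesicle("docked", x)

    x_lo, x_hi = mem.xs[0] + 20, mem.xs[-1] - 20
    for _ in range(rng.poisson(params.cytoplasmic_sv_mean * area_scale)):
        vesicles.append(_construct(VesicleAnnotation, dict(
            id=new_id("cytoplasmic"),
            center=_pt(rng.uniform(x_lo, x_hi), rng.uniform(65.0, 300.0)),
            diameter=float(_sv_diameter(params, rng)), core="clear", tether_observed=False,
        )))
    for _ in range(rng.poisson(params.dense_core_mean)):
        d = max(rng.normal(params.dense_core_diameter_mean, params.dense_core_diameter_sd),
                params.diameter_floor)
        vesicles.append(_construct(VesicleAnnotation, dict(
            id=new_id("dense_core"),
            center=_pt(rng.uniform(x_lo, x_hi), rng.uniform(65.0, 300.0)),
            diameter=float(d), core="dense", tether_observed=False,
        )))
    for _ in range(rng.poisson(interior_large_vesicle_mean(timepoint, params))):
        vesicles.append(_construct(VesicleAnnotation, dict(
            id=new_id("interior_lv"),
            center=_pt(rng.uniform(x_lo, x_hi), rng.uniform(160.0, 300.0)),
            diameter=float(_lv_diameter(params, rng)), core="clear", tether_observed=False,
        )))

    for _ in range(rng.poisson(exocytic_pit_mean(timepoint, params))):
        w = max(rng.normal(params.exocytic_pit_width_mean, params.exocytic_pit_width_sd), 20.0)
        depth = rng.uniform(0.35 * w, 0.48 * w)
        x = az_foot_x()
        # keep the synaptic-vesicle-sized pit clear of the adherens junctions
        x = min(max(x, geom.aj_left + 80), geom.aj_right - 80)
        y = mem.y_at(x)
        pits.append(_construct(PitAnnotation, dict(
            id=new_id("exo_pit"),
            apex=_pt(x, y + depth),
            mouth_left=_pt(x - w / 2, mem.y_at(x - w / 2)),
            mouth_right=_pt(x + w / 2, mem.y_at(x + w / 2)),
            width=float(w), depth=float(depth),
        )))

    return _construct(ProfileAnnotation, dict(
        section_index=section_index,
        membrane=mem.points(),
        dense_projection=dp,
        adherens_junctions=ajs,
        vesicles=vesicles,
        pits=pits,
        profile_area=float(area),
    ))


def _add_dp_large_vesicle(prof: ProfileAnnotation, params: GeneratorParams,
                          rng: np.random.Generator, tag: str) -> None:
    d = _lv_diameter(params, rng)
    side = 1.0 if rng.random() < 0.5 else -1.0
    x = side * (params.dp_half_width + rng.uniform(15.0, 85.0))
    y = d / 2 + rng.uniform(2.0, 40.0)
    prof.vesicles.append(_construct(VesicleAnnotation, dict(
        id=tag, center=_pt(x, y), diameter=float(d),
        core="clear", tether_observed=False)))


def _add_aj_large_vesicle(prof: ProfileAnnotation, geom: _SynapseGeometry,
                          params: GeneratorParams, rng: np.random.Generator,
                          tag: str) -> None:
    d = _lv_diameter(params, rng)
    x_aj = geom.aj_left if rng.random() < 0.5 else geom.aj_right
    prof.vesicles.append(_construct(VesicleAnnotation, dict(
        id=tag,
        center=_pt(x_aj + rng.uniform(-20.0, 20.0),
                   rng.uniform(d / 2 + 2.0, 40.0)),
        diameter=float(d), core="clear", tether_observed=False)))


def _add_aj_pit(prof: ProfileAnnotation, geom: _SynapseGeometry,
                params: GeneratorParams, rng: np.random.Generator, tag: str) -> None:
    w = rng.uniform(40.0, 50.0)
    depth = rng.uniform(8.0, 0.45 * w)
    x_aj = geom.aj_left if rng.random() < 0.5 else geom.aj_right
    x = x_aj + rng.uniform(-15.0, 15.0)
    ys = {p.x: p.y for p in prof.membrane}
    xs = np.array(sorted(ys))
    yv = np.array([ys[x_] for x_ in xs])

    def y_at(q: float) -> float:
        return float(np.interp(q, xs, yv))

    prof.pits.append(_construct(PitAnnotation, dict(
        id=tag,
        apex=_pt(x, y_at(x) + depth),
        mouth_left=_pt(x - w / 2, y_at(x - w / 2)),
        mouth_right=_pt(x + w / 2, y_at(x + w / 2)),
        width=float(w), depth=float(depth),
    )))


def generate_synapse(
    timepoint: Timepoint,
    params: GeneratorParams = GeneratorParams(),
    seed: Union[int, np.random.Generator] = 0,
    synapse_id: str = "syn0",
) -> SynapseReconstruction:
    """One reconstruction of 4–6 contiguous profiles sharing a geometry,
    with per-synapse endocytic structures placed at their sites."""
    rng = _rng(seed)
    geom = _sample_geometry(params, rng)
    lo, hi = params.profiles_per_synapse
    n_prof = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, 1000))
    profiles = [
        generate_profile(timepoint, params, rng, section_index=start + i, geometry=geom)
        for i in range(n_prof)
    ]
    for i in range(rng.poisson(dp_large_vesicle_mean(timepoint, params))):
        prof = profiles[rng.integers(n_prof)]
        _add_dp_large_vesicle(prof, params, rng, f"dp_lv-{i}")
    for i in range(rng.poisson(aj_large_vesicle_mean(timepoint, params))):
        prof = profiles[rng.integers(n_prof)]
        _add_aj_large_vesicle(prof, geom, params, rng, f"aj_lv-{i}")
    for i in range(rng.poisson(aj_pit_mean(timepoint, params))):
        prof = profiles[rng.integers(n_prof)]
        _add_aj_pit(prof, geom, params, rng, f"aj_pit-{i}")
    return _construct(SynapseReconstruction, dict(
        id=synapse_id, profiles=profiles, section_thickness=33.0))


def _condition_label(timepoint: Timepoint) -> str:
    if timepoint is None:
        return "synthetic/unstimulated"
    return f"synthetic/{timepoint:g}ms"


def generate_dataset(
    timepoints: Sequence[Timepoint],
    n_synapses: Union[int, Sequence[int]],
    params: GeneratorParams = GeneratorParams(),
    seed: Union[int, np.random.Generator] = 0,
) -> list[ConditionDataset]:
    """One dataset per timepoint, each with ``n_synapses`` reconstructions
    (an int applies to every timepoint).  Deterministic in the seed."""
    rng = _rng(seed)
    if isinstance(n_synapses, int):
        n_synapses = [n_synapses] * len(timepoints)
    if len(n_synapses) != len(timepoints):
        raise ValueError("n_synapses must be a single int or match timepoints")
    out = []
    for t, n in zip(timepoints, n_synapses):
        synapses = [
            generate_synapse(t, params, rng, synapse_id=f"syn{i}") for i in range(n)
        ]
        out.append(_construct(ConditionDataset, dict(
            condition_label=_condition_label(t),
            stimulated=t is not None,
            interval_to_freeze=t,
            synapses=synapses,
        )))
    return out


def generate_profiles_dataset(
    timepoint: Timepoint,
    n_profiles: int,
    params: GeneratorParams = GeneratorParams(),
    seed: Union[int, np.random.Generator] = 0,
) -> ConditionDataset:
    """A dataset with a target number of *profiles* (as the docked-pool
    experiment is tallied), built from 4–6-profile reconstructions."""
    rng = _rng(seed)
    synapses = []
    total = 0
    while total < n_profiles:
        syn = generate_synapse(timepoint, params, rng, synapse_id=f"syn{len(synapses)}")
        if total + len(syn.profiles) > n_profiles:
            syn.profiles = syn.profiles[: n_profiles - total]
        total += len(syn.profiles)
        synapses.append(syn)
    return _construct(ConditionDataset, dict(
        condition_label=_condition_label(timepoint),
        stimulated=timepoint is not None,
        interval_to_freeze=timepoint,
        synapses=synapses,
    ))


# ---------------------------------------------------------------------------
# Paired-pulse ratios and diameter samples


def generate_paired_pulse(
    intervals: Sequence[float] = PAIRED_PULSE_INTERVALS,
    params: GeneratorParams = GeneratorParams(),
    seed: Union[int, np.random.Generator] = 0,
) -> TimeSeries:
    """Second/first response ratios at the given inter-pulse intervals:
    ``1 − A_f·exp(−t/τ_f) − A_s·exp(−t/τ_s)`` plus Gaussian noise."""
    rng = _rng(seed)
    t = np.asarray(intervals, dtype=float)
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("intervals must be positive and increasing")
    y = (1.0
         - params.pp_amp_fast * np.exp(-t / params.pp_tau_fast)
         - params.pp_amp_slow * np.exp(-t / params.pp_tau_slow))
    y = y + rng.normal(0.0, params.pp_noise_sd, len(t))
    return TimeSeries(t=t, y=y)


def generate_diameters(
    n: int,
    means: Sequence[float] = (38.0, 46.0),
    sds: Sequence[float] = (3.0, 3.0),
    weights: Optional[Sequence[float]] = None,
    seed: Union[int, np.random.Generator] = 0,
    truncate_min: Optional[float] = None,
) -> np.ndarray:
    """Mixture-of-normals diameter draws (nm); ``truncate_min`` rejects draws
    at or below the floor (use 35 when emulating large vesicles)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = _rng(seed)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    w = (np.full(len(means), 1.0 / len(means)) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    out = np.empty(n)
    i = 0
    while i < n:
        c = rng.choice(len(means), p=w)
        d = rng.normal(means[c], sds[c])
        if truncate_min is not None and d <= truncate_min:
            continue
        if d <= 0:
            continue
        out[i] = d
        i += 1
    return out


# ---------------------------------------------------------------------------
# Freeze-timing simulator


@dataclass(frozen=True)
class FreezeTimingResult:
    """One simulated flash-and-freeze trial (all times ms).

    ``trigger_offset`` is when the freezer's start signal goes out relative
    to the light stimulus (negative = freezer triggered before the light);
    ``realized_interval`` is the post-hoc stimulus-to-freeze interval
    reconstructed from the actual pressure delay.
    """

    commanded_interval: float
    trigger_offset: float
    actual_delay: float
    realized_interval: float
    frozen_before_light: bool


def simulate_freeze_timing(
    commanded_interval: float,
    params: FreezeTimingParams = FreezeTimingParams(),
    seed: Union[int, np.random.Generator] = 0,
) -> FreezeTimingResult:
    """Trigger schedule and realized interval for one trial.

    The freezer is triggered ``commanded − (nominal delay + pressure-to-
    freeze)`` after the light; the actual delay is uniform in nominal ±
    jitter, so the realized interval is ``commanded + (actual − nominal)``.
    With the nominal 178 ms lead, a 1 s interval means triggering 822 ms
    after the light and a 100 ms interval 78 ms *before* it.
    """
    if commanded_interval <= 0:
        raise ValueError("commanded_interval must be > 0 ms")
    rng = _rng(seed)
    nominal = params.command_to_pressure_delay
    trigger = commanded_interval - (nominal + params.pressure_to_freeze)
    actual = rng.uniform(nominal - params.delay_jitter_halfwidth,
                         nominal + params.delay_jitter_halfwidth)
    realized = trigger + actual + params.pressure_to_freeze
    return FreezeTimingResult(
        commanded_interval=commanded_interval,
        trigger_offset=trigger,
        actual_delay=actual,
        realized_interval=realized,
        frozen_before_light=realized < 0,
    )
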