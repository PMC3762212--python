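"""Shared fixtures: hand-built micro-geometries and seeded generator output."""

from __future__ import annotations

import numpy as np
import pytest

from synmorph.annotations_io import (
    ConditionDataset,
    PitAnnotation,
    Point,
    ProfileAnnotation,
    SynapseReconstruction,
    VesicleAnnotation,
)


def straight_membrane(x0: float = -1000.0, x1: float = 1000.0, step: float = 100.0):
    """A flat membrane trace along y = 0."""
    xs = np.arange(x0, x1 + step / 2, step)
    return [Point(x=float(x), y=0.0) for x in xs]


def make_vesicle(x: float, y: float, diameter: float = 30.0, core: str = "clear",
                 tether: bool = False, vid: str = "v1") -> VesicleAnnotation:
    return VesicleAnnotation(id=vid, center=Point(x=x, y=y), diameter=diameter,
                             core=core, tether_observed=tether)


def make_profile(
    vesicles=(),
    pits=(),
    section_index: int = 0,
    aj_x=(-300.0, 300.0),
    dp: bool = True,
) -> ProfileAnnotation:
    """Flat membrane, a 80×40 nm dense projection at the origin, adherens
    junctions at ±300 nm by default."""
    dense = ([Point(x=-40.0, y=0.0), Point(x=40.0, y=0.0),
              Point(x=40.0, y=40.0), Point(x=-40.0, y=40.0)] if dp else None)
    return ProfileAnnotation(
        section_index=section_index,
        membrane=straight_membrane(),
        dense_projection=dense,
        adherens_junctions=[Point(x=float(x), y=0.0) for x in aj_x],
        vesicles=list(vesicles),
        pits=list(pits),
        profile_area=60_700.0,
    )


def make_synapse(profiles, sid: str = "s1") -> SynapseReconstruction:
    return SynapseReconstruction(id=sid, profiles=list(profiles))


def make_dataset(synapses, stimulated: bool = False, interval=None,
                 label: str = "test") -> ConditionDataset:
    return ConditionDataset(condition_label=label, stimulated=stimulated,
                            interval_to_freeze=interval, synapses=list(synapses))


def make_pit(x: float, width: float, depth: float, pid: str = "p1") -> PitAnnotation:
    return PitAnnotation(
        id=pid,
        apex=Point(x=x, y=depth),
        mouth_left=Point(x=x - width / 2, y=0.0),
        mouth_right=Point(x=x + width / 2, y=0.0),
        width=width, depth=depth,
    )


@pytest.fixture
def flat_profile() -> ProfileAnnotation:
    return make_profile()


@pytest.fixture
def flat_synapse(flat_profile) -> SynapseReconstruction:
    return make_synapse([flat_profile])


@pytest.fixture(scope="session")
def generated_unstimulated() -> ConditionDataset:
    from synmorph.synthetic_data import generate_profiles_dataset

    return generate_profiles_dataset(None, 120, seed=42)
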