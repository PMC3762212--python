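"""Vesicle-pool, zone, site and pit classification rules.

Every vesicle in a profile is assigned to exactly one pool by its distance
to the plasma membrane and the annotator's tether call:

* ``docked`` — outer edge in physical contact with the membrane
  (edge distance ≤ a small contact tolerance, 2 nm by default);
* ``tethered`` — within 30 nm with a visible tether filament;
* ``pool30`` — within 30 nm with no visible tether;
* ``cytoplasmic`` — everything further away.

The vesicle *kind* follows its appearance: dense-core vesicles by their dark
core; clear-core vesicles larger than 35 nm (strictly) are "large vesicles"
— the endocytic product tracked over time — and the rest are synaptic
vesicles.

Zones partition the membrane: the active zone runs from the dense
projection to the flanking adherens junctions; beyond them lies the
perisynaptic zone.  Endocytic structures are attributed to a *site*: within
100 nm (3-D) of the dense projection, else within 50 nm of an adherens
junction, else interior; dense-projection association takes precedence when
both radii overlap.

Pits split into exocytic (synaptic-vesicle-sized opening away from adherens
junctions) and endocytic, the latter shallow or deep at the hemisphere cut
``depth = width / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

from shapely import LineString, Point as ShapelyPoint

from .annotations_io import (
    PitAnnotation,
    ProfileAnnotation,
    SynapseReconstruction,
    VesicleAnnotation,
)

Pool = Literal["docked", "tethered", "pool30", "cytoplasmic"]
Kind = Literal["synaptic_vesicle", "dense_core", "large_vesicle"]
Zone = Literal["active_zone", "perisynaptic"]
Site = Literal["dense_projection", "adherens_junction", "interior"]
PitClass = Literal["exocytic", "shallow_endocytic", "deep_endocytic"]


@dataclass(frozen=True)
class ClassificationParams:
    """Distance thresholds, all in nm.

    contact_tolerance: membrane-contact slack absorbing annotation jitter.
    tether_max_distance: outer limit of the tethered / 30-nm pools.
    large_vesicle_min_diameter: exclusive lower bound for "large" clear-core
        vesicles.
    dp_site_radius / aj_site_radius: site-association radii for endocytic
        structures (dense projection wins on overlap).
    """

    contact_tolerance: float = 2.0
    tether_max_distance: float = 30.0
    large_vesicle_min_diameter: float = 35.0
    dp_site_radius: float = 100.0
    aj_site_radius: float = 50.0

    def __post_init__(self) -> None:
        for name in ("contact_tolerance", "tether_max_distance",
                     "large_vesicle_min_diameter", "dp_site_radius",
                     "aj_site_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tether_max_distance <= self.contact_tolerance:
            raise ValueError("tether_max_distance must exceed contact_tolerance")


@dataclass(frozen=True)
class PoolLabel:
    pool: Pool
    kind: Kind


@dataclass(frozen=True)
class ZoneLabel:
    zone: Zone
    #: True when an adherens junction was missing on the relevant side and the
    #: membrane end stood in for the zone boundary.
    boundary_from_membrane_end: bool = False


@dataclass(frozen=True)
class SiteLabel:
    site: Site
    #: True when the structure fell within both the dense-projection and the
    #: adherens-junction radius and precedence decided (audit trail).
    in_both_radii: bool = False


def _membrane_line(profile: ProfileAnnotation) -> LineString:
    if len(profile.membrane) < 2:
        raise ValueError("membrane polyline needs at least 2 points")
    return LineString([p.as_tuple() for p in profile.membrane])


def edge_distance_to_membrane(
    v: VesicleAnnotation, profile: ProfileAnnotation
) -> float:
    """Distance (nm) from the vesicle's outer edge to the membrane polyline.

    The vesicle is a circle of radius ``diameter / 2`` about its center;
    overlap (center closer than the radius) clamps to 0.
    """
    line = _membrane_line(profile)
    d = line.distance(ShapelyPoint(v.center.x, v.center.y)) - v.radius
    return max(d, 0.0)


def vesicle_kind(v: VesicleAnnotation, params: ClassificationParams) -> Kind:
    """Kind from appearance: dark core → dense_core; clear core strictly
    above the 35 nm threshold → large_vesicle; else synaptic_vesicle."""
    if v.core == "dense":
        return "dense_core"
    if v.diameter > params.large_vesicle_min_diameter:
        return "large_vesicle"
    return "synaptic_vesicle"


def pool_from_edge_distance(
    edge_distance: float, tether_observed: bool, params: ClassificationParams
) -> Pool:
    """Pool from the membrane edge distance and the annotator's tether call."""
    if edge_distance <= params.contact_tolerance:
        return "docked"
    if edge_distance <= params.tether_max_distance:
        return "tethered" if tether_observed else "pool30"
    return "cytoplasmic"


def classify_vesicle(
    v: VesicleAnnotation,
    profile: ProfileAnnotation,
    params: ClassificationParams = ClassificationParams(),
) -> PoolLabel:
    """Assign the (pool, kind) label for one vesicle."""
    d = edge_distance_to_membrane(v, profile)
    return PoolLabel(
        pool=pool_from_edge_distance(d, v.tether_observed, params),
        kind=vesicle_kind(v, params),
    )


# ---------------------------------------------------------------------------
# Zones

def _arc_positions(profile: ProfileAnnotation) -> tuple[LineString, Optional[tuple[float, float]], list[float]]:
    """Membrane line, dense-projection arc span, and adherens-junction arc
    positions, all as arc-length coordinates along the membrane."""
    line = _membrane_line(profile)
    dp_span = None
    if profile.dense_projection:
        s = [line.project(ShapelyPoint(p.as_tuple())) for p in profile.dense_projection]
        dp_span = (min(s), max(s))
    aj = [line.project(ShapelyPoint(p.as_tuple())) for p in profile.adherens_junctions]
    return line, dp_span, aj


def _nearest_dp_profile(
    profile: ProfileAnnotation, synapse: SynapseReconstruction
) -> ProfileAnnotation:
    bearing = [p for p in synapse.profiles if p.dense_projection]
    if not bearing:
        raise ValueError(f"reconstruction {synapse.id} has no dense projection")
    return min(bearing, key=lambda p: abs(p.section_index - profile.section_index))


def assign_zone(
    v: VesicleAnnotation,
    profile: ProfileAnnotation,
    synapse: Optional[SynapseReconstruction] = None,
) -> ZoneLabel:
    """Active zone vs perisynaptic, by the vesicle's membrane foot-point.

    The foot-point (nearest point on the membrane) lies in the active zone
    when its arc position falls between the dense projection and the
    flanking adherens-junction marks; the boundary itself counts as active
    zone.  A profile without its own dense projection borrows the outline of
    the nearest dense-projection-bearing section in the reconstruction
    (projected in-plane).  A missing adherens junction on one side leaves
    the membrane end as the de-facto boundary; the label is flagged.
    """
    dp_polygon = profile.dense_projection
    if not dp_polygon:
        if synapse is None:
            raise ValueError(
                "profile has no dense projection; pass the reconstruction to borrow one")
        dp_polygon = _nearest_dp_profile(profile, synapse).dense_projection

    line = _membrane_line(profile)
    s_dp = [line.project(ShapelyPoint(p.as_tuple())) for p in dp_polygon]
    dp_lo, dp_hi = min(s_dp), max(s_dp)
    s_foot = line.project(ShapelyPoint(v.center.x, v.center.y))
    aj = [line.project(ShapelyPoint(p.as_tuple())) for p in profile.adherens_junctions]

    left = [a for a in aj if a <= dp_lo]
    right = [a for a in aj if a >= dp_hi]
    from_end = False
    if left:
        lo = max(left)
    else:
        lo, from_end = 0.0, True
    if right:
        hi = min(right)
    else:
        hi, from_end = line.length, True
    zone: Zone = "active_zone" if lo <= s_foot <= hi else "perisynaptic"
    return ZoneLabel(zone=zone, boundary_from_membrane_end=from_end)


# ---------------------------------------------------------------------------
# Sites

def assign_site(
    x: Union[VesicleAnnotation, PitAnnotation],
    synapse: SynapseReconstruction,
    params: ClassificationParams = ClassificationParams(),
    profile: Optional[ProfileAnnotation] = None,
) -> SiteLabel:
    """Attribute an endocytic structure to its nearest recycling site.

    Distances are 3-D: in-plane separation combined with the section offset
    times the section thickness.  Dense-projection association (≤ 100 nm to
    the nearest dense-projection edge) takes precedence over
    adherens-junction association (≤ 50 nm to the nearest mark); anything
    else is interior.  ``profile`` locates ``x`` in the reconstruction; it
    is found by identity search when omitted.
    """
    from .morphometry import (  # local import: morphometry builds on this module
        point_distance_to_adherens_junction_3d,
        point_distance_to_dense_projection_3d,
    )

    if profile is None:
        profile = _find_profile_of(x, synapse)
    pos = x.center if isinstance(x, VesicleAnnotation) else x.apex

    d_dp = point_distance_to_dense_projection_3d(pos, profile.section_index, synapse)
    d_aj = point_distance_to_adherens_junction_3d(pos, profile.section_index, synapse)

    within_dp = d_dp <= params.dp_site_radius
    within_aj = d_aj is not None and d_aj <= params.aj_site_radius
    if within_dp:
        return SiteLabel(site="dense_projection", in_both_radii=within_aj)
    if within_aj:
        return SiteLabel(site="adherens_junction")
    return SiteLabel(site="interior")


def _find_profile_of(
    x: Union[VesicleAnnotation, PitAnnotation], synapse: SynapseReconstruction
) -> ProfileAnnotation:
    for prof in synapse.profiles:
        if isinstance(x, VesicleAnnotation):
            if any(v is x for v in prof.vesicles):
                return prof
        else:
            if any(p is x for p in prof.pits):
                return prof
    raise ValueError("structure does not belong to this reconstruction")


# ---------------------------------------------------------------------------
# Pits

def classify_pit(
    p: PitAnnotation,
    profile: ProfileAnnotation,
    synapse: SynapseReconstruction,
    params: ClassificationParams = ClassificationParams(),
) -> PitClass:
    """Exocytic vs shallow/deep endocytic pit.

    A pit with a synaptic-vesicle-sized mouth (width ≤ 35 nm) away from
    adherens junctions is a collapsing fusion intermediate (exocytic).
    Everything else is endocytic, shallow when ``depth < width / 2`` and
    deep from the hemisphere point on.
    """
    site = assign_site(p, synapse, params=params, profile=profile)
    if (
        p.width <= params.large_vesicle_min_diameter
        and site.site != "adherens_junction"
    ):
        return "exocytic"
    return "shallow_endocytic" if p.depth < p.width / 2 else "deep_endocytic"
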