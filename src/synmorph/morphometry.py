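"""Distances, binned distributions, normalized pool counts and group tests.

Distances to the dense projection are three-dimensional: the in-plane
distance to the nearest edge of the nearest dense-projection-bearing
section's outline (projected into the structure's plane), combined with the
out-of-plane offset ``sections × section thickness`` by the Pythagorean
rule.  Distance distributions use 33-nm bins (one section thickness) with a
reserved bin 0 for structures touching the dense projection.

Counts are reported raw and normalized to reference geometry so varicosity
size does not masquerade as a pool change: active-zone counts scale to a
typical 670 nm active zone, whole-profile counts to a typical 60,700 nm²
cross-section.

Group comparisons use the Mann-Whitney U test (counts are small and
skewed), exact for small samples, normal approximation with tie and
continuity correction otherwise, with a Bonferroni-adjusted threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely import LineString, Point as ShapelyPoint, Polygon

from .annotations_io import (
    ConditionDataset,
    Point,
    ProfileAnnotation,
    SynapseReconstruction,
    VesicleAnnotation,
)
from .classification import ClassificationParams, assign_site, classify_pit


@dataclass(frozen=True)
class NormalizationRefs:
    """Reference geometry for count normalization (nm and nm²)."""

    typical_active_zone_length: float = 670.0
    typical_profile_area: float = 60_700.0

    def __post_init__(self) -> None:
        if self.typical_active_zone_length <= 0 or self.typical_profile_area <= 0:
            raise ValueError("normalization references must be > 0")


# ---------------------------------------------------------------------------
# 3-D distances


def _dp_shape(dense_projection: list[Point]):
    coords = [p.as_tuple() for p in dense_projection]
    if len(coords) >= 3:
        return Polygon(coords)
    if len(coords) == 2:
        return LineString(coords)
    return ShapelyPoint(coords[0])


def point_distance_to_dense_projection_3d(
    point: Point, section_index: int, synapse: SynapseReconstruction
) -> float:
    """3-D distance (nm) from an in-plane point to the nearest
    dense-projection edge anywhere in the reconstruction.

    For each dense-projection-bearing section, the outline is projected into
    the point's plane; ``d = sqrt(x² + z²)`` with x the in-plane distance to
    the outline (0 inside it) and z the section offset times the section
    thickness.  The minimum over bearing sections is returned.
    """
    bearing = [p for p in synapse.profiles if p.dense_projection]
    if not bearing:
        raise ValueError(f"reconstruction {synapse.id} has no dense projection")
    sp = ShapelyPoint(point.x, point.y)
    best = math.inf
    for prof in bearing:
        x = _dp_shape(prof.dense_projection).distance(sp)
        z = abs(prof.section_index - section_index) * synapse.section_thickness
        best = min(best, math.hypot(x, z))
    return best


def point_distance_to_adherens_junction_3d(
    point: Point, section_index: int, synapse: SynapseReconstruction
) -> Optional[float]:
    """3-D distance (nm) to the nearest adherens-junction mark in the
    reconstruction, or None when no junction is annotated anywhere."""
    best = math.inf
    for prof in synapse.profiles:
        z = abs(prof.section_index - section_index) * synapse.section_thickness
        for aj in prof.adherens_junctions:
            d = math.hypot(math.hypot(point.x - aj.x, point.y - aj.y), z)
            best = min(best, d)
    return None if math.isinf(best) else best


def distance_to_dense_projection_3d(
    v: VesicleAnnotation,
    synapse: SynapseReconstruction,
    section_index: Optional[int] = None,
) -> float:
    """3-D distance from a vesicle's center to the nearest dense-projection
    edge (see :func:`point_distance_to_dense_projection_3d`).

    ``section_index`` locates the vesicle; when omitted the vesicle is found
    by identity in the reconstruction.
    """
    if section_index is None:
        for prof in synapse.profiles:
            if any(u is v for u in prof.vesicles):
                section_index = prof.section_index
                break
        else:
            raise ValueError("vesicle does not belong to this reconstruction")
    return point_distance_to_dense_projection_3d(v.center, section_index, synapse)


def vesicle_touches_dense_projection(
    v: VesicleAnnotation,
    synapse: SynapseReconstruction,
    section_index: Optional[int] = None,
    contact_tolerance: float = 2.0,
) -> bool:
    """Whether the vesicle's outer edge contacts the dense projection
    (center distance within radius + tolerance)."""
    d = distance_to_dense_projection_3d(v, synapse, section_index)
    return d - v.radius <= contact_tolerance


# ---------------------------------------------------------------------------
# Distance histograms


@dataclass
class DistanceHistogram:
    """Binned distances from the dense projection.

    Bin 0 is reserved for touching structures; bin k ≥ 1 covers the
    half-open interval [(k−1)·w, k·w) nm.
    """

    bin_width: float
    counts: np.ndarray
    bin0_is_touching: bool = True

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def bin_edges(self) -> np.ndarray:
        """Lower edges of bins 1..K (bin 0 has no distance extent)."""
        return np.arange(len(self.counts) - 1) * self.bin_width


def bin_by_distance(
    distances: Sequence[float],
    touching: Optional[Sequence[bool]] = None,
    bin_width: float = 33.0,
) -> DistanceHistogram:
    """Place distances into section-width bins with a reserved touching bin.

    A structure flagged touching lands in bin 0 regardless of its measured
    distance; every other structure at distance d lands in bin
    ``floor(d / bin_width) + 1`` (so an untouching structure at exactly
    0 nm is in bin 1, and 33.0 nm starts bin 2).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be ≥ 0")
    t = (
        np.zeros(len(d), dtype=bool)
        if touching is None
        else np.asarray(touching, dtype=bool)
    )
    if len(t) != len(d):
        raise ValueError("touching flags must match distances in length")
    idx = np.where(t, 0, np.floor_divide(d, bin_width).astype(int) + 1)
    n_bins = int(idx.max()) + 1 if len(idx) else 1
    counts = np.bincount(idx, minlength=n_bins)
    return DistanceHistogram(bin_width=bin_width, counts=counts)


def dp_distance_histogram(
    dataset: ConditionDataset,
    bin_width: float = 33.0,
    contact_tolerance: float = 2.0,
) -> DistanceHistogram:
    """Distance distribution of all vesicles from the dense projection,
    in section-width bins with the touching bin reserved."""
    distances: list[float] = []
    touching: list[bool] = []
    for syn in dataset.synapses:
        for prof in syn.profiles:
            for v in prof.vesicles:
                d = point_distance_to_dense_projection_3d(
                    v.center, prof.section_index, syn)
                distances.append(d)
                touching.append(d - v.radius <= contact_tolerance)
    return bin_by_distance(distances, touching, bin_width)


# ---------------------------------------------------------------------------
# Normalization and zone geometry


def normalize_count(
    count: float,
    observed: float,
    refs: NormalizationRefs = NormalizationRefs(),
    mode: str = "active_zone_length",
) -> float:
    """Scale a count to the reference geometry: ``count × reference / observed``."""
    if observed <= 0:
        raise ValueError("observed measure must be > 0")
    if mode == "active_zone_length":
        ref = refs.typical_active_zone_length
    elif mode == "profile_area":
        ref = refs.typical_profile_area
    else:
        raise ValueError(f"unknown normalization mode '{mode}'")
    return count * ref / observed


def active_zone_length(
    profile: ProfileAnnotation,
    synapse: Optional[SynapseReconstruction] = None,
) -> tuple[float, bool]:
    """Membrane arc length from the dense-projection edge to the flanking
    adherens junction, summed over both sides.

    Returns ``(length_nm, fallback_used)``; the flag is set when a side had
    no adherens junction and the membrane end bounded the zone instead.
    Profiles without their own dense projection borrow the nearest one in
    the reconstruction.
    """
    dp = profile.dense_projection
    if not dp:
        if synapse is None:
            raise ValueError("profile has no dense projection; pass the reconstruction")
        from .classification import _nearest_dp_profile

        dp = _nearest_dp_profile(profile, synapse).dense_projection
    line = LineString([p.as_tuple() for p in profile.membrane])
    s_dp = [line.project(ShapelyPoint(p.as_tuple())) for p in dp]
    dp_lo, dp_hi = min(s_dp), max(s_dp)
    aj = [line.project(ShapelyPoint(p.as_tuple())) for p in profile.adherens_junctions]
    left = [a for a in aj if a <= dp_lo]
    right = [a for a in aj if a >= dp_hi]
    fallback = not left or not right
    lo = max(left) if left else 0.0
    hi = min(right) if right else line.length
    return (dp_lo - lo) + (hi - dp_hi), fallback


# ---------------------------------------------------------------------------
# Pool aggregation

_PROFILE_METRICS = [
    "docked_active", "docked_peri", "tethered_active", "tethered_peri",
    "pool30_active", "pool30_peri", "total_sv",
    "docked_active_per_az", "tethered_active_per_az", "pool30_active_per_az",
    "docked_per_area", "tethered_per_area", "total_sv_per_area",
]

_SYNAPSE_METRICS = [
    "large_vesicles_dp", "large_vesicles_aj", "large_vesicles_interior",
    "shallow_pits_aj", "deep_pits_aj", "exocytic_pits",
]


@dataclass
class PoolCounts:
    """Per-profile and per-synapse tallies with their summaries.

    ``per_profile`` has one row per profile (docked/tethered/30-nm counts by
    zone, raw and normalized); ``per_synapse`` one row per reconstruction
    (large vesicles and pits by site).  The summaries carry mean, SEM and n
    per metric; the SEM of a single observation is reported as 0.
    """

    per_profile: pd.DataFrame
    per_synapse: pd.DataFrame
    profile_summary: pd.DataFrame = field(init=False)
    synapse_summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.profile_summary = _summarize(self.per_profile, _PROFILE_METRICS)
        self.synapse_summary = _summarize(self.per_synapse, _SYNAPSE_METRICS)


def _summarize(df: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        col = df[m] if m in df else pd.Series(dtype=float)
        col = col.dropna()
        n = len(col)
        mean = float(col.mean()) if n else float("nan")
        sem = float(col.std(ddof=1) / math.sqrt(n)) if n > 1 else (0.0 if n == 1 else float("nan"))
        rows.append({"metric": m, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows).set_index("metric")


def aggregate_pools(
    dataset: ConditionDataset,
    refs: NormalizationRefs = NormalizationRefs(),
    params: ClassificationParams = ClassificationParams(),
) -> PoolCounts:
    """Classify every structure in the dataset and tally the standard
    pool counts.

    Docked/tethered/30-nm synaptic-vesicle counts are tallied per profile by
    zone, normalized both by active-zone length (zone counts) and by profile
    area (whole-profile counts).  Large vesicles and pits are tallied per
    reconstruction by site — the scale on which endocytic structures occur
    once or twice per synapse.
    """
    if not dataset.synapses or dataset.n_profiles == 0:
        raise ValueError("dataset has no profiles to aggregate")

    from .classification import pool_from_edge_distance, vesicle_kind

    prof_rows = []
    syn_rows = []
    for syn in dataset.synapses:
        syn_row = {m: 0 for m in _SYNAPSE_METRICS}
        syn_row["synapse_id"] = syn.id
        for prof in syn.profiles:
            row = {m: 0 for m in _PROFILE_METRICS[:7]}
            row["synapse_id"] = syn.id
            row["section_index"] = prof.section_index

            # vectorized per-profile geometry: membrane distances and
            # arc-length foot points for every vesicle at once
            line = LineString([p.as_tuple() for p in prof.membrane])
            if prof.vesicles:
                coords = np.array([(v.center.x, v.center.y) for v in prof.vesicles])
                radii = np.array([v.radius for v in prof.vesicles])
                pts = shapely.points(coords)
                edge_d = np.maximum(shapely.distance(pts, line) - radii, 0.0)
                s_foot = shapely.line_locate_point(line, pts)
            else:
                edge_d = s_foot = np.empty(0)

            dp = prof.dense_projection
            if not dp:
                from .classification import _nearest_dp_profile

                dp = _nearest_dp_profile(prof, syn).dense_projection
            s_dp = shapely.line_locate_point(
                line, shapely.points([p.as_tuple() for p in dp]))
            dp_lo, dp_hi = float(s_dp.min()), float(s_dp.max())
            s_aj = shapely.line_locate_point(
                line, shapely.points([p.as_tuple() for p in prof.adherens_junctions])
            ) if prof.adherens_junctions else np.empty(0)
            left = s_aj[s_aj <= dp_lo]
            right = s_aj[s_aj >= dp_hi]
            az_lo = float(left.max()) if len(left) else 0.0
            az_hi = float(right.min()) if len(right) else line.length

            n_sv = 0
            for v, d, s in zip(prof.vesicles, edge_d, s_foot):
                kind = vesicle_kind(v, params)
                if kind == "large_vesicle":
                    site = assign_site(v, syn, params=params, profile=prof).site
                    key = {
                        "dense_projection": "large_vesicles_dp",
                        "adherens_junction": "large_vesicles_aj",
                        "interior": "large_vesicles_interior",
                    }[site]
                    syn_row[key] += 1
                    continue
                if kind == "dense_core":
                    continue
                n_sv += 1
                pool = pool_from_edge_distance(float(d), v.tether_observed, params)
                if pool == "cytoplasmic":
                    continue
                suffix = "active" if az_lo <= s <= az_hi else "peri"
                if pool == "docked":
                    row[f"docked_{suffix}"] += 1
                elif pool == "tethered":
                    row[f"tethered_{suffix}"] += 1
                else:
                    row[f"pool30_{suffix}"] += 1
            row["total_sv"] = n_sv

            for p in prof.pits:
                pclass = classify_pit(p, prof, syn, params)
                if pclass == "exocytic":
                    syn_row["exocytic_pits"] += 1
                else:
                    site = assign_site(p, syn, params=params, profile=prof).site
                    if site == "adherens_junction":
                        key = ("shallow_pits_aj" if pclass == "shallow_endocytic"
                               else "deep_pits_aj")
                        syn_row[key] += 1

            az_len = (dp_lo - az_lo) + (az_hi - dp_hi)
            for pool in ("docked", "tethered", "pool30"):
                row[f"{pool}_active_per_az"] = (
                    normalize_count(row[f"{pool}_active"], az_len, refs,
                                    "active_zone_length")
                    if az_len > 0 else float("nan")
                )
            row["docked_per_area"] = normalize_count(
                row["docked_active"] + row["docked_peri"], prof.profile_area,
                refs, "profile_area")
            row["tethered_per_area"] = normalize_count(
                row["tethered_active"] + row["tethered_peri"], prof.profile_area,
                refs, "profile_area")
            row["total_sv_per_area"] = normalize_count(
                row["total_sv"], prof.profile_area, refs, "profile_area")
            prof_rows.append(row)
        syn_rows.append(syn_row)

    return PoolCounts(
        per_profile=pd.DataFrame(prof_rows),
        per_synapse=pd.DataFrame(syn_rows),
    )


# ---------------------------------------------------------------------------
# Group comparison


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney U result with a Bonferroni-adjusted threshold."""

    u_statistic: float
    p_value: float
    method: str
    adjusted_alpha: float
    significant: bool
    n_a: int
    n_b: int


def _exact_mannwhitney_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of all
    assignments of the pooled sample to the two groups (handles ties;
    U counts pairs with a > b plus half the tied pairs)."""
    import itertools

    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    gt = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    idx_a = list(range(n1))
    idx_b = list(range(n1, n))
    u_obs = float(gt[np.ix_(idx_a, idx_b)].sum())
    u_lo = min(u_obs, n1 * (n - n1) - u_obs)
    count = total = 0
    all_idx = frozenset(range(n))
    for combo in itertools.combinations(range(n), n1):
        rest = list(all_idx - set(combo))
        u = gt[np.ix_(list(combo), rest)].sum()
        total += 1
        if min(u, n1 * (n - n1) - u) <= u_lo + 1e-9:
            count += 1
    return u_obs, count / total


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples.

    The null distribution is exact (full enumeration, or full permutation
    when ties are present) when both samples have ≤ 8 observations, and the
    normal approximation with tie and continuity correction otherwise.  The
    significance threshold is ``alpha / n_comparisons``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be ≥ 1")

    small = len(a) <= 8 and len(b) <= 8
    if small:
        u, p = _exact_mannwhitney_two_sided(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"

    threshold = alpha / n_comparisons
    return GroupComparison(
        u_statistic=u,
        p_value=p,
        method=method,
        adjusted_alpha=threshold,
        significant=p < threshold,
        n_a=len(a),
        n_b=len(b),
    )
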