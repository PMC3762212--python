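"""Annotation data model and I/O for serial-section synapse profiles.

A flash-and-freeze experiment yields ribbons of ultrathin (33 nm) sections
through synaptic varicosities.  Each section ("profile") is annotated with
the presynaptic plasma-membrane trace, the dense-projection outline, the
adherens-junction marks, and every vesicle and membrane pit.  Contiguous
profiles sharing one dense projection form a "synapse" reconstruction, and
reconstructions are grouped into condition datasets (genotype × stimulation
× freeze interval).

Units are fixed package-wide: lengths in nm, areas in nm², times in ms.
Coordinates are 2-D within a section; the out-of-plane coordinate is implied
by ``section_index × section_thickness``.

Two on-disk forms are supported: canonical JSON (one dataset per file) and a
flat CSV dialect for spreadsheet use (one row per profile / vesicle / pit;
see :data:`CSV_COLUMNS`).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterator, Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

#: Default section thickness in nm; carried on each reconstruction, never re-derived.
DEFAULT_SECTION_THICKNESS = 33.0

#: Default tolerance (nm) for "this point lies on the membrane trace" checks.
DEFAULT_PLACEMENT_TOLERANCE = 5.0


class _Model(BaseModel):
    model_config = ConfigDict(extra="allow", validate_assignment=False)


class Point(_Model):
    """A 2-D point in the section plane, in nm."""

    x: float
    y: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


class VesicleAnnotation(_Model):
    """One vesicle: center, diameter, core appearance, and the annotator's
    tether call (a visual feature, not recoverable from geometry)."""

    id: str
    center: Point
    diameter: float = Field(description="outer diameter, nm")
    core: Literal["clear", "dense"]
    tether_observed: bool = False

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


class PitAnnotation(_Model):
    """A membrane invagination: deepest point plus the two points where the
    pit mouth meets the membrane trace."""

    id: str
    apex: Point
    mouth_left: Point
    mouth_right: Point
    width: float = Field(description="mouth span, nm")
    depth: float = Field(description="apex-to-mouth depth, nm")


class ProfileAnnotation(_Model):
    """One EM section through a varicosity."""

    section_index: int
    membrane: list[Point] = Field(description="open polyline, cleft-facing")
    dense_projection: Optional[list[Point]] = Field(
        default=None, description="closed polygon; None when the section misses it"
    )
    adherens_junctions: list[Point] = Field(default_factory=list)
    vesicles: list[VesicleAnnotation] = Field(default_factory=list)
    pits: list[PitAnnotation] = Field(default_factory=list)
    profile_area: float = Field(description="annotated cross-section area, nm²")


class SynapseReconstruction(_Model):
    """Ordered contiguous profiles sharing one dense projection — the unit
    for per-synapse (endocytic-structure) counting."""

    id: str
    profiles: list[ProfileAnnotation]
    section_thickness: float = DEFAULT_SECTION_THICKNESS

    def iter_profiles(self) -> Iterator[ProfileAnnotation]:
        return iter(self.profiles)


class ConditionDataset(_Model):
    """All reconstructions for one experimental condition."""

    condition_label: str
    stimulated: bool
    interval_to_freeze: Optional[float] = Field(
        default=None, description="stimulus-to-freeze interval, ms; None if unstimulated"
    )
    synapses: list[SynapseReconstruction] = Field(default_factory=list)

    @property
    def n_profiles(self) -> int:
        return sum(len(s.profiles) for s in self.synapses)


class ValidationIssue(_Model):
    """One invariant violation; issues are data, not exceptions."""

    record: str
    field: str
    rule: str


class SchemaError(ValueError):
    """Raised when a file lacks a required field or cannot be parsed."""


class DatasetValidationError(ValueError):
    """Raised when a parsed dataset violates structural invariants."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        lines = [f"{i.record}: {i.field}: {i.rule}" for i in issues]
        super().__init__("dataset failed validation:\n  " + "\n  ".join(lines))


# ---------------------------------------------------------------------------
# Validation


def _point_to_polyline_distance(p: Point, polyline: list[Point]) -> float:
    best = math.inf
    for a, b in zip(polyline, polyline[1:]):
        ax, ay, bx, by = a.x, a.y, b.x, b.y
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        if seg2 == 0.0:
            d = math.hypot(p.x - ax, p.y - ay)
        else:
            t = max(0.0, min(1.0, ((p.x - ax) * dx + (p.y - ay) * dy) / seg2))
            d = math.hypot(p.x - (ax + t * dx), p.y - (ay + t * dy))
        best = min(best, d)
    return best


def validate_dataset(
    dataset: ConditionDataset,
    placement_tolerance: float = DEFAULT_PLACEMENT_TOLERANCE,
) -> list[ValidationIssue]:
    """Check every structural invariant; return one issue record per violation.

    An empty list means the dataset is fully valid.  Checks: positive vesicle
    diameters, positive pit widths and non-negative depths, mouth points and
    adherens-junction marks on the membrane trace (within
    ``placement_tolerance`` nm), ≥ 2 membrane points, positive profile areas,
    strictly consecutive section indices, at least one dense projection per
    reconstruction, finite coordinates, and a positive freeze interval when
    stimulated.
    """
    issues: list[ValidationIssue] = []

    def issue(record: str, field: str, rule: str) -> None:
        issues.append(ValidationIssue(record=record, field=field, rule=rule))

    if dataset.stimulated and not (
        dataset.interval_to_freeze is not None and dataset.interval_to_freeze > 0
    ):
        issue(dataset.condition_label, "interval_to_freeze",
              "must be > 0 ms when the condition is stimulated")

    for syn in dataset.synapses:
        idx = [p.section_index for p in syn.profiles]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            gaps = [f"{a}->{b}" for a, b in zip(idx, idx[1:]) if b - a != 1]
            issue(syn.id, "profiles",
                  f"section indices must be strictly consecutive; gaps at {', '.join(gaps)}")
        if not any(p.dense_projection for p in syn.profiles):
            issue(syn.id, "profiles", "at least one profile must contain a dense projection")
        if syn.section_thickness <= 0:
            issue(syn.id, "section_thickness", "must be > 0 nm")

        for prof in syn.profiles:
            rec = f"{syn.id}/section {prof.section_index}"
            if len(prof.membrane) < 2:
                issue(rec, "membrane", "polyline needs at least 2 points")
            if prof.profile_area <= 0:
                issue(rec, "profile_area", "must be > 0 nm²")
            for pt in prof.membrane:
                if not (math.isfinite(pt.x) and math.isfinite(pt.y)):
                    issue(rec, "membrane", "coordinates must be finite")
                    break
            if len(prof.membrane) >= 2:
                for j, aj in enumerate(prof.adherens_junctions):
                    d = _point_to_polyline_distance(aj, prof.membrane)
                    if d > placement_tolerance:
                        issue(rec, f"adherens_junctions[{j}]",
                              f"point is {d:.1f} nm off the membrane trace "
                              f"(tolerance {placement_tolerance:g} nm)")
            for v in prof.vesicles:
                if v.diameter <= 0:
                    issue(f"{rec}/vesicle {v.id}", "diameter", "must be > 0 nm")
            for p in prof.pits:
                if p.width <= 0:
                    issue(f"{rec}/pit {p.id}", "width", "must be > 0 nm")
                if p.depth < 0:
                    issue(f"{rec}/pit {p.id}", "depth", "must be ≥ 0 nm")
                if len(prof.membrane) >= 2:
                    for name, pt in (("mouth_left", p.mouth_left),
                                     ("mouth_right", p.mouth_right)):
                        d = _point_to_polyline_distance(pt, prof.membrane)
                        if d > placement_tolerance:
                            issue(f"{rec}/pit {p.id}", name,
                                  f"point is {d:.1f} nm off the membrane trace "
                                  f"(tolerance {placement_tolerance:g} nm)")
    return issues


# ---------------------------------------------------------------------------
# JSON I/O


def dataset_json_schema() -> dict:
    """JSON schema of the canonical on-disk dataset document."""
    return ConditionDataset.model_json_schema()


def _read_json(path: Path) -> ConditionDataset:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON: {e}") from e
    try:
        return ConditionDataset.model_validate(payload)
    except Exception as e:  # pydantic error: rewrap naming field + record
        raise SchemaError(f"{path}: does not match the dataset schema: {e}") from e


def _write_json(dataset: ConditionDataset, path: Path) -> None:
    path.write_text(
        json.dumps(dataset.model_dump(mode="json"), indent=1, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# CSV dialect
#
# One row per record.  record_type selects which columns are meaningful:
#   profile — carries dataset/synapse metadata and the section geometry
#             (membrane / dense projection as "x y;x y;..." strings);
#             emitted for every profile, including empty ones.
#   vesicle — one vesicle; keyed by (synapse_id, section_index).
#   pit     — one pit, likewise.

CSV_COLUMNS = [
    "record_type", "condition_label", "stimulated", "interval_to_freeze_ms",
    "synapse_id", "section_thickness_nm", "section_index",
    "profile_area_nm2", "membrane", "dense_projection", "adherens_junctions",
    "id", "x_nm", "y_nm", "diameter_nm", "core", "tether_observed",
    "apex_x_nm", "apex_y_nm", "mouth_left_x_nm", "mouth_left_y_nm",
    "mouth_right_x_nm", "mouth_right_y_nm", "width_nm", "depth_nm",
]


def _pts_to_str(pts: Optional[list[Point]]) -> str:
    if not pts:
        return ""
    return ";".join(f"{p.x!r} {p.y!r}" for p in pts)


def _pts_from_str(s: str) -> list[Point]:
    if not s:
        return []
    out = []
    for tok in s.split(";"):
        x, y = tok.split()
        out.append(Point(x=float(x), y=float(y)))
    return out


def _write_csv(dataset: ConditionDataset, path: Path) -> None:
    rows: list[dict] = []
    meta = {
        "condition_label": dataset.condition_label,
        "stimulated": dataset.stimulated,
        "interval_to_freeze_ms": (
            "" if dataset.interval_to_freeze is None else dataset.interval_to_freeze
        ),
    }
    for syn in dataset.synapses:
        for prof in syn.profiles:
            key = {"synapse_id": syn.id, "section_index": prof.section_index}
            rows.append({
                "record_type": "profile", **meta, **key,
                "section_thickness_nm": syn.section_thickness,
                "profile_area_nm2": prof.profile_area,
                "membrane": _pts_to_str(prof.membrane),
                "dense_projection": _pts_to_str(prof.dense_projection),
                "adherens_junctions": _pts_to_str(prof.adherens_junctions),
            })
            for v in prof.vesicles:
                rows.append({
                    "record_type": "vesicle", **meta, **key,
                    "id": v.id, "x_nm": v.center.x, "y_nm": v.center.y,
                    "diameter_nm": v.diameter, "core": v.core,
                    "tether_observed": v.tether_observed,
                })
            for p in prof.pits:
                rows.append({
                    "record_type": "pit", **meta, **key,
                    "id": p.id,
                    "apex_x_nm": p.apex.x, "apex_y_nm": p.apex.y,
                    "mouth_left_x_nm": p.mouth_left.x, "mouth_left_y_nm": p.mouth_left.y,
                    "mouth_right_x_nm": p.mouth_right.x, "mouth_right_y_nm": p.mouth_right.y,
                    "width_nm": p.width, "depth_nm": p.depth,
                })
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    if df.empty:  # keep the metadata even for an empty dataset
        df = pd.DataFrame([{"record_type": "dataset", **meta}], columns=CSV_COLUMNS)
    # exact float round-trip: shortest-repr formatting, not pandas' default
    df = df.map(lambda v: repr(v) if isinstance(v, float) else v)
    df.to_csv(path, index=False)


def _require(row: pd.Series, col: str, record: str):
    val = row.get(col)
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        raise SchemaError(f"missing required field '{col}' in {record}")
    return val


def _read_csv(path: Path) -> ConditionDataset:
    try:
        df = pd.read_csv(path, float_precision="round_trip",
                         dtype={"membrane": str, "dense_projection": str,
                                "adherens_junctions": str, "id": str,
                                "core": str, "synapse_id": str})
    except Exception as e:
        raise SchemaError(f"{path}: not readable as CSV: {e}") from e
    if "record_type" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'record_type'")

    first = df.iloc[0] if len(df) else None
    if first is None:
        raise SchemaError(f"{path}: empty CSV, no dataset metadata row")
    interval = first.get("interval_to_freeze_ms")
    dataset = ConditionDataset(
        condition_label=str(_require(first, "condition_label", "row 1")),
        stimulated=bool(first["stimulated"]),
        interval_to_freeze=None if pd.isna(interval) else float(interval),
        synapses=[],
    )
    syn_by_id: dict[str, SynapseReconstruction] = {}
    prof_by_key: dict[tuple[str, int], ProfileAnnotation] = {}

    for i, row in df.iterrows():
        rec = f"row {i + 2}"  # header is line 1
        rtype = row["record_type"]
        if rtype == "dataset":
            continue
        sid = str(_require(row, "synapse_id", rec))
        sect = int(_require(row, "section_index", rec))
        if rtype == "profile":
            syn = syn_by_id.get(sid)
            if syn is None:
                syn = SynapseReconstruction(
                    id=sid, profiles=[],
                    section_thickness=float(row.get("section_thickness_nm"))
                    if not pd.isna(row.get("section_thickness_nm"))
                    else DEFAULT_SECTION_THICKNESS,
                )
                syn_by_id[sid] = syn
                dataset.synapses.append(syn)
            dp = _pts_from_str(row.get("dense_projection") if isinstance(row.get("dense_projection"), str) else "")
            prof = ProfileAnnotation(
                section_index=sect,
                membrane=_pts_from_str(str(_require(row, "membrane", rec))),
                dense_projection=dp or None,
                adherens_junctions=_pts_from_str(
                    row.get("adherens_junctions") if isinstance(row.get("adherens_junctions"), str) else ""),
                profile_area=float(_require(row, "profile_area_nm2", rec)),
            )
            syn.profiles.append(prof)
            prof_by_key[(sid, sect)] = prof
        elif rtype == "vesicle":
            prof = prof_by_key.get((sid, sect))
            if prof is None:
                raise SchemaError(f"{rec}: vesicle refers to unknown profile ({sid}, {sect})")
            prof.vesicles.append(VesicleAnnotation(
                id=str(_require(row, "id", rec)),
                center=Point(x=float(_require(row, "x_nm", rec)),
                             y=float(_require(row, "y_nm", rec))),
                diameter=float(_require(row, "diameter_nm", rec)),
                core=str(_require(row, "core", rec)),
                tether_observed=bool(row["tether_observed"]),
            ))
        elif rtype == "pit":
            prof = prof_by_key.get((sid, sect))
            if prof is None:
                raise SchemaError(f"{rec}: pit refers to unknown profile ({sid}, {sect})")
            prof.pits.append(PitAnnotation(
                id=str(_require(row, "id", rec)),
                apex=Point(x=float(_require(row, "apex_x_nm", rec)),
                           y=float(_require(row, "apex_y_nm", rec))),
                mouth_left=Point(x=float(_require(row, "mouth_left_x_nm", rec)),
                                 y=float(_require(row, "mouth_left_y_nm", rec))),
                mouth_right=Point(x=float(_require(row, "mouth_right_x_nm", rec)),
                                  y=float(_require(row, "mouth_right_y_nm", rec))),
                width=float(_require(row, "width_nm", rec)),
                depth=float(_require(row, "depth_nm", rec)),
            ))
        else:
            raise SchemaError(f"{rec}: unknown record_type '{rtype}'")
    # profiles arrive in file order; keep reconstruction order by section index
    for syn in dataset.synapses:
        syn.profiles.sort(key=lambda p: p.section_index)
    return dataset


# ---------------------------------------------------------------------------
# Public I/O surface

Format = Literal["json", "csv"]


def _infer_format(path: Path, format: Optional[Format]) -> Format:
    if format is not None:
        return format
    return "csv" if path.suffix.lower() == ".csv" else "json"


def read_dataset(
    path: Union[str, Path],
    format: Optional[Format] = None,
    validate: bool = True,
    placement_tolerance: float = DEFAULT_PLACEMENT_TOLERANCE,
) -> ConditionDataset:
    """Read a condition dataset from JSON (canonical) or the flat CSV dialect.

    Raises :class:`SchemaError` on missing fields / unparseable files and
    :class:`DatasetValidationError` (listing each offending record) when
    ``validate`` is on and any invariant fails.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    dataset = _read_csv(path) if fmt == "csv" else _read_json(path)
    if validate:
        issues = validate_dataset(dataset, placement_tolerance=placement_tolerance)
        if issues:
            raise DatasetValidationError(issues)
    return dataset


def write_dataset(
    dataset: ConditionDataset,
    path: Union[str, Path],
    format: Optional[Format] = None,
) -> None:
    """Write a dataset; ``read_dataset(write_dataset(d))`` round-trips."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(dataset, path)
    else:
        _write_json(dataset, path)
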