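"""Per-cell spatial qualities, contacts and conditional process instances.

This layer joins a meta-model to its snapshot series: cells in a lattice
snapshot are voxel collections, and their qualities (volume, centroid,
surface), contact graph and process instances are computed here.

Conventions
-----------
* Adjacency is the 6-neighborhood: only face-sharing voxels touch, and a
  face carries area ``scale²``.
* Under wall boundaries a voxel face on the domain edge counts toward the
  cell's surface; those faces are booked against the boundary sentinel id
  ``ContactMap.BOUNDARY`` (−1) so the decomposition
  ``surface(a) = Σ_b faces(a,b) × scale²`` (b over cells, medium and the
  boundary) closes exactly.  Periodic axes wrap instead.
* A lattice with ``nz == 1`` is treated as 2D with implied unit thickness:
  volume = voxel_count × scale² × 1.  Surfaces still count all six faces.
* Conditional processes follow the iff-contact rule: an adhesion instance
  exists between two cells exactly when they share at least one face.
* The reserved float field ``TargetVolume`` (painted per voxel by the
  owning cell) is read back as a target-volume quality per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import CBOError, MappingError
from .metamodel import MEDIUM_TYPE_ID, MetaModel
from .ontology import Curie, Quality
from .units import unit_curie
from .vtkio import (
    CenterSnapshot,
    LatticeSnapshot,
    enumerate_series,
    read_structured_points,
)

__all__ = [
    "CellRecord",
    "ContactMap",
    "ProcessInstance",
    "TimeSeries",
    "Event",
    "cell_geometry",
    "contact_map",
    "instantiate_conditional_processes",
    "check_spatial_exclusivity",
    "field_statistics",
    "per_cell_field_mean",
    "build_timeseries",
]

TARGET_VOLUME_FIELD = "TargetVolume"

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class CellRecord:
    cell_id: int
    type_id: int
    prototype: str | None
    voxel_count: int
    volume: float
    centroid: tuple[float, float, float]
    surface: float
    fragment_count: int
    field_means: dict[str, float] = dfield(default_factory=dict)
    target_qualities: list[Quality] = dfield(default_factory=list)


class ContactMap:
    """Symmetric shared-face counts between label pairs.

    Keys may include medium (0) and the boundary sentinel (−1, wall
    boundaries only).  ``contact(a, a)`` is undefined and never stored.
    """

    BOUNDARY = -1

    def __init__(self):
        self._faces: dict[tuple[int, int], int] = {}

    def _key(self, a: int, b: int) -> tuple[int, int]:
        if a == b:
            raise KeyError("contact of a label with itself is undefined")
        return (a, b) if a < b else (b, a)

    def add(self, a: int, b: int, n: int = 1) -> None:
        k = self._key(a, b)
        self._faces[k] = self._faces.get(k, 0) + n

    def get(self, a: int, b: int) -> int:
        return self._faces.get(self._key(a, b), 0)

    def items(self):
        return self._faces.items()

    def partners(self, a: int) -> dict[int, int]:
        out = {}
        for (x, y), n in self._faces.items():
            if x == a:
                out[y] = n
            elif y == a:
                out[x] = n
        return out

    def total_faces(self, a: int) -> int:
        return sum(self.partners(a).values())

    def __len__(self):
        return len(self._faces)


@dataclass(frozen=True)
class ProcessInstance:
    process: str
    participants: tuple[int, ...]
    time: Quality | None = None
    magnitude: float | None = None


@dataclass(frozen=True)
class Event:
    time: float
    kind: str  # division | death | phenotype_change | creation
    ids: tuple[int, ...]


@dataclass
class TimeSeries:
    times: list[Quality]
    records: list[list[CellRecord]]
    events: list[Event]


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

def contact_map(snapshot: LatticeSnapshot, boundary=("wall", "wall", "wall")) -> ContactMap:
    """Shared 6-neighborhood face counts per unordered label pair.

    Wall axes book domain-edge faces against the boundary sentinel;
    periodic axes pair the first and last slabs instead.
    """
    a = snapshot.cell_id
    cm = ContactMap()

    def accumulate(lo: np.ndarray, hi: np.ndarray):
        mask = lo != hi
        if not mask.any():
            return
        pairs = np.stack([lo[mask], hi[mask]], axis=1)
        pairs.sort(axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        for (x, y), n in zip(uniq.tolist(), counts.tolist()):
            cm.add(int(x), int(y), int(n))

    for axis in range(3):
        n = a.shape[axis]
        if n > 1:
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, n - 1)
            sl_hi[axis] = slice(1, n)
            accumulate(a[tuple(sl_lo)], a[tuple(sl_hi)])
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[axis] = 0
        last[axis] = n - 1
        if boundary[axis] == "periodic":
            if n > 1:
                accumulate(a[tuple(last)], a[tuple(first)])
            # n == 1 with periodic wrap: a voxel is its own neighbor; no face
        else:  # wall: both end slabs face out of the domain
            edge = a[tuple(first)]
            accumulate(edge, np.full_like(edge, ContactMap.BOUNDARY))
            edge = a[tuple(last)]
            accumulate(edge, np.full_like(edge, ContactMap.BOUNDARY))
    return cm


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def cell_geometry(
    snapshot: LatticeSnapshot,
    scale: Quality,
    boundary=("wall", "wall", "wall"),
    type_map: dict[int, str] | None = None,
    contacts: ContactMap | None = None,
) -> list[CellRecord]:
    """One record per nonzero cell id, sorted by id.

    volume = voxel_count × scale³ (scale² × 1 for 2D lattices); centroid =
    mean voxel-center position × scale; surface = exposed 6-neighborhood
    faces × scale².  ``type_map`` (TypeID → prototype name) fills the
    prototype field when given.
    """
    snapshot.validate()
    s = float(scale.value)
    dims = snapshot.dims
    two_d = dims[2] == 1 and (dims[0] > 1 or dims[1] > 1)
    voxel_volume = s * s if two_d else s ** 3

    ids = snapshot.cell_id
    types = snapshot.type_of_cells()
    if contacts is None:
        contacts = contact_map(snapshot, boundary)

    labels = sorted(types)
    records = []
    flat = ids.ravel()
    counts = np.bincount(flat, minlength=max(labels, default=0) + 1)
    # centroid accumulators via index grids
    idx = np.indices(dims, dtype=np.float64)
    for cid in labels:
        mask = ids == cid
        count = int(counts[cid])
        centroid = tuple(
            float((idx[d][mask].mean() + 0.5) * s) for d in range(3)
        )
        surface = contacts.total_faces(cid) * s * s
        frag, n_frag = ndimage.label(mask, structure=_STRUCT6)
        field_means = {
            name: float(arr[mask].mean()) for name, arr in snapshot.fields.items()
            if name != TARGET_VOLUME_FIELD
        }
        target_qualities = []
        if TARGET_VOLUME_FIELD in snapshot.fields:
            tv = float(snapshot.fields[TARGET_VOLUME_FIELD][mask].mean())
            target_qualities.append(
                Quality(Curie("CBO", "Volume"), tv, "target", None)
            )
        records.append(
            CellRecord(
                cell_id=cid,
                type_id=types[cid],
                prototype=(type_map or {}).get(types[cid]),
                voxel_count=count,
                volume=count * voxel_volume,
                centroid=centroid,
                surface=surface,
                fragment_count=int(n_frag),
                field_means=field_means,
                target_qualities=target_qualities,
            )
        )
    return records


# --------------------------------------------------------------------------
# conditional processes
# --------------------------------------------------------------------------

def instantiate_conditional_processes(
    model: MetaModel,
    snapshot: LatticeSnapshot,
    contacts: ContactMap | None = None,
    time: Quality | None = None,
) -> list[ProcessInstance]:
    """Materialize process instances implied by a snapshot.

    Pairwise contact-conditioned specs yield one instance per contacting
    cell pair whose prototypes match (iff-contact); unary ``always`` specs
    yield one instance per cell of the participant prototype; unary
    field-threshold specs yield instances for cells whose mean field value
    is on the declared side of the threshold.
    """
    type_map = model.type_id_map()
    cell_types = snapshot.type_of_cells()
    proto_of: dict[int, str] = {}
    for cid, tid in cell_types.items():
        if tid not in type_map:
            raise MappingError(f"snapshot TypeID {tid} has no prototype in the model")
        proto_of[cid] = type_map[tid]

    if contacts is None:
        contacts = contact_map(
            snapshot,
            model.system.boundary if model.system else ("wall",) * 3,
        )
    scale = float(model.system.distance_scale.value) if model.system else 1.0

    out: list[ProcessInstance] = []
    for spec in model.processes.values():
        if len(spec.participants) == 2 and spec.condition == "contact_required":
            want = tuple(sorted(spec.participants))
            for (a, b), faces in contacts.items():
                if a <= 0 or b <= 0:
                    continue  # medium and boundary do not adhere
                pair = tuple(sorted((proto_of[a], proto_of[b])))
                if pair == want:
                    out.append(
                        ProcessInstance(spec.name, (a, b), time, faces * scale * scale)
                    )
        elif len(spec.participants) == 1:
            proto = spec.participants[0]
            members = [cid for cid, p in proto_of.items() if p == proto]
            if spec.condition == "always":
                out.extend(ProcessInstance(spec.name, (cid,), time) for cid in members)
            elif spec.condition in ("field_below_threshold", "field_above_threshold"):
                fname = spec.parameter_value(
                    "change_field", spec.parameter_value("field")
                )
                thr = spec.parameter_value(
                    "change_threshold", spec.parameter_value("threshold")
                )
                if fname is None or thr is None or fname not in snapshot.fields:
                    continue
                means = per_cell_field_mean(snapshot, str(fname))
                below = spec.condition == "field_below_threshold"
                for cid in members:
                    v = means.get(cid)
                    if v is None:
                        continue
                    if (v < thr) if below else (v > thr):
                        out.append(ProcessInstance(spec.name, (cid,), time, v))
    return out


# --------------------------------------------------------------------------
# exclusivity
# --------------------------------------------------------------------------

def check_spatial_exclusivity(snapshot, tolerance: float = 0.0) -> list[tuple]:
    """Spatial-exclusivity violations.

    A lattice snapshot with a single id array cannot double-book a voxel,
    so it is vacuously valid.  For center models, a pair of spheres
    violates exclusivity when their center distance is below
    ``(r_a + r_b) · (1 − tolerance)``.
    """
    if isinstance(snapshot, LatticeSnapshot):
        return []
    assert isinstance(snapshot, CenterSnapshot)
    out = []
    pts = snapshot.points
    r = snapshot.radius
    n = len(pts)
    for i in range(n):
        d = np.linalg.norm(pts[i + 1 :] - pts[i], axis=1)
        limit = (r[i] + r[i + 1 :]) * (1.0 - tolerance)
        for j in np.nonzero(d < limit)[0]:
            out.append(
                (int(snapshot.cell_id[i]), int(snapshot.cell_id[i + 1 + j]), float(d[j]))
            )
    return out


# --------------------------------------------------------------------------
# fields
# --------------------------------------------------------------------------

def field_statistics(
    snapshot: LatticeSnapshot, field_name: str, scale: Quality | None = None
) -> tuple[float, float, float, float]:
    """(min, max, mean, total_mass) of a field; mass = Σ value × voxel
    volume at the given distance scale (unit voxels if omitted)."""
    if field_name not in snapshot.fields:
        raise KeyError(f"unknown field {field_name!r}")
    arr = snapshot.fields[field_name]
    s = float(scale.value) if scale is not None else 1.0
    dims = snapshot.dims
    two_d = dims[2] == 1 and (dims[0] > 1 or dims[1] > 1)
    voxel_volume = s * s if two_d else s ** 3
    return (
        float(arr.min()),
        float(arr.max()),
        float(arr.mean()),
        float(arr.sum() * voxel_volume),
    )


def per_cell_field_mean(snapshot: LatticeSnapshot, field_name: str) -> dict[int, float]:
    """Mean field value over each nonzero cell's voxels."""
    if field_name not in snapshot.fields:
        raise KeyError(f"unknown field {field_name!r}")
    ids = snapshot.cell_id.ravel()
    vals = snapshot.fields[field_name].ravel()
    nmax = int(ids.max(initial=0))
    counts = np.bincount(ids, minlength=nmax + 1)
    sums = np.bincount(ids, weights=vals, minlength=nmax + 1)
    return {
        cid: float(sums[cid] / counts[cid])
        for cid in range(1, nmax + 1)
        if counts[cid] > 0
    }


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def build_timeseries(model: MetaModel, directory=None) -> TimeSeries:
    """Read a snapshot series and infer cell-level events between
    consecutive snapshots.

    * an id that disappears → ``death``;
    * a new id is attributed to the parent whose previous-snapshot voxels
      it overlaps most (a daughter occupies part of the parent's old
      footprint); with no overlap, the nearest shrinking cell by centroid;
      with no candidate at all → ``creation``;
    * a persistent id whose type changes → ``phenotype_change``.
    """
    if model.series is None:
        raise CBOError("meta-model has no VTK series link")
    link = model.series
    directory = Path(directory) if directory is not None else Path(link.directory)
    scale = model.system.distance_scale if model.system else Quality(
        Curie("CBO", "SystemPixelDistanceScale"), 1.0, "actual", unit_curie("micrometer")
    )
    boundary = model.system.boundary if model.system else ("wall",) * 3
    type_map = model.type_id_map()
    known_ids = set(type_map)

    times: list[Quality] = []
    all_records: list[list[CellRecord]] = []
    events: list[Event] = []
    prev: dict[int, CellRecord] | None = None
    prev_ids: np.ndarray | None = None

    for path, t in enumerate_series(directory, link):
        snap = read_structured_points(path, time=t)
        for tid in snap.type_of_cells().values():
            if tid not in known_ids:
                raise MappingError(f"snapshot TypeID {tid} not in meta-model")
        recs = cell_geometry(snap, scale, boundary, type_map)
        cur = {r.cell_id: r for r in recs}
        tval = float(t.value)
        if prev is not None:
            for cid in sorted(set(prev) - set(cur)):
                events.append(Event(tval, "death", (cid,)))
            shrinking = [
                r for cid, r in cur.items()
                if cid in prev and r.voxel_count < prev[cid].voxel_count
            ]
            for cid in sorted(set(cur) - set(prev)):
                child = cur[cid]
                parent_id = None
                if prev_ids is not None:
                    overlap = prev_ids[snap.cell_id == cid]
                    overlap = overlap[overlap > 0]
                    if overlap.size:
                        counts_ov = np.bincount(overlap)
                        parent_id = int(np.argmax(counts_ov))
                if parent_id is None:
                    best = np.inf
                    for cand in shrinking:
                        d = float(
                            np.linalg.norm(
                                np.subtract(cand.centroid, child.centroid)
                            )
                        )
                        if d < best:
                            best, parent_id = d, cand.cell_id
                if parent_id is not None:
                    events.append(Event(tval, "division", (parent_id, cid)))
                else:
                    events.append(Event(tval, "creation", (cid,)))
            for cid in sorted(set(cur) & set(prev)):
                if cur[cid].type_id != prev[cid].type_id:
                    events.append(Event(tval, "phenotype_change", (cid,)))
        times.append(t)
        all_records.append(recs)
        prev = cur
        prev_ids = snap.cell_id
    return TimeSeries(times, all_records, events)
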