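"""Legacy-VTK ASCII snapshot IO and the file-name time convention.

Two dataset dialects carry the spatiality of a multicell model:

* ``STRUCTURED_POINTS`` for voxel lattices — per-voxel ``CellId`` and
  ``CellType`` integer arrays plus one float array per named chemical
  field.  Values are listed x-fastest, then y, then z.
* ``POLYDATA`` for center models — sphere centers with per-point
  ``Radius``, ``CellId`` and ``CellType`` arrays.

Snapshot files in a series are named ``<root>_<zero-padded-index>.vtk``;
the associated meta-model's time-step quality (the temporal-interval
multiplier) converts the integer index into simulated time.  The writer
zero-pads indices to 10 digits; the reader accepts any width.

Only ASCII legacy VTK is supported; spacing is written in lattice units
(1 1 1), physical scale living in the meta-model's pixel distance scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConventionError,
    InconsistencyError,
    SeriesIncompleteError,
    TruncationError,
    VTKFormatError,
)
from .metamodel import SeriesLink
from .ontology import Curie, Quality

__all__ = [
    "LatticeSnapshot",
    "CenterSnapshot",
    "write_structured_points",
    "read_structured_points",
    "write_polydata",
    "read_polydata",
    "peek_header",
    "decode_snapshot_time",
    "snapshot_filename",
    "enumerate_series",
]

_PAD_WIDTH = 10
_VALUES_PER_LINE = 9


# --------------------------------------------------------------------------
# snapshot containers
# --------------------------------------------------------------------------

@dataclass
class LatticeSnapshot:
    """A voxel grid at one instant.

    ``cell_id`` and ``cell_type`` are int arrays of shape ``dims``
    (index order x, y, z); ``fields`` maps field names to float arrays of
    the same shape.  Label 0 is medium/background.
    """

    dims: tuple[int, int, int]
    cell_id: np.ndarray
    cell_type: np.ndarray
    fields: dict[str, np.ndarray] = field(default_factory=dict)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time: Quality | None = None

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int32).reshape(self.dims)
        self.cell_type = np.asarray(self.cell_type, dtype=np.int32).reshape(self.dims)
        self.fields = {
            k: np.asarray(v, dtype=np.float64).reshape(self.dims)
            for k, v in self.fields.items()
        }

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def validate(self) -> None:
        if np.any(self.cell_id < 0):
            raise InconsistencyError("negative cell id")
        self.type_of_cells()  # raises on inconsistent typing

    def type_of_cells(self) -> dict[int, int]:
        """Map each nonzero cell id to its (single) cell type."""
        ids = self.cell_id.ravel()
        types = self.cell_type.ravel()
        out: dict[int, int] = {}
        mask = ids > 0
        for cid, ctype in zip(ids[mask].tolist(), types[mask].tolist()):
            prev = out.setdefault(cid, ctype)
            if prev != ctype:
                raise InconsistencyError(
                    f"cell {cid} carries types {prev} and {ctype}"
                )
        return out


@dataclass
class CenterSnapshot:
    """A center model at one instant: spheres with radii and ids."""

    points: np.ndarray  # (n, 3) float
    radius: np.ndarray
    cell_id: np.ndarray
    cell_type: np.ndarray
    time: Quality | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = len(self.points)
        self.radius = np.asarray(self.radius, dtype=np.float64).reshape(n)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int32).reshape(n)
        self.cell_type = np.asarray(self.cell_type, dtype=np.int32).reshape(n)

    def validate(self) -> None:
        if np.any(self.radius <= 0):
            raise VTKFormatError("radii must be positive")


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    return f"{x:.9g}"


def _wrap(values, fmt=str) -> list[str]:
    toks = [fmt(v) for v in values]
    return [
        " ".join(toks[i : i + _VALUES_PER_LINE])
        for i in range(0, len(toks), _VALUES_PER_LINE)
    ]


def _scalars_block(name: str, dtype: str, values, fmt) -> list[str]:
    return [f"SCALARS {name} {dtype} 1", "LOOKUP_TABLE default", *_wrap(values, fmt)]


def write_structured_points(snapshot: LatticeSnapshot, path) -> None:
    """Write a lattice snapshot as ASCII legacy-VTK STRUCTURED_POINTS."""
    snapshot.validate()
    nx, ny, nz = snapshot.dims
    lines = [
        "# vtk DataFile Version 3.0",
        "cbokit lattice snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN " + " ".join(_fmt_float(v) for v in snapshot.origin),
        "SPACING " + " ".join(_fmt_float(v) for v in snapshot.spacing),
        f"POINT_DATA {snapshot.n_points}",
    ]
    order = lambda a: a.ravel(order="F")  # x fastest, then y, then z
    lines += _scalars_block("CellId", "int", order(snapshot.cell_id), str)
    lines += _scalars_block("CellType", "int", order(snapshot.cell_type), str)
    for name in snapshot.fields:
        lines += _scalars_block(name, "float", order(snapshot.fields[name]), _fmt_float)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_polydata(snapshot: CenterSnapshot, path) -> None:
    """Write a center-model snapshot as ASCII legacy-VTK POLYDATA."""
    snapshot.validate()
    n = len(snapshot.points)
    lines = [
        "# vtk DataFile Version 3.0",
        "cbokit center snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
        *_wrap(snapshot.points.ravel(), _fmt_float),
        f"POINT_DATA {n}",
    ]
    lines += _scalars_block("Radius", "float", snapshot.radius, _fmt_float)
    lines += _scalars_block("CellId", "int", snapshot.cell_id, str)
    lines += _scalars_block("CellType", "int", snapshot.cell_type, str)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

class _TokenStream:
    """Whitespace tokenizer over the body of a VTK file: value lists may be
    wrapped across lines arbitrarily."""

    def __init__(self, text: str):
        self.tokens = text.split()
        self.pos = 0

    def next(self) -> str:
        if self.pos >= len(self.tokens):
            raise TruncationError("unexpected end of file")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def take(self, n: int) -> list[str]:
        if self.pos + n > len(self.tokens):
            raise TruncationError(
                f"expected {n} values, found {len(self.tokens) - self.pos}"
            )
        out = self.tokens[self.pos : self.pos + n]
        self.pos += n
        return out

    def eof(self) -> bool:
        return self.pos >= len(self.tokens)


def _read_preamble(text: str) -> tuple[str, _TokenStream]:
    lines = text.splitlines()
    if len(lines) < 4:
        raise VTKFormatError("file too short for a legacy-VTK header")
    if not lines[0].lstrip().startswith("# vtk DataFile"):
        raise VTKFormatError("missing '# vtk DataFile' header line")
    if lines[2].strip().upper() != "ASCII":
        raise VTKFormatError("only ASCII legacy VTK is supported")
    body = "\n".join(lines[3:])
    stream = _TokenStream(body)
    if stream.next() != "DATASET":
        raise VTKFormatError("expected DATASET after the ASCII line")
    return stream.next(), stream


def _read_scalars(stream: _TokenStream, n: int):
    name = stream.next()
    dtype = stream.next()
    # optional numComp token
    peek = stream.next()
    if peek == "LOOKUP_TABLE":
        stream.next()  # table name
    else:
        if stream.next() != "LOOKUP_TABLE":
            raise VTKFormatError(f"expected LOOKUP_TABLE in SCALARS {name}")
        stream.next()
    raw = stream.take(n)
    if dtype in ("int", "short", "long", "unsigned_int", "unsigned_char"):
        values = np.array([int(t) for t in raw], dtype=np.int32)
    else:
        values = np.array([float(t) for t in raw], dtype=np.float64)
    return name, values


def read_structured_points(path, time: Quality | None = None) -> LatticeSnapshot:
    """Read an ASCII STRUCTURED_POINTS lattice snapshot."""
    dataset, stream = _read_preamble(Path(path).read_text(encoding="utf-8"))
    if dataset != "STRUCTURED_POINTS":
        raise VTKFormatError(f"unsupported DATASET {dataset!r}")
    dims = origin = spacing = None
    n = None
    while not stream.eof():
        key = stream.next()
        if key == "DIMENSIONS":
            dims = tuple(int(stream.next()) for _ in range(3))
        elif key == "ORIGIN":
            origin = tuple(float(stream.next()) for _ in range(3))
        elif key == "SPACING":
            spacing = tuple(float(stream.next()) for _ in range(3))
        elif key == "POINT_DATA":
            n = int(stream.next())
            break
        else:
            raise VTKFormatError(f"unexpected token {key!r} in header")
    if dims is None or n is None:
        raise VTKFormatError("header lacks DIMENSIONS or POINT_DATA")
    if n != dims[0] * dims[1] * dims[2]:
        raise TruncationError(f"POINT_DATA {n} != product of DIMENSIONS {dims}")
    arrays: dict[str, np.ndarray] = {}
    order: list[str] = []
    while not stream.eof():
        key = stream.next()
        if key != "SCALARS":
            raise VTKFormatError(f"unexpected token {key!r}; expected SCALARS")
        name, values = _read_scalars(stream, n)
        arrays[name] = values
        order.append(name)
    if "CellId" not in arrays or "CellType" not in arrays:
        raise VTKFormatError("lattice snapshot needs CellId and CellType arrays")

    def grid(a):
        return a.reshape(dims, order="F")

    fields = {
        name: grid(arrays[name].astype(np.float64))
        for name in order
        if name not in ("CellId", "CellType")
    }
    snap = LatticeSnapshot(
        dims=dims,
        cell_id=grid(arrays["CellId"]),
        cell_type=grid(arrays["CellType"]),
        fields=fields,
        origin=origin or (0.0, 0.0, 0.0),
        spacing=spacing or (1.0, 1.0, 1.0),
        time=time,
    )
    snap.validate()
    return snap


def read_polydata(path, time: Quality | None = None) -> CenterSnapshot:
    """Read an ASCII POLYDATA center-model snapshot."""
    dataset, stream = _read_preamble(Path(path).read_text(encoding="utf-8"))
    if dataset != "POLYDATA":
        raise VTKFormatError(f"unsupported DATASET {dataset!r}")
    if stream.next() != "POINTS":
        raise VTKFormatError("expected POINTS")
    n = int(stream.next())
    stream.next()  # dtype
    pts = np.array([float(t) for t in stream.take(3 * n)]).reshape(n, 3)
    arrays: dict[str, np.ndarray] = {}
    while not stream.eof():
        key = stream.next()
        if key == "POINT_DATA":
            m = int(stream.next())
            if m != n:
                raise TruncationError(f"POINT_DATA {m} != POINTS {n}")
        elif key == "SCALARS":
            name, values = _read_scalars(stream, n)
            arrays[name] = values
        else:
            raise VTKFormatError(f"unexpected token {key!r}")
    missing = {"Radius", "CellId", "CellType"} - set(arrays)
    if missing:
        raise VTKFormatError(f"center snapshot lacks arrays: {sorted(missing)}")
    snap = CenterSnapshot(
        points=pts,
        radius=arrays["Radius"],
        cell_id=arrays["CellId"],
        cell_type=arrays["CellType"],
        time=time,
    )
    if n:
        snap.validate()
    return snap


def peek_header(path) -> dict:
    """Read only the header of a legacy-VTK file.

    Returns dataset kind plus, for STRUCTURED_POINTS, the dimensions and
    total point count (``n_points``) without touching the value arrays —
    usable on headers describing lattices far too large to materialize.
    """
    text = Path(path).read_text(encoding="utf-8")
    dataset, stream = _read_preamble(text)
    info: dict = {"dataset": dataset}
    if dataset == "STRUCTURED_POINTS":
        while not stream.eof():
            key = stream.next()
            if key == "DIMENSIONS":
                dims = tuple(int(stream.next()) for _ in range(3))
                info["dims"] = dims
                info["n_points"] = dims[0] * dims[1] * dims[2]
                break
        if "dims" not in info:
            raise VTKFormatError("header lacks DIMENSIONS")
    elif dataset == "POLYDATA":
        if stream.next() != "POINTS":
            raise VTKFormatError("expected POINTS")
        info["n_points"] = int(stream.next())
    return info


# --------------------------------------------------------------------------
# series conventions
# --------------------------------------------------------------------------

def snapshot_filename(file_root: str, index: int) -> str:
    """``<root>_<10-digit index>.vtk``"""
    return f"{file_root}_{index:0{_PAD_WIDTH}d}.vtk"


def decode_snapshot_time(filename: str, link: SeriesLink) -> Quality:
    """Decode simulated time from a snapshot file name.

    time = (integer suffix) x (time step), in the time step's unit.
    """
    name = Path(filename).name
    m = re.match(rf"^{re.escape(link.file_root)}_(\d+)\.vtk$", name)
    if m is None:
        raise ConventionError(
            f"{name!r} does not match <{link.file_root}>_<digits>.vtk"
        )
    index = int(m.group(1))
    return Quality(
        Curie("CBO", "TemporalInterval"),
        index * float(link.time_step.value),
        "actual",
        link.time_step.unit,
    )


def enumerate_series(directory, link: SeriesLink) -> list[tuple[Path, Quality]]:
    """All series snapshots in *directory*, sorted by decoded time.

    The zero-index initial-condition file must be present and first.
    """
    directory = Path(directory)
    out = []
    for p in directory.iterdir():
        m = re.match(rf"^{re.escape(link.file_root)}_(\d+)\.vtk$", p.name)
        if m:
            out.append((p, decode_snapshot_time(p.name, link)))
    out.sort(key=lambda pt: (float(pt[1].value), pt[0].name))
    if not out or float(out[0][1].value) != 0.0:
        raise SeriesIncompleteError(
            f"series {link.file_root!r} in {directory} lacks its zero-index initial file"
        )
    return out
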