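"""Deterministic toy multicell simulator driven by a meta-model.

The simulator interprets a meta-model's process specs (growth, division,
necrosis, phenotypic change, secretion/consumption, field diffusion and
decay) as simple lattice dynamics and emits snapshot series in the
package's VTK conventions, together with a ground-truth event log.  It is
a fixture generator: cells relax toward their target volumes by adding or
removing one boundary voxel per step (deterministic, lowest-lexicographic
tie-break) instead of energy-minimizing lattice dynamics, so the output
exercises meta-model/snapshot semantics, not tissue mechanics.

Step order (one call to :func:`step`):

1. fields — explicit-Euler diffusion, decay, per-cell secretion/uptake
   (uptake floored at the available local mass);
2. phenotypic change — a cell switches prototype when its mean field
   value crosses the spec's threshold;
3. necrosis bookkeeping — necrotic cells lose ``necrosis_decrement``
   (default 0.5) of target volume per step and get surface coefficient 0;
4. growth — target volume += rate × dt for growing prototypes;
5. volume relaxation — one voxel accreted/shed per cell per step while
   actual volume is below/above target;
6. division — at ``division_threshold`` voxels a cell bisects along its
   longest axis; daughters share the prototype, target volumes halve;
7. death — cells with no voxels or non-positive target are removed.

The only randomness is the seeded initial cell placement; everything
after step 0 is deterministic, so identical seeds give byte-identical
output directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import analysis
from .errors import CBOError, StabilityError
from .metamodel import (
    MetaModel,
    SeriesLink,
    define_field_prototype,
    define_process,
    define_prototype,
    define_system,
    export_metamodel,
    link_vtk_series,
    validate_metamodel,
)
from .ontology import Curie, Quality
from .units import unit_curie
from .vtkio import LatticeSnapshot, snapshot_filename, write_structured_points

__all__ = [
    "SimState",
    "Scenario",
    "FieldParams",
    "make_scenario",
    "initialize",
    "step",
    "diffuse_field",
    "run",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

_MIN = unit_curie("minute")
_UM = unit_curie("micrometer")


def _q(cls: str, value, kind="actual", unit=None) -> Quality:
    return Quality(Curie("CBO", cls), value, kind, unit)


@dataclass
class FieldParams:
    diffusion: float = 0.0  # lattice units^2 per minute
    decay: float = 0.0  # fraction per minute
    secretion: dict[str, float] = dfield(default_factory=dict)  # prototype -> rate
    uptake: dict[str, float] = dfield(default_factory=dict)


@dataclass
class Scenario:
    name: str
    model: MetaModel
    dt: Quality  # time per step
    n_steps: int
    output_every: int
    file_root: str
    field_params: dict[str, FieldParams]
    initial_fields: dict[str, float]
    n_seed_cells: int
    seed_target_volume: float
    seed_region: tuple[int, int]  # inclusive coordinate band for placement

    def check_stability(self) -> None:
        dt = float(self.dt.value)
        for name, fp in self.field_params.items():
            if fp.diffusion * dt > 1.0 / 6.0:
                raise StabilityError(
                    f"field {name!r}: D*dt/h^2 = {fp.diffusion * dt:.3f} > 1/6"
                )


@dataclass
class SimState:
    snapshot: LatticeSnapshot
    target_volume: dict[int, float]
    surface_coefficient: dict[int, float]
    rng_seed: int
    step_index: int = 0
    next_id: int = 1
    event_log: list[tuple[int, str, tuple[int, ...]]] = dfield(default_factory=list)


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

def _mini_model() -> MetaModel:
    """Reduced-scale tumor-growth model: corpuscular tumor cells with
    hypoxic and necrotic subphenotypes, a nutrient field and one secreted
    signal field, and the full process roster (growth, division, necrosis,
    adhesion, phenotype change, secretion/consumption, diffusion/decay)."""
    m = MetaModel()
    m.system = define_system(
        "TumorGrowthMini",
        (20, 20, 20),
        _q("SystemPixelDistanceScale", 4.44, unit=_UM),
        boundary="wall",
        platform="cbokit-toy-simulator",
        biology_xrefs=[Curie("GO", "0001525")],  # angiogenesis
    )
    define_prototype(m, "Medium", "Medium", "Continuous", vtk_type_id=0)
    define_prototype(m, "TumorCell", "Cell", "Corpuscular", 1,
                     default_qualities=[_q("Volume", 16.0, "target")])
    define_prototype(m, "HypoxicTumorCell", "Cell", "Corpuscular", 2,
                     xrefs=[Curie("MP", "0005039")],
                     default_qualities=[_q("Volume", 16.0, "target")])
    define_prototype(m, "NecroticTumorCell", "Cell", "Corpuscular", 3)
    define_field_prototype(m, "NutrientField", "Nutrient")
    define_field_prototype(m, "SignalField", "VEGF")

    define_process(m, "T_Growth", "CellGrowth", ["TumorCell"],
                   {"growth_rate": _q("ProcessQuality", 0.5)})
    define_process(m, "H_Growth", "CellGrowth", ["HypoxicTumorCell"],
                   {"growth_rate": _q("ProcessQuality", 0.1)})
    define_process(m, "T_Division", "CellDivision", ["TumorCell"],
                   {"division_threshold": _q("ProcessQuality", 16)})
    define_process(m, "H_Division", "CellDivision", ["HypoxicTumorCell"],
                   {"division_threshold": _q("ProcessQuality", 16)})
    define_process(m, "T_H_Change", "PhenotypicChange", ["TumorCell"],
                   {"change_field": _q("ProcessQuality", "Nutrient"),
                    "change_threshold": _q("ProcessQuality", 0.5),
                    "target_prototype": _q("ProcessQuality", "HypoxicTumorCell")},
                   condition="field_below_threshold")
    define_process(m, "H_T_Change", "PhenotypicChange", ["HypoxicTumorCell"],
                   {"change_field": _q("ProcessQuality", "Nutrient"),
                    "change_threshold": _q("ProcessQuality", 0.65),
                    "target_prototype": _q("ProcessQuality", "TumorCell")},
                   condition="field_above_threshold")
    define_process(m, "H_N_Change", "PhenotypicChange", ["HypoxicTumorCell"],
                   {"change_field": _q("ProcessQuality", "Nutrient"),
                    "change_threshold": _q("ProcessQuality", 0.15),
                    "target_prototype": _q("ProcessQuality", "NecroticTumorCell")},
                   condition="field_below_threshold")
    define_process(m, "N_Necrosis", "Necrosis", ["NecroticTumorCell"],
                   {"necrosis_decrement": _q("ProcessQuality", 0.5)})
    define_process(m, "T_T_Adh", "CellCellAdhesion", ["TumorCell", "TumorCell"],
                   {"adhesion_strength": _q("ProcessQuality", 1.0)},
                   condition="contact_required")
    define_process(m, "H_T_Adh", "CellCellAdhesion",
                   ["HypoxicTumorCell", "TumorCell"],
                   {"adhesion_strength": _q("ProcessQuality", 0.5)},
                   condition="contact_required")
    define_process(m, "T_NutrientUptake", "Consumption", ["TumorCell"],
                   {"field": _q("ProcessQuality", "Nutrient"),
                    "uptake_rate": _q("ProcessQuality", 0.05)})
    define_process(m, "H_NutrientUptake", "Consumption", ["HypoxicTumorCell"],
                   {"field": _q("ProcessQuality", "Nutrient"),
                    "uptake_rate": _q("ProcessQuality", 0.02)})
    define_process(m, "H_SignalSecretion", "Secretion", ["HypoxicTumorCell"],
                   {"field": _q("ProcessQuality", "VEGF"),
                    "secretion_rate": _q("ProcessQuality", 0.05)})
    define_process(m, "Nutrient_Diffusion", "Diffusion", ["NutrientField"],
                   {"diffusion_coefficient": _q("ProcessQuality", 0.1)})
    define_process(m, "Signal_Diffusion", "Diffusion", ["SignalField"],
                   {"diffusion_coefficient": _q("ProcessQuality", 0.1)})
    define_process(m, "Signal_Decay", "Decay", ["SignalField"],
                   {"decay_rate": _q("ProcessQuality", 0.02)})
    return m


def _toy_model() -> MetaModel:
    m = MetaModel()
    m.system = define_system(
        "TwoCellToy", (8, 8, 8),
        _q("SystemPixelDistanceScale", 1.0, unit=_UM), boundary="wall",
        platform="cbokit-toy-simulator",
    )
    define_prototype(m, "Medium", "Medium", "Continuous", vtk_type_id=0)
    define_prototype(m, "TumorCell", "Cell", "Corpuscular", 1)
    define_process(m, "T_T_Adh", "CellCellAdhesion", ["TumorCell", "TumorCell"],
                   {"adhesion_strength": _q("ProcessQuality", 1.0)},
                   condition="contact_required")
    return m


def _field_params_from_model(model: MetaModel) -> dict[str, FieldParams]:
    """Collect per-field dynamics from the model's process specs."""
    field_of_proto = {
        p.name: p.field_name for p in model.prototypes.values()
        if p.physical_type == "Diffuse"
    }
    params = {fname: FieldParams() for fname in field_of_proto.values()}
    for spec in model.processes.values():
        cls = spec.process_class.local_id
        part = spec.participants[0] if spec.participants else None
        if cls == "Diffusion" and part in field_of_proto:
            params[field_of_proto[part]].diffusion = float(
                spec.parameter_value("diffusion_coefficient", 0.0))
        elif cls == "Decay" and part in field_of_proto:
            params[field_of_proto[part]].decay = float(
                spec.parameter_value("decay_rate", 0.0))
        elif cls == "Secretion":
            fname = str(spec.parameter_value("field"))
            if fname in params:
                params[fname].secretion[part] = float(
                    spec.parameter_value("secretion_rate", 0.0))
        elif cls == "Consumption":
            fname = str(spec.parameter_value("field"))
            if fname in params:
                params[fname].uptake[part] = float(
                    spec.parameter_value("uptake_rate", 0.0))
    return params


def make_scenario(name: str) -> Scenario:
    """Bundled scenarios: ``tumor_angiogenesis_mini`` and ``two_cell_toy``."""
    if name == "tumor_angiogenesis_mini":
        model = _mini_model()
        scen = Scenario(
            name=name,
            model=model,
            dt=_q("TemporalInterval", 1.0, unit=_MIN),
            n_steps=60,
            output_every=10,
            file_root="tumor_mini",
            field_params=_field_params_from_model(model),
            initial_fields={"Nutrient": 1.0, "VEGF": 0.0},
            n_seed_cells=6,
            seed_target_volume=4.0,
            seed_region=(5, 14),
        )
    elif name == "two_cell_toy":
        model = _toy_model()
        scen = Scenario(
            name=name,
            model=model,
            dt=_q("TemporalInterval", 1.0, unit=_MIN),
            n_steps=10,
            output_every=5,
            file_root="two_cell",
            field_params={},
            initial_fields={},
            n_seed_cells=0,
            seed_target_volume=8.0,
            seed_region=(0, 0),
        )
    else:
        raise KeyError(f"unknown scenario {name!r}")
    assert not validate_metamodel(scen.model)
    scen.check_stability()
    return scen


def initialize(scenario: Scenario, seed: int = 0) -> SimState:
    """Build the initial state.  The seeded RNG is used only here, for
    cell placement; the dynamics afterwards are fully deterministic."""
    model = scenario.model
    dims = model.system.extent
    cell_id = np.zeros(dims, dtype=np.int32)
    cell_type = np.zeros(dims, dtype=np.int32)
    targets: dict[int, float] = {}
    if scenario.name == "two_cell_toy":
        cell_id[2:4, 3:5, 3:5] = 1
        cell_id[4:6, 3:5, 3:5] = 2
        cell_type[cell_id > 0] = model.prototypes["TumorCell"].vtk_type_id
        targets = {1: scenario.seed_target_volume, 2: scenario.seed_target_volume}
        nid = 3
    else:
        rng = np.random.default_rng(seed)
        lo, hi = scenario.seed_region
        coords = set()
        while len(coords) < scenario.n_seed_cells:
            coords.add(tuple(int(v) for v in rng.integers(lo, hi + 1, size=3)))
        tumor_tid = model.prototypes["TumorCell"].vtk_type_id
        for i, (x, y, z) in enumerate(sorted(coords), start=1):
            cell_id[x, y, z] = i
            cell_type[x, y, z] = tumor_tid
            targets[i] = scenario.seed_target_volume
        nid = scenario.n_seed_cells + 1
    fields = {
        fname: np.full(dims, value, dtype=np.float64)
        for fname, value in scenario.initial_fields.items()
    }
    snap = LatticeSnapshot(dims=dims, cell_id=cell_id, cell_type=cell_type,
                           fields=fields)
    return SimState(
        snapshot=snap,
        target_volume=targets,
        surface_coefficient={cid: 1.0 for cid in targets},
        rng_seed=seed,
        next_id=nid,
    )


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def diffuse_field(field: np.ndarray, D: float, dt: float, h: float = 1.0,
                  boundary: str = "zero_flux") -> np.ndarray:
    """One explicit-Euler step of the 7-point diffusion stencil.

    Zero-flux boundaries conserve total mass exactly (missing neighbors
    mirror the edge value); periodic boundaries wrap.
    """
    alpha = D * dt / (h * h)
    if alpha > 1.0 / 6.0:
        raise StabilityError(f"D*dt/h^2 = {alpha:.4f} exceeds the 1/6 bound")
    if alpha == 0.0:
        return field.copy()
    mode = "wrap" if boundary == "periodic" else "edge"
    p = np.pad(field, 1, mode=mode)
    lap = (
        p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
        + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
        + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
        - 6.0 * field
    )
    return field + alpha * lap


def _proto_of(state: SimState, model: MetaModel) -> dict[int, str]:
    type_map = model.type_id_map()
    return {cid: type_map[tid] for cid, tid in state.snapshot.type_of_cells().items()}


def _grow_candidates(mask: np.ndarray, free: np.ndarray) -> np.ndarray:
    halo = ndimage.binary_dilation(mask, structure=_STRUCT6) & ~mask
    return np.argwhere(halo & free)


def _shed_candidates(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~interior)


def step(state: SimState, scenario: Scenario) -> SimState:
    """Advance one step in place (and return the state)."""
    scenario.check_stability()
    model = scenario.model
    snap = state.snapshot
    dt = float(scenario.dt.value)
    state.step_index += 1
    now = state.step_index

    # (1) field dynamics
    for fname, fp in scenario.field_params.items():
        arr = snap.fields[fname]
        arr = diffuse_field(arr, fp.diffusion, dt)
        if fp.decay:
            arr = arr * (1.0 - fp.decay * dt)
        proto_of = _proto_of(state, model)
        for proto, rate in sorted(fp.secretion.items()):
            tids = [p.vtk_type_id for p in model.prototypes.values()
                    if p.name == proto]
            if tids and tids[0] is not None:
                arr[snap.cell_type == tids[0]] += rate * dt
        for proto, rate in sorted(fp.uptake.items()):
            tids = [p.vtk_type_id for p in model.prototypes.values()
                    if p.name == proto]
            if tids and tids[0] is not None:
                m = snap.cell_type == tids[0]
                arr[m] = np.maximum(arr[m] - rate * dt, 0.0)
        snap.fields[fname] = arr

    # (2) phenotypic change
    changed: set[int] = set()
    for spec in model.processes.values():
        if spec.process_class.local_id != "PhenotypicChange":
            continue
        src = spec.participants[0]
        dst = str(spec.parameter_value("target_prototype"))
        fname = str(spec.parameter_value("change_field"))
        thr = float(spec.parameter_value("change_threshold"))
        below = spec.condition == "field_below_threshold"
        if fname not in snap.fields:
            continue
        means = analysis.per_cell_field_mean(snap, fname)
        proto_of = _proto_of(state, model)
        dst_tid = model.prototypes[dst].vtk_type_id
        for cid in sorted(means):
            if cid in changed or proto_of.get(cid) != src:
                continue
            v = means[cid]
            if (v < thr) if below else (v > thr):
                snap.cell_type[snap.cell_id == cid] = dst_tid
                changed.add(cid)
                state.event_log.append((now, "phenotype_change", (cid,)))

    # (3) necrosis bookkeeping
    proto_of = _proto_of(state, model)
    for spec in model.processes.values():
        if spec.process_class.local_id != "Necrosis":
            continue
        dec = float(spec.parameter_value("necrosis_decrement", 0.5))
        for cid in sorted(state.target_volume):
            if proto_of.get(cid) == spec.participants[0]:
                state.target_volume[cid] -= dec
                state.surface_coefficient[cid] = 0.0

    # (4) growth
    for spec in model.processes.values():
        if spec.process_class.local_id != "CellGrowth":
            continue
        rate = float(spec.parameter_value("growth_rate",
                                          spec.parameter_value("rate", 0.0)))
        for cid in sorted(state.target_volume):
            if proto_of.get(cid) == spec.participants[0]:
                state.target_volume[cid] += rate * dt

    # (5) volume relaxation: one boundary voxel per cell per step
    counts = np.bincount(snap.cell_id.ravel())
    for cid in sorted(state.target_volume):
        actual = int(counts[cid]) if cid < len(counts) else 0
        target = state.target_volume[cid]
        if actual == 0:
            continue
        mask = snap.cell_id == cid
        if actual < target:
            cands = _grow_candidates(mask, snap.cell_id == 0)
            if len(cands):
                x, y, z = cands[0]
                snap.cell_id[x, y, z] = cid
                snap.cell_type[x, y, z] = int(snap.cell_type[mask][0])
        elif actual > target:
            cands = _shed_candidates(mask)
            if len(cands):
                x, y, z = cands[0]
                snap.cell_id[x, y, z] = 0
                snap.cell_type[x, y, z] = 0

    # (6) division
    thresholds: dict[str, float] = {}
    for spec in model.processes.values():
        if spec.process_class.local_id == "CellDivision":
            thresholds[spec.participants[0]] = float(
                spec.parameter_value("division_threshold", np.inf))
    proto_of = _proto_of(state, model)
    counts = np.bincount(snap.cell_id.ravel())
    for cid in sorted(state.target_volume):
        thr = thresholds.get(proto_of.get(cid, ""), np.inf)
        n = int(counts[cid]) if cid < len(counts) else 0
        if n < thr or n < 2:
            continue
        vox = np.argwhere(snap.cell_id == cid)
        extents = vox.max(axis=0) - vox.min(axis=0)
        axis = int(np.argmax(extents))
        order = np.lexsort(
            tuple(vox[:, a] for a in reversed([axis] + [a for a in range(3) if a != axis]))
        )
        upper = vox[order][n // 2 :]
        child = state.next_id
        state.next_id += 1
        snap.cell_id[tuple(upper.T)] = child
        half = state.target_volume[cid] / 2.0
        state.target_volume[cid] = half
        state.target_volume[child] = half
        state.surface_coefficient[child] = state.surface_coefficient.get(cid, 1.0)
        state.event_log.append((now, "division", (cid, child)))

    # (7) death
    counts = np.bincount(snap.cell_id.ravel())
    for cid in sorted(state.target_volume):
        n = int(counts[cid]) if cid < len(counts) else 0
        if n == 0 or state.target_volume[cid] <= 0.0:
            if n:
                m = snap.cell_id == cid
                snap.cell_id[m] = 0
                snap.cell_type[m] = 0
            del state.target_volume[cid]
            state.surface_coefficient.pop(cid, None)
            state.event_log.append((now, "death", (cid,)))
    return state


# --------------------------------------------------------------------------
# series output
# --------------------------------------------------------------------------

def _painted_snapshot(state: SimState) -> LatticeSnapshot:
    """Snapshot copy with the reserved TargetVolume field painted."""
    snap = state.snapshot
    tv = np.zeros(snap.dims, dtype=np.float64)
    for cid, target in state.target_volume.items():
        tv[snap.cell_id == cid] = target
    fields = {k: v.copy() for k, v in snap.fields.items()}
    fields[analysis.TARGET_VOLUME_FIELD] = tv
    return LatticeSnapshot(
        dims=snap.dims,
        cell_id=snap.cell_id.copy(),
        cell_type=snap.cell_type.copy(),
        fields=fields,
    )


def run(scenario: Scenario, out_dir, seed: int = 0,
        n_steps: int | None = None,
        output_every: int | None = None) -> tuple[SeriesLink, list]:
    """Run a scenario and write its snapshot series.

    Writes ``<root>_<10-digit step>.vtk`` snapshots (indices are elapsed
    model steps), the meta-model with its series link (``<root>.omn``) and
    the ground-truth ``events.tsv``.  Returns the series link and the
    event log as ``(step, kind, ids)`` tuples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_steps = scenario.n_steps if n_steps is None else n_steps
    output_every = scenario.output_every if output_every is None else output_every
    if output_every < 1:
        raise CBOError("output_every must be >= 1")

    state = initialize(scenario, seed)
    root = scenario.file_root
    write_structured_points(_painted_snapshot(state), out_dir / snapshot_filename(root, 0))
    for _ in range(n_steps):
        step(state, scenario)
        if state.step_index % output_every == 0:
            write_structured_points(
                _painted_snapshot(state),
                out_dir / snapshot_filename(root, state.step_index),
            )
    # the exported meta-model names its directory relative to itself, so
    # identical seeds give byte-identical output directories anywhere
    link_vtk_series(scenario.model, root, snapshot_filename(root, 0),
                    scenario.dt, ".")
    export_metamodel(scenario.model, out_dir / f"{root}.omn")
    link = link_vtk_series(
        scenario.model, root, snapshot_filename(root, 0), scenario.dt, str(out_dir)
    )
    dt = float(scenario.dt.value)
    lines = ["step\ttime_minutes\tkind\tids"]
    for s, kind, ids in state.event_log:
        lines.append(f"{s}\t{s * dt:g}\t{kind}\t{','.join(map(str, ids))}")
    (out_dir / "events.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return link, list(state.event_log)
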