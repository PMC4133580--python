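# cbokit

A toolkit for describing multicell systems — tissues, *in vitro* assays,
agent-based simulations — with the **Cell Behavior Ontology (CBO)**, and for
joining those descriptions to the spatial snapshot data they annotate.

Multicell modeling platforms each use their own model-description language,
so the *biology* a simulation encodes (which cell types exist, which grow,
divide, die, adhere, chemotax) is usually locked up in code and prose. The
CBO approach separates the two concerns:

* a **meta-model** — a small ontology extending the CBO with model-specific
  *prototype classes* (cell and field types) and *process classes* (growth,
  division, necrosis, adhesion, phenotypic change, ...) attached to those
  prototypes — carries the semantics;
* **legacy-VTK snapshot files** (`STRUCTURED_POINTS` voxel lattices for
  grid models, `POLYDATA` center/radius sets for center models) carry the
  spatiality, one file per time point, named
  `<root>_<zero-padded-index>.vtk` so that simulated time =
  index × file-time-step.

cbokit implements both halves and the semantics that join them: per-cell
morphometrics from label lattices, contact graphs, conditional process
instantiation (adhesion between two cells exists **iff** they are in
contact), event inference across a series, a deterministic toy simulator
that emits conformant series, and an annotator that embeds/extracts CBO
term paths in source-code comments.

## Who this is for

Modelers who want their lattice or center-model simulations (GGH/CPM-style
platforms such as CompuCell3D, and anything else that can write legacy
VTK) to carry a machine-readable statement of their biology, and analysts
who want to compute per-cell quantities and events from such snapshot
series without touching the simulator that produced them.

## Core concepts

| Concept | Meaning |
|---|---|
| `CBO_Object` / `CBO_Process` | continuants (cells, fields, qualities) vs occurrents (processes), the two roots of the hierarchy |
| Corpuscular / Continuous / Diffuse | how an entity occupies space: spatially exclusive with a boundary (a cell); boundary-less portion (medium); an overlay field (a chemical concentration) |
| Prototype class | a model-specific class with dual parentage — biological (`Cell`, `Field`) and physical (`CorpuscularEntity`, ...) — whose instances inherit its qualities and processes |
| VTK TypeID | the integer a snapshot file uses for members of a prototype (`hasVTKTypeID`); 0 is reserved for medium |
| actual vs target value | a quality's current value vs its set-point (`hasFloatValue` / `hasFloatValueTarget`), e.g. actual and target cell volume |
| Series link | file root + zero-index initial file + file time step: the contract that converts snapshot file names into simulated times |

Meta-models are read and written in a constrained Manchester-syntax
dialect (`.omn`): `Class:` blocks with `SubClassOf:` / `EquivalentTo:`
clauses and `Individual:` blocks with `Types:` / `Facts:` clauses.

## Worked example

The bundled listing `use_case_1.omn` describes a published tumor-growth-
with-angiogenesis model: a 180×180×180 voxel lattice (5 832 000 lattice
points per snapshot, i.e. 5.8 million), voxel edge 4.44 µm, snapshot series
rooted at `use_case_1` with a 1-minute file time step.

```python
from cbokit import metamodel as mm, vtkio, load_core_hierarchy

frag = mm.load_use_case_fragment()
link = mm.series_link_from_fragment(frag)
t = vtkio.decode_snapshot_time("use_case_1_0000000600.vtk", link)
print(t.value, t.unit)          # 600.0 UO:minute

h = load_core_hierarchy()
h.merge_fragment(frag)
q = h.resolve_quality("TumorGrowthWithAngiogenesis", "SystemPixelDistanceScale")
print(q.value, q.unit)          # 4.44 UO:micrometer
```

The snapshot indexed 600 sits at simulated time 600 min (index × 1 minute),
and the system's pixel distance scale resolves to a 4.44 µm voxel edge —
so a one-voxel cell has volume 4.44³ ≈ 87.53 µm³.

A reduced-scale synthetic version of the same model ships as a simulator
scenario (20³ lattice, tumor/hypoxic/necrotic prototypes, nutrient and
signal fields):

```
$ cbo simulate --scenario tumor_angiogenesis_mini --steps 30 --out run/ --seed 1
wrote series 'tumor_mini' to run/ (6 logged events)
$ cbo extract run/tumor_mini.omn --dir run/ -o cells.tsv
$ cbo events run/tumor_mini.omn --dir run/
30	division	1,7
30	division	2,8
...
```

(The six seeded cells all divide during the third 10-minute snapshot
interval; events inferred between snapshots are stamped with the later
snapshot's time, so at the default 10-step output cadence the divisions
report as time 30.)

`cells.tsv` holds one row per cell per snapshot (time, prototype, voxel
count, volume, centroid, surface, per-field means); `cbo events` prints
the divisions, deaths and phenotype changes inferred between consecutive
snapshots. Cells starve as they deplete the nutrient field, turn hypoxic
below the threshold, then necrotic; necrotic cells lose 0.5 of target
volume per step with their surface coupling zeroed, shrink, and die.

Source-code annotation round-trips through plain comments:

```
$ cbo annotate steppable.py --line 12 --terms "CBO_Process CellProcess CellGrowth"
$ cbo scan src/ -o index.json
$ cbo search index.json CBO_Process CellDeath
```

## Layout

```
src/cbokit/ontology.py    class hierarchy, CURIEs, qualities, Manchester dialect
src/cbokit/metamodel.py   system/prototype/process construction, validation, export
src/cbokit/vtkio.py       legacy-VTK lattice & center snapshots, series conventions
src/cbokit/analysis.py    per-cell geometry, contacts, process instances, events
src/cbokit/simulate.py    deterministic toy simulator emitting conformant series
src/cbokit/annotate.py    source-code annotation, extraction, search index
src/cbokit/cli.py         the `cbo` command
docs/methods.md           models, conventions, parameter choices, limitations
```
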