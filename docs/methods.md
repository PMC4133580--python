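# Methods

This note records the models, conventions and numerical choices behind
cbokit, the reasoning where the design was genuinely open, and what the
synthetic scenarios do and do not establish about real data.

## The ontology layer

The bundled class hierarchy is a working subset of the CBO: the universal
class with its two children `CBO_Object` (continuants: physical entities
and their qualities) and `CBO_Process` (occurrents), the physical-entity
trichotomy (corpuscular / continuous / diffuse), the biological entity
types (`Cell`, `Field`, `Medium`, `ExtracellularMatrix`), system
bookkeeping qualities (extent, pixel distance scale, boundary condition,
temporal interval, the VTK series-link classes, computational platform)
and the process families (cell processes including growth, division,
death/necrosis, adhesion, phenotypic change, secretion, consumption and
chemotaxis; field processes; fundamental physical processes including
barrier crossing). The full released CBO has on the order of 240 classes;
only the subset needed to express lattice and center-model meta-models is
bundled. External reference-ontology terms (GO, MP, CL, PATO, UO) appear
as opaque CURIEs — there is no IRI expansion or import resolution, and no
OWL-DL reasoning beyond transitive subclass/instance closure. These are
deliberate non-goals: the toolkit's job is meta-model mechanics, not
general ontology processing.

Relations are a closed set: an OBO-RO-style object-relation subset plus
`has_Quality` (added as first-class because some OBO-RO releases lack
it), the literal-valued data relations `hasIntValue` / `hasFloatValue` /
`hasStringValue`, their `...Target` twins for set-points, `hasUnit`, and
`hasVTKTypeID`. The actual/target split matters because most multicell
modeling paradigms give a cell both a current and a target value of a
quality (volume, above all), and the difference drives the dynamics.

**Units.** A small built-in registry (micrometer, millimeter, meter,
nanometer; second, minute, hour, day) keyed by `UO:`-style CURIEs with SI
conversion factors. The length/time scales of cell-resolved tissue models
fall entirely inside this range, so no external unit ontology is
imported. Dimension checks are enforced where a quantity's meaning
requires them (distance scales must be lengths, time steps times).

**The Manchester dialect.** Meta-models are exchanged in a constrained
Manchester-syntax dialect rather than full OWL: `Class:` blocks
(`SubClassOf:`, `EquivalentTo:` with `relation value literal` data
restrictions, `Annotations:`, `Facts:`) and `Individual:` blocks
(`Types:`, `Facts:`, `Annotations:`). The parser is whitespace- and
line-folding-insensitive — block and clause keywords may appear anywhere
on a line, because published listings fold lines mid-clause — and accepts
both straight and typographic double quotes, which printed listings mix
freely. The serializer is deterministic (classes then individuals, each
alphabetical; facts in insertion order; shortest-round-trip float
rendering), so export is reproducible byte-for-byte and
`parse ∘ serialize` is an identity up to fact ordering.

## Meta-model construction and validation

Construction mirrors how a modeler describes a simulation: system →
prototypes → processes → series link.

* **System**: lattice extent, per-axis boundary behavior (wall or
  periodic; wall is the default), pixel distance scale (a length
  quality), platform, biology cross-references. 1D/2D extents are padded
  with implied unit lengths, and the declared dimensionality is kept so
  that volumes stay well defined across dimensionalities (a 2D cell's
  "volume" is voxel count × scale² × 1).
* **Prototypes** get dual parentage — a biological parent under
  `BioEntityType` and one of the three physical types. Corpuscular
  prototypes must carry a unique VTK TypeID; diffuse prototypes name the
  snapshot field they map to. TypeID 0 is reserved for medium/background:
  label lattices need a non-cell label, and no published table assigns
  medium an ID. The bundled tumor scenario fixes Medium=0, TumorCell=1,
  HypoxicTumorCell=2, NecroticTumorCell=3 — IDs 1 (tumor) and 3 (necrotic
  gating) follow the published worked example, the rest are assigned
  here.
* **Processes** attach to one participant (growth, division, death,
  phenotypic change, secretion, consumption) or two (cell–cell adhesion).
  Pairwise participants are stored order-normalized (alphabetical), so
  defining (A, B) and querying (B, A) hit the same spec — adhesion
  between two prototypes is one relationship, not two. Subphenotypes
  (hypoxic, necrotic) are modeled as sibling prototypes linked by
  `PhenotypicChange` processes rather than nested subclasses: the
  interconversion is a process with its own threshold parameters, and
  sibling prototypes keep the TypeID ↔ prototype mapping a bijection.
* **The series link** names the file root, the all-zero-index initial
  file and the file time step (a positive time quality) — the multiplier
  that converts a snapshot file name's integer suffix into simulated
  time.

`validate_metamodel` returns coded violations (`MISSING_TYPEID`,
`DUPLICATE_TYPEID`, `UNRESOLVED_PARTICIPANT`, `BAD_ARITY`, `NO_SYSTEM`,
`BAD_SERIES_LINK`, `UNKNOWN_UNIT`) as data rather than exceptions, and an
empty list is the precondition for export. Export/import round-trips
every field; quality parameters ride along as quality individuals named
`<owner>_q<i>` / `<owner>_p_<name>`.

## VTK snapshot conventions

Only ASCII legacy VTK is supported, in two dialects: `STRUCTURED_POINTS`
(per-voxel `CellId` and `CellType` int arrays plus one float array per
named field, values x-fastest then y then z) and `POLYDATA` (sphere
centers with `Radius`, `CellId`, `CellType`). Array names, ASCII
encoding and `POINT_DATA` placement are fixed as the interoperability
contract so golden-file tests are deterministic; the reader tolerates
arbitrary line wrapping of value lists. `SPACING` is written as `1 1 1`:
snapshot files stay scale-agnostic, with physical scale carried by the
meta-model's pixel distance scale — spatiality and semantics separate
cleanly. Writers zero-pad time indices to 10 digits (the width used in
the published file names); readers accept any width. Floats are written
with 9 significant digits, which round-trips the toolkit's own outputs
losslessly at that precision.

Whether published supplementary files store cell type as its own array or
derive it from ID ranges is not documented anywhere we could check; two
arrays are used here, with the invariant (enforced on read and write)
that every nonzero cell id carries exactly one type across its voxels.

## Per-cell analysis

Adjacency is the 6-neighborhood: faces are the natural area-bearing
adjacency on a cubic lattice and match GGH conventions, so surface =
exposed faces × scale² and contact area between two cells = shared faces
× scale². Under wall boundaries a voxel face on the domain edge counts
toward the cell's surface and is booked against a boundary sentinel id
(−1) in the contact map, so the decomposition

    surface(a) = Σ_b faces(a, b) × scale²   (b over cells, medium, boundary)

closes exactly; periodic axes wrap instead. Centroids are mean voxel-center
positions ((index + ½) × scale). Cells may be voxel-disconnected (GGH
cells can fragment); volume counts all voxels with the id and
`fragment_count` reports 6-connected components.

Conditional processes follow the iff-contact rule: a contact-conditioned
adhesion instance exists between two cells exactly when they share at
least one face, with magnitude = contact area. Field-threshold conditions
(used by phenotypic-change specs) compare a cell's mean field value
against the spec's threshold. Spatial exclusivity is vacuous for a
single-id-array lattice; for center models a pair violates it when center
distance < (r_a + r_b)(1 − tolerance). The center-model contact rule is
an extension beyond any published definition and is only used there.

**Event inference** between consecutive snapshots: a vanished id is a
death; a persistent id with a new type is a phenotype change; a new id is
attributed to the parent whose previous-snapshot voxels it overlaps most
(a daughter occupies part of the parent's old footprint), falling back to
the nearest shrinking cell by centroid, and to a creation event if no
candidate exists. Overlap attribution was chosen over nearest-centroid
alone because simultaneous divisions of adjacent cells make the nearest
shrinking centroid ambiguous, while footprint overlap is exact whenever
the sampling interval contains a single division of that cell. Inference
can only see what snapshots sample: at coarse output cadences multiple
events within one interval collapse, so ground-truth event logs from the
simulator remain the authoritative record and the inference is validated
against them at one-step cadence.

**Per-cell target volumes in snapshots.** Snapshots carry a reserved
float field `TargetVolume`, painted with the owning cell's target volume
over its voxels (0 in medium). Individuals and their qualities live
outside the ontology file by design, and the lattice dialect has no
per-cell attribute block, so painting set-points onto the lattice is the
least invasive way to round-trip them; analysis reads the field back as a
target-volume quality per cell and excludes it from chemical field
statistics.

## The toy simulator

The simulator is a fixture generator: it interprets a meta-model's
process specs as simple deterministic lattice dynamics so that snapshot
series with known ground truth can be produced at will. It deliberately
does **not** implement GGH/CPM energy minimization — cells relax toward
their target volumes by adding or removing one boundary voxel per step,
chosen at the lowest lexicographic coordinate among candidates. All
tie-breaks are lexicographic; the single seeded RNG is used only for
initial cell placement, so identical seeds give byte-identical output
directories. Step order: fields (explicit-Euler diffusion, decay,
secretion/uptake with uptake floored at the available mass) → phenotypic
change → necrosis bookkeeping (target −= decrement, surface coefficient
0) → growth (target += rate·dt) → volume relaxation → division (bisect
along the longest axis at `division_threshold` voxels; daughters share
the prototype and halve the target) → death (no voxels or non-positive
target). Every event is logged as (step, kind, ids).

Diffusion uses the 7-point explicit stencil with the stability bound
D·dt/h² ≤ 1/6 enforced at scenario construction and on every call.
Zero-flux boundaries mirror the edge value, which conserves total mass
exactly (the tests require ≤1e-6 relative over 100 steps and observe
~1e-15); periodic boundaries wrap.

### The `tumor_angiogenesis_mini` scenario

A reduced-scale rendition of the tumor-growth use case: 20³ voxel lattice
(the full model is 180³ with thousands of cells; reproducing its
unpublished platform physics and parameters is out of scope), wall
boundaries, 4.44 µm voxel edge, dt = 1 minute matching the use case's
file time step, six single-voxel tumor cells seeded in the central
region, and two diffusible fields — a nutrient and one secreted signal.
The published description is ambiguous between two and three fields ("two
diffusible fields" vs an enumeration naming two signals plus a nutrient);
the scenario declares two and documents the discrepancy rather than
resolving it.

Process parameters (per minute, lattice units; volumes in voxels):

| parameter | value | rationale |
|---|---|---|
| tumor growth rate | 0.5 | reaches the division threshold in ~24 min from a fresh daughter — fast for biology, sized so divisions occur within short runs |
| hypoxic growth rate | 0.1 | hypoxia slows growth |
| division threshold | 16 voxels | a 2-cell-diameter cube at this scale |
| hypoxia threshold | nutrient < 0.5 | half the initial supply |
| recovery threshold | nutrient > 0.65 | hysteresis so cells do not flicker between phenotypes |
| necrosis threshold | nutrient < 0.15 | deep starvation |
| necrosis decrement | 0.5 per step | the one dynamics constant the worked example publishes |
| nutrient uptake (tumor/hypoxic) | 0.05 / 0.02 | sized so a growing colony depletes its neighborhood within simulated hours |
| signal secretion (hypoxic) | 0.05 | hypoxic cells emit the angiogenic signal |
| field diffusion D | 0.1 | inside the 1/6 stability bound at dt = 1 |
| signal decay | 0.02 | keeps the signal localized around its source |

Only the 0.5 necrosis decrement is a published constant; every other
number is this package's own choice of a plausible regime, picked once so
that the reduced scenario exhibits the use case's qualitative repertoire
(growth → division; local nutrient depletion → hypoxia → necrosis →
death) within a 100-step desk-scale run, and not revisited. Endothelial
prototypes and chemotaxis-biased accretion are omitted from the bundled
scenario; chemotaxis in particular would be a biased-accretion
simplification of real cell-field dynamics and is left out rather than
misrepresented.

`two_cell_toy` is the minimal fixture: 8³ lattice, two adjacent 2×2×2
cube cells of one prototype, one contact-conditioned adhesion process, no
growth — a static series whose every quantity is checkable by hand.

### What the synthetic scenarios do and do not show

They exercise the conventions and semantics end to end: dialect and VTK
round trips, TypeID mapping, time decoding, geometry/contact identities,
conditional-process instantiation, event inference against ground truth.
They do not validate tissue mechanics (no surface energetics, no realistic
cell shapes — accretion produces compact but arbitrary morphologies), field
physics beyond linear diffusion/decay, or any quantitative claim about the
full-scale published model. Passing tests establish that the toolkit's
bookkeeping is exact, not that the toy dynamics resemble tumor biology.

## Test and verification sizes

Property suites run at desk scale chosen for exhaustive oracles: random
DAGs ≤ 50 nodes against graph reachability, random lattices ≤ 10³ against
brute-force face scans, 100 randomized meta-models through the
export/import round trip, and one 60-step mini-scenario run at one-step
output cadence whose inferred events are compared set-exactly against the
simulator's log. The acceptance script touches no simulation: it parses
the bundled series-link listing and decodes the published example
snapshot's time through the file-name convention.

## Known limitations

* No OWL/RDF serialization; the dialect covers the constructs the
  toolkit itself emits, not arbitrary Manchester syntax (no cardinality
  restrictions, no general class expressions).
* Binary and XML VTK, `CELL_DATA`, vectors/tensors, rectilinear and
  unstructured grids are unsupported.
* Fragment counting ignores periodic wrap (a cell spanning a periodic
  seam counts as two fragments).
* Event inference degrades with coarse snapshot cadence by construction;
  there is no tracking across division for center models.
* The annotator's index is a token index over whole files, which is the
  point (web indexers see whole files), but it therefore cannot
  distinguish a term in an annotation from the same token in code.
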