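"""Meta-model construction: system, prototypes, processes, VTK series link.

A meta-model is a new ontology extending the CBO with the classes and
individuals that describe one particular multicell model.  Construction
follows four steps:

1. define the spatiotemporal domain (the *system*): lattice extent,
   voxel distance scale, boundary behavior, computational platform;
2. define prototype cell/field classes with dual parentage — a biological
   parent (``Cell``, ``Field``...) and a physical-entity type
   (corpuscular / continuous / diffuse) — plus a VTK TypeID for
   corpuscular prototypes;
3. attach process classes (growth, division, death, adhesion, phenotypic
   change, secretion...) to prototype participants, optionally with an
   occurrence condition (e.g. adhesion iff contact);
4. link the meta-model to a legacy-VTK snapshot series via a file root,
   an initial-condition file and a per-index time step.

Exported meta-models are Manchester-dialect text; ``import_metamodel``
restores them field-by-field.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import units
from .errors import (
    ArityError,
    ConflictError,
    ConventionError,
    DomainError,
    IncompleteError,
    ReferenceError_,
    UnitError,
    ValidationError,
)
from .ontology import (
    ClassDecl,
    ClassHierarchy,
    Curie,
    Fragment,
    Individual,
    Quality,
    RelationKind,
    load_core_hierarchy,
    parse_manchester,
    serialize_manchester,
)

__all__ = [
    "SystemSpec",
    "PrototypeClass",
    "ProcessSpec",
    "SeriesLink",
    "MetaModel",
    "Violation",
    "MEDIUM_TYPE_ID",
    "define_system",
    "define_prototype",
    "define_process",
    "link_vtk_series",
    "validate_metamodel",
    "export_metamodel",
    "import_metamodel",
    "series_link_from_fragment",
    "load_use_case_fragment",
]

#: VTK TypeID reserved for the medium/background label in lattice files
MEDIUM_TYPE_ID = 0

_PHYSICAL_CLASSES = {
    "Corpuscular": Curie("CBO", "CorpuscularEntity"),
    "Continuous": Curie("CBO", "ContinuousEntity"),
    "Diffuse": Curie("CBO", "DiffuseEntity"),
}
_PHYSICAL_BY_CLASS = {v: k for k, v in _PHYSICAL_CLASSES.items()}

#: process classes that require exactly two participants
_PAIRWISE_CLASSES = {"CellCellAdhesion"}

_CONDITIONS = ("always", "contact_required", "field_below_threshold",
               "field_above_threshold")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SystemSpec:
    """The model universe: extent, scale, boundaries, platform."""

    name: str
    extent: tuple[int, int, int]
    distance_scale: Quality
    boundary: tuple[str, str, str] = ("wall", "wall", "wall")
    platform: str = ""
    biology_xrefs: frozenset[Curie] = frozenset()
    declared_dimensionality: int = 3


@dataclass
class PrototypeClass:
    """A model-specific cell or field class with dual parentage."""

    name: str
    bio_parent: Curie
    physical_type: str  # Corpuscular | Continuous | Diffuse
    vtk_type_id: int | None = None
    field_name: str | None = None
    xrefs: frozenset[Curie] = frozenset()
    default_qualities: tuple[Quality, ...] = ()


@dataclass
class ProcessSpec:
    """A process class attached to one or two prototype participants."""

    name: str
    process_class: Curie
    participants: tuple[str, ...]
    parameters: dict[str, Quality] = field(default_factory=dict)
    condition: str = "always"

    def parameter_value(self, name: str, default=None):
        q = self.parameters.get(name)
        return default if q is None else q.value


@dataclass
class SeriesLink:
    """Link from a meta-model to its snapshot series on disk.

    ``time_step`` is the temporal-interval multiplier: simulated time =
    (integer suffix of the file name) x time_step.
    """

    file_root: str
    initial_file: str
    time_step: Quality
    directory: str = "."


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


@dataclass
class MetaModel:
    system: SystemSpec | None = None
    prototypes: dict[str, PrototypeClass] = field(default_factory=dict)
    processes: dict[str, ProcessSpec] = field(default_factory=dict)
    series: SeriesLink | None = None
    extra: Fragment = field(default_factory=Fragment)

    # -- lookup ------------------------------------------------------------

    def prototype_by_type_id(self, type_id: int) -> PrototypeClass:
        for p in self.prototypes.values():
            if p.vtk_type_id == type_id:
                return p
        from .errors import MappingError

        raise MappingError(f"no prototype with VTK TypeID {type_id}")

    def type_id_map(self) -> dict[int, str]:
        """TypeID -> prototype name for every prototype carrying an ID."""
        return {
            p.vtk_type_id: p.name
            for p in self.prototypes.values()
            if p.vtk_type_id is not None
        }

    def find_process(self, participants) -> ProcessSpec | None:
        """Retrieve a process by participant set, order-insensitively for
        pairwise processes: (A, B) and (B, A) hit the same spec."""
        key = tuple(sorted(participants)) if len(participants) > 1 else tuple(participants)
        for spec in self.processes.values():
            if spec.participants == key or tuple(sorted(spec.participants)) == key:
                return spec
        return None

    def processes_for(self, prototype: str) -> list[ProcessSpec]:
        return [s for s in self.processes.values() if prototype in s.participants]

    def hierarchy(self) -> ClassHierarchy:
        """Core CBO subset extended with this model's T-Box classes."""
        h = load_core_hierarchy()
        for p in self.prototypes.values():
            h.add_class(Curie("MM", p.name),
                        [p.bio_parent, _PHYSICAL_CLASSES[p.physical_type]],
                        xrefs=p.xrefs)
        for s in self.processes.values():
            h.add_class(Curie("MM", s.name), [s.process_class])
        h.validate()
        return h


# --------------------------------------------------------------------------
# construction operations
# --------------------------------------------------------------------------

def define_system(
    name: str,
    extent,
    distance_scale: Quality,
    boundary="wall",
    platform: str = "",
    biology_xrefs=(),
) -> SystemSpec:
    """Create the system spec.  1D/2D extents are padded with implied unit
    lengths so volumes stay well defined across dimensionalities."""
    if not name or len(name.split()) != 1:
        raise DomainError(f"system name must be a single token, got {name!r}")
    ext = tuple(int(e) for e in extent)
    if not 1 <= len(ext) <= 3:
        raise DomainError(f"extent needs 1-3 components, got {len(ext)}")
    if any(e < 1 for e in ext):
        raise DomainError(f"extent components must be >= 1, got {ext}")
    dim = len(ext)
    ext = ext + (1,) * (3 - dim)
    if not isinstance(distance_scale.unit, Curie) or not units.is_length(distance_scale.unit):
        raise UnitError("distance_scale must carry a length unit")
    if float(distance_scale.value) <= 0:
        raise DomainError("distance_scale must be positive")
    if isinstance(boundary, str):
        boundary = (boundary,) * 3
    boundary = tuple(boundary)
    if len(boundary) != 3 or any(b not in ("wall", "periodic") for b in boundary):
        raise DomainError(f"boundary must be wall/periodic per axis, got {boundary}")
    return SystemSpec(
        name=name,
        extent=ext,
        distance_scale=distance_scale,
        boundary=boundary,
        platform=str(platform),
        biology_xrefs=frozenset(biology_xrefs),
        declared_dimensionality=dim,
    )


def define_prototype(
    model: MetaModel,
    name: str,
    bio_parent: Curie | str,
    physical_type: str,
    vtk_type_id: int | None = None,
    xrefs=(),
    default_qualities=(),
) -> PrototypeClass:
    """Register a prototype class with dual parentage and a unique TypeID."""
    if name in model.prototypes:
        raise ConflictError(f"prototype {name!r} already defined")
    if physical_type not in _PHYSICAL_CLASSES:
        raise DomainError(f"physical_type must be one of {sorted(_PHYSICAL_CLASSES)}")
    core = load_core_hierarchy()
    bio = core.resolve(bio_parent)
    if not core.is_subclass_of(bio, Curie("CBO", "BioEntityType")):
        raise ReferenceError_(f"{bio} is not under BioEntityType")
    if physical_type == "Corpuscular":
        if vtk_type_id is None:
            raise IncompleteError(f"corpuscular prototype {name!r} needs a VTK TypeID")
        if vtk_type_id == MEDIUM_TYPE_ID:
            raise ConflictError(
                f"TypeID {MEDIUM_TYPE_ID} is reserved for medium/background"
            )
    field_name = None
    if physical_type == "Diffuse":
        field_name = name
    if vtk_type_id is not None:
        for p in model.prototypes.values():
            if p.vtk_type_id == vtk_type_id:
                raise ConflictError(
                    f"TypeID {vtk_type_id} already used by {p.name!r}"
                )
    proto = PrototypeClass(
        name=name,
        bio_parent=bio,
        physical_type=physical_type,
        vtk_type_id=vtk_type_id,
        field_name=field_name,
        xrefs=frozenset(Curie.parse(x) if isinstance(x, str) else x for x in xrefs),
        default_qualities=tuple(default_qualities),
    )
    model.prototypes[name] = proto
    return proto


def define_field_prototype(
    model: MetaModel, name: str, field_name: str | None = None, xrefs=(),
) -> PrototypeClass:
    """Convenience: a diffuse field prototype (named scalar lattice)."""
    proto = define_prototype(model, name, Curie("CBO", "Field"), "Diffuse", None, xrefs)
    proto.field_name = field_name or name
    return proto


def define_process(
    model: MetaModel,
    name: str,
    process_class: Curie | str,
    participants,
    parameters: dict[str, Quality] | None = None,
    condition: str = "always",
) -> ProcessSpec:
    """Attach a process class to its prototype participants.

    Pairwise processes (cell-cell adhesion) store their participant pair
    order-normalized (alphabetical), so (A, B) and (B, A) are one spec.
    """
    if name in model.processes:
        raise ConflictError(f"process {name!r} already defined")
    core = load_core_hierarchy()
    pclass = core.resolve(process_class)
    if not core.is_subclass_of(pclass, Curie("CBO", "CBO_Process")):
        raise ReferenceError_(f"{pclass} is not under CBO_Process")
    parts = tuple(participants)
    for p in parts:
        if p not in model.prototypes:
            raise ReferenceError_(f"undeclared participant prototype {p!r}")
    want = 2 if pclass.local_id in _PAIRWISE_CLASSES else 1
    if len(parts) != want:
        raise ArityError(
            f"{pclass.local_id} takes {want} participant(s), got {len(parts)}"
        )
    if len(parts) == 2:
        parts = tuple(sorted(parts))
    if condition not in _CONDITIONS:
        raise DomainError(f"condition must be one of {_CONDITIONS}")
    parameters = dict(parameters or {})
    if pclass.local_id == "PhenotypicChange":
        target = parameters.get("target_prototype")
        if target is None or target.value not in model.prototypes:
            raise ReferenceError_(
                f"PhenotypicChange {name!r} needs a declared target_prototype"
            )
        if target.value == parts[0]:
            raise ConflictError(
                f"PhenotypicChange {name!r} target equals its participant"
            )
    spec = ProcessSpec(name, pclass, parts, parameters, condition)
    model.processes[name] = spec
    return spec


_SERIES_FILE_RE = re.compile(r"^(?P<root>.+)_(?P<digits>\d+)\.vtk$")


def link_vtk_series(
    model: MetaModel,
    file_root: str,
    initial_file: str,
    time_step: Quality,
    directory: str = ".",
) -> SeriesLink:
    """Store the VTK series link (file root, zero-index initial file,
    per-index time step)."""
    if float(time_step.value) <= 0:
        raise DomainError("time step must be positive")
    if time_step.unit is None or not units.is_time(time_step.unit):
        raise UnitError("time step must carry a time unit")
    m = _SERIES_FILE_RE.match(initial_file)
    if m is None or m.group("root") != file_root:
        raise ConventionError(
            f"initial file {initial_file!r} does not match <{file_root}>_<digits>.vtk"
        )
    if int(m.group("digits")) != 0:
        raise ConventionError(
            f"initial-condition file must have an all-zero index, got {initial_file!r}"
        )
    link = SeriesLink(
        file_root,
        initial_file,
        replace(time_step, quality_class=Curie("CBO", "VTK_FileTimeStep")),
        str(directory),
    )
    model.series = link
    return link


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_metamodel(model: MetaModel) -> list[Violation]:
    """Well-formedness check; empty list means exportable."""
    out: list[Violation] = []
    if model.system is None:
        out.append(Violation("NO_SYSTEM", "no system defined"))
    else:
        scale = model.system.distance_scale
        if scale.unit is None or not units.is_known(scale.unit):
            out.append(Violation("UNKNOWN_UNIT", f"distance scale unit {scale.unit}"))
    seen_ids: dict[int, str] = {}
    for p in model.prototypes.values():
        if p.physical_type == "Corpuscular" and p.vtk_type_id is None:
            out.append(Violation("MISSING_TYPEID", f"prototype {p.name!r}"))
        if p.vtk_type_id is not None:
            if p.vtk_type_id in seen_ids:
                out.append(
                    Violation(
                        "DUPLICATE_TYPEID",
                        f"TypeID {p.vtk_type_id}: {seen_ids[p.vtk_type_id]!r} and {p.name!r}",
                    )
                )
            seen_ids[p.vtk_type_id] = p.name
        for q in p.default_qualities:
            if q.unit is not None and not units.is_known(q.unit):
                out.append(Violation("UNKNOWN_UNIT", f"{p.name!r} quality unit {q.unit}"))
    for s in model.processes.values():
        for part in s.participants:
            if part not in model.prototypes:
                out.append(Violation("UNRESOLVED_PARTICIPANT", f"{s.name!r}: {part!r}"))
        want = 2 if s.process_class.local_id in _PAIRWISE_CLASSES else 1
        if len(s.participants) != want:
            out.append(
                Violation("BAD_ARITY", f"{s.name!r}: {len(s.participants)} participants")
            )
        for pname, q in s.parameters.items():
            if q.unit is not None and not units.is_known(q.unit):
                out.append(
                    Violation("UNKNOWN_UNIT", f"{s.name!r} parameter {pname!r}")
                )
    if model.series is not None:
        link = model.series
        ok = True
        if float(link.time_step.value) <= 0:
            ok = False
        if link.time_step.unit is None or not units.is_time(link.time_step.unit):
            ok = False
        m = _SERIES_FILE_RE.match(link.initial_file)
        if m is None or m.group("root") != link.file_root or int(m.group("digits")) != 0:
            ok = False
        if not ok:
            out.append(Violation("BAD_SERIES_LINK", f"{link.file_root!r}"))
    return out


# --------------------------------------------------------------------------
# export / import
# --------------------------------------------------------------------------

def _quality_individual(qid: str, q: Quality) -> Individual:
    kinds_act = {int: RelationKind.HAS_INT_VALUE, float: RelationKind.HAS_FLOAT_VALUE,
                 str: RelationKind.HAS_STRING_VALUE}
    kinds_tgt = {int: RelationKind.HAS_INT_VALUE_TARGET,
                 float: RelationKind.HAS_FLOAT_VALUE_TARGET}
    table = kinds_tgt if q.value_kind == "target" else kinds_act
    kind = table[type(q.value)]
    facts = [(kind, q.value)]
    if q.unit is not None:
        facts.append((RelationKind.HAS_UNIT, q.unit))
    return Individual(qid, [q.quality_class], facts)


def _read_quality_individual(ind: Individual) -> Quality:
    unit = None
    for u in ind.facts_of(RelationKind.HAS_UNIT):
        unit = units.unit_curie(u) if units.is_known(u) else (
            u if isinstance(u, Curie) else Curie.parse(u, default_prefix="UO"))
    qc = ind.types[0] if ind.types else Curie("CBO", "PhysicalObjectQuality")
    for kind, val in ind.facts:
        if kind in (RelationKind.HAS_INT_VALUE, RelationKind.HAS_FLOAT_VALUE,
                    RelationKind.HAS_STRING_VALUE):
            return Quality(qc, val, "actual", unit)
        if kind in (RelationKind.HAS_INT_VALUE_TARGET, RelationKind.HAS_FLOAT_VALUE_TARGET):
            return Quality(qc, val, "target", unit)
    raise ValueError(f"quality individual {ind.id!r} carries no value")


def to_fragment(model: MetaModel) -> Fragment:
    """Render a meta-model as a Manchester-dialect fragment."""
    frag = Fragment(dict(model.extra.classes), dict(model.extra.individuals))

    for p in model.prototypes.values():
        decl = ClassDecl(p.name)
        decl.parents = [p.bio_parent, _PHYSICAL_CLASSES[p.physical_type]]
        if p.vtk_type_id is not None:
            decl.equivalents.append((RelationKind.HAS_VTK_TYPE_ID, p.vtk_type_id))
        for x in sorted(p.xrefs):
            decl.annotations.append(("xref", str(x)))
        if p.field_name is not None:
            decl.annotations.append(("field_name", p.field_name))
        for i, q in enumerate(p.default_qualities):
            qid = f"{p.name}_q{i}"
            frag.individuals[qid] = _quality_individual(qid, q)
            decl.facts.append((RelationKind.HAS_QUALITY, qid))
        frag.classes[p.name] = decl

    for s in model.processes.values():
        decl = ClassDecl(s.name)
        decl.parents = [s.process_class]
        for part in s.participants:
            decl.annotations.append(("participant", part))
        decl.annotations.append(("condition", s.condition))
        for pname in s.parameters:
            qid = f"{s.name}_p_{pname}"
            frag.individuals[qid] = _quality_individual(qid, s.parameters[pname])
            decl.facts.append((RelationKind.HAS_QUALITY, qid))
        frag.classes[s.name] = decl

    sysspec = model.system
    if sysspec is not None:
        sind = Individual(sysspec.name, [Curie("CBO", "System")])
        sind.annotations.append(("boundary", " ".join(sysspec.boundary)))
        sind.annotations.append(("dimensionality", str(sysspec.declared_dimensionality)))
        if sysspec.platform:
            sind.annotations.append(("platform", sysspec.platform))
        for x in sorted(sysspec.biology_xrefs):
            sind.annotations.append(("xref", str(x)))

        ext_id = f"{sysspec.name}_extent"
        frag.individuals[ext_id] = Individual(
            ext_id, [Curie("CBO", "DiscreteExtent")],
            [(RelationKind.HAS_STRING_VALUE, " ".join(map(str, sysspec.extent)))],
        )
        sind.facts.append((RelationKind.HAS_QUALITY, ext_id))

        scale_id = f"{sysspec.name}_pixelScale"
        frag.individuals[scale_id] = _quality_individual(scale_id, sysspec.distance_scale)
        sind.facts.append((RelationKind.HAS_QUALITY, scale_id))

        if model.series is not None:
            link = model.series
            root_id = f"{sysspec.name}_VTK_FileRoot"
            init_id = f"{sysspec.name}_VTK_InitialFile"
            step_id = f"{sysspec.name}_VTK_FileTimeStep"
            frag.individuals[root_id] = Individual(
                root_id, [Curie("CBO", "VTK_FileRoot")],
                [(RelationKind.HAS_STRING_VALUE, link.file_root)],
            )
            frag.individuals[init_id] = Individual(
                init_id, [Curie("CBO", "VTK_InitialCondition")],
                [(RelationKind.HAS_STRING_VALUE, link.initial_file)],
            )
            frag.individuals[step_id] = _quality_individual(
                step_id, replace(link.time_step,
                                 quality_class=Curie("CBO", "VTK_FileTimeStep")))
            for qid in (init_id, step_id, root_id):
                sind.facts.append((RelationKind.HAS_QUALITY, qid))
            if link.directory != ".":
                sind.annotations.append(("directory", link.directory))
        frag.individuals[sysspec.name] = sind
    return frag


def export_metamodel(model: MetaModel, path) -> str:
    """Validate and write the meta-model; returns the serialized text."""
    violations = validate_metamodel(model)
    if violations:
        raise ValidationError(violations)
    text = serialize_manchester(to_fragment(model))
    Path(path).write_text(text, encoding="utf-8")
    return text


def from_fragment(frag: Fragment) -> MetaModel:
    """Reconstruct a meta-model from a parsed dialect fragment."""
    core = load_core_hierarchy()
    model = MetaModel()
    consumed: set[str] = set()

    def ann(decl, key) -> list[str]:
        return [v for k, v in decl.annotations if k == key]

    # classify T-Box extensions into prototypes and processes
    for name, decl in frag.classes.items():
        phys = [p for p in decl.parents if p in _PHYSICAL_BY_CLASS]
        if phys:
            bio = next((p for p in decl.parents if p not in _PHYSICAL_BY_CLASS), None)
            type_id = None
            for kind, val in decl.equivalents:
                if kind is RelationKind.HAS_VTK_TYPE_ID:
                    type_id = int(val)
            quals = []
            for k, target in decl.facts:
                if k is RelationKind.HAS_QUALITY and str(target) in frag.individuals:
                    quals.append(_read_quality_individual(frag.individuals[str(target)]))
                    consumed.add(str(target))
            fnames = ann(decl, "field_name")
            model.prototypes[name] = PrototypeClass(
                name=name,
                bio_parent=bio if bio is not None else Curie("CBO", "Cell"),
                physical_type=_PHYSICAL_BY_CLASS[phys[0]],
                vtk_type_id=type_id,
                field_name=fnames[0] if fnames else None,
                xrefs=frozenset(Curie.parse(x) for x in ann(decl, "xref")),
                default_qualities=tuple(quals),
            )
            continue
        parent = decl.parents[0] if decl.parents else None
        if parent is not None and parent in core and core.is_subclass_of(
            parent, Curie("CBO", "CBO_Process")
        ):
            params: dict[str, Quality] = {}
            for k, target in decl.facts:
                tid = str(target)
                if k is RelationKind.HAS_QUALITY and tid in frag.individuals:
                    pname = tid.split("_p_", 1)[1] if "_p_" in tid else tid
                    params[pname] = _read_quality_individual(frag.individuals[tid])
                    consumed.add(tid)
            conds = ann(decl, "condition")
            model.processes[name] = ProcessSpec(
                name=name,
                process_class=parent,
                participants=tuple(ann(decl, "participant")),
                parameters=params,
                condition=conds[0] if conds else "always",
            )
            continue
        model.extra.classes[name] = decl

    # the system individual and its quality individuals
    sys_ind = None
    for ind in frag.individuals.values():
        if any(t.local_id == "System" for t in ind.types):
            sys_ind = ind
            break
    if sys_ind is not None:
        consumed.add(sys_ind.id)
        extent = (1, 1, 1)
        scale = None
        link_root = link_init = link_step = None
        for k, target in sys_ind.facts:
            if k is not RelationKind.HAS_QUALITY:
                continue
            q = frag.individuals.get(str(target))
            if q is None:
                continue
            consumed.add(q.id)
            tlocal = {t.local_id for t in q.types}
            if "DiscreteExtent" in tlocal:
                sval = q.facts_of(RelationKind.HAS_STRING_VALUE)
                if sval:
                    extent = tuple(int(x) for x in str(sval[0]).split())
            elif "SystemPixelDistanceScale" in tlocal:
                scale = _read_quality_individual(q)
                scale = replace(scale, quality_class=Curie("CBO", "SystemPixelDistanceScale"))
            elif "VTK_FileRoot" in tlocal:
                link_root = str(q.facts_of(RelationKind.HAS_STRING_VALUE)[0])
            elif "VTK_InitialCondition" in tlocal:
                link_init = str(q.facts_of(RelationKind.HAS_STRING_VALUE)[0])
            elif "VTK_FileTimeStep" in tlocal or "TemporalInterval" in tlocal:
                link_step = _read_quality_individual(q)

        def one(key, default):
            vals = [v for k, v in sys_ind.annotations if k == key]
            return vals[0] if vals else default

        boundary = tuple(one("boundary", "wall wall wall").split())
        dim = int(one("dimensionality", "3"))
        model.system = SystemSpec(
            name=sys_ind.id,
            extent=extent,
            distance_scale=scale if scale is not None else Quality(
                Curie("CBO", "SystemPixelDistanceScale"), 1.0, "actual",
                units.unit_curie("micrometer")),
            boundary=boundary,
            platform=one("platform", ""),
            biology_xrefs=frozenset(
                Curie.parse(v) for k, v in sys_ind.annotations if k == "xref"
            ),
            declared_dimensionality=dim,
        )
        if link_root is not None and link_init is not None and link_step is not None:
            model.series = SeriesLink(
                link_root, link_init,
                replace(link_step, quality_class=Curie("CBO", "VTK_FileTimeStep")),
                one("directory", "."),
            )

    for iid, ind in frag.individuals.items():
        if iid not in consumed:
            model.extra.individuals[iid] = ind
    return model


def import_metamodel(path) -> MetaModel:
    return from_fragment(parse_manchester(Path(path).read_text(encoding="utf-8")))


# --------------------------------------------------------------------------
# bundled use-case listing
# --------------------------------------------------------------------------

def load_use_case_text() -> str:
    """The bundled series-link listing for the tumor-growth use case."""
    return (
        importlib.resources.files("cbokit")
        .joinpath("data/use_case_1.omn")
        .read_text(encoding="utf-8")
    )


def load_use_case_fragment() -> Fragment:
    return parse_manchester(load_use_case_text())


def series_link_from_fragment(frag: Fragment) -> SeriesLink:
    """Build a :class:`SeriesLink` from the VTK individuals of a fragment
    (file root, initial condition, time step), as in the published listing."""
    root = init = step = None
    for ind in frag.individuals.values():
        tlocal = {t.local_id for t in ind.types}
        if "VTK_FileRoot" in tlocal:
            root = str(ind.facts_of(RelationKind.HAS_STRING_VALUE)[0])
        elif "VTK_InitialCondition" in tlocal:
            init = str(ind.facts_of(RelationKind.HAS_STRING_VALUE)[0])
        elif "VTK_FileTimeStep" in tlocal:
            step = _read_quality_individual(ind)
            step = replace(step, quality_class=Curie("CBO", "VTK_FileTimeStep"))
    if root is None or init is None or step is None:
        raise ConventionError("fragment lacks VTK series-link individuals")
    return SeriesLink(root, init, step)
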