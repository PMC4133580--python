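"""Core representation of the Cell Behavior Ontology (CBO).

The CBO describes cells and tissue components as spatial, semiautonomous
agents.  Its continuant/occurrent split (objects persisting through time
versus processes unfolding in time) appears here as the two roots
``CBO_Object`` and ``CBO_Process`` beneath the universal class.  This
module provides:

* :class:`Curie` — compact identifiers (``CBO:Cell``, ``GO:0008219``) with
  opaque prefixes (no IRI expansion);
* :class:`RelationKind` — the closed relation set: an OBO-RO-style object
  relation subset plus ``has_Quality`` and the literal-valued data
  relations (``hasIntValue``/``hasFloatValue``/``hasStringValue``, their
  ``...Target`` set-point twins, ``hasUnit``, ``hasVTKTypeID``);
* :class:`Quality` — a typed value with actual/target kind and unit;
* :class:`ClassHierarchy` — class nodes + individuals, with subclass
  closure and quality resolution;
* a reader/writer for the constrained Manchester-syntax dialect used to
  exchange meta-model fragments (``Class:``/``Individual:`` blocks with
  ``SubClassOf:``/``EquivalentTo:``/``Types:``/``Facts:``/``Annotations:``
  clauses).

The bundled hierarchy returned by :func:`load_core_hierarchy` is a working
subset of the released CBO: every class needed to express lattice and
center-model meta-models (prototypes, processes, system qualities, VTK
series linkage) is present; the full released class list is not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Union

from .errors import (
    AmbiguousQualityError,
    DialectError,
    ManchesterParseError,
    QualityAbsentError,
    SerializationError,
    UnresolvedClassError,
)

__all__ = [
    "Curie",
    "RelationKind",
    "Quality",
    "ClassNode",
    "Individual",
    "ClassDecl",
    "Fragment",
    "ClassHierarchy",
    "load_core_hierarchy",
    "parse_manchester",
    "serialize_manchester",
]


# --------------------------------------------------------------------------
# identifiers and relations
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Curie:
    """A compact URI: ``prefix:local_id``.  Prefixes are opaque tokens."""

    prefix: str
    local_id: str

    def __post_init__(self):
        if not self.prefix:
            raise ValueError("Curie prefix must be non-empty")

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    @classmethod
    def parse(cls, token: str, default_prefix: str = "CBO") -> "Curie":
        """Parse ``PREFIX:local`` or a bare name (given the default prefix)."""
        token = token.strip()
        if ":" in token:
            prefix, local = token.split(":", 1)
            return cls(prefix, local)
        return cls(default_prefix, token)


class RelationKind(Enum):
    IS_A = "isA"
    INSTANCE_OF = "instanceOf"
    HAS_QUALITY = "has_Quality"
    HAS_PROCESS = "hasProcess"
    PARTICIPATES_IN = "participates_in"
    PROCESS_OF = "process_of"
    HAS_VTK_TYPE_ID = "hasVTKTypeID"
    EQUIVALENT_TO = "equivalentTo"
    HAS_INT_VALUE = "hasIntValue"
    HAS_FLOAT_VALUE = "hasFloatValue"
    HAS_STRING_VALUE = "hasStringValue"
    HAS_INT_VALUE_TARGET = "hasIntValueTarget"
    HAS_FLOAT_VALUE_TARGET = "hasFloatValueTarget"
    HAS_UNIT = "hasUnit"

    @property
    def is_literal(self) -> bool:
        return self in _LITERAL_KINDS


#: relations whose object is a literal (or, for hasUnit, a unit CURIE)
_LITERAL_KINDS = {
    RelationKind.HAS_INT_VALUE,
    RelationKind.HAS_FLOAT_VALUE,
    RelationKind.HAS_STRING_VALUE,
    RelationKind.HAS_INT_VALUE_TARGET,
    RelationKind.HAS_FLOAT_VALUE_TARGET,
    RelationKind.HAS_UNIT,
    RelationKind.HAS_VTK_TYPE_ID,
}

_ACTUAL_KINDS = {
    RelationKind.HAS_INT_VALUE,
    RelationKind.HAS_FLOAT_VALUE,
    RelationKind.HAS_STRING_VALUE,
}
_TARGET_KINDS = {
    RelationKind.HAS_INT_VALUE_TARGET,
    RelationKind.HAS_FLOAT_VALUE_TARGET,
}

_RELATION_BY_NAME = {k.value: k for k in RelationKind}


# --------------------------------------------------------------------------
# qualities, individuals, classes
# --------------------------------------------------------------------------

LiteralValue = Union[int, float, str]


@dataclass(frozen=True)
class Quality:
    """A quality value, e.g. a volume of 87.5 µm³ or a target volume.

    ``value_kind`` distinguishes the current value of a quality from its
    set-point (many modeling paradigms give a cell both an actual and a
    target volume).
    """

    quality_class: Curie
    value: LiteralValue
    value_kind: str = "actual"  # "actual" | "target"
    unit: Curie | None = None

    def __post_init__(self):
        if self.value_kind not in ("actual", "target"):
            raise ValueError(f"bad value_kind {self.value_kind!r}")
        if self.value_kind == "target" and isinstance(self.value, str):
            raise ValueError("target qualities must be numeric")


@dataclass
class ClassNode:
    id: Curie
    label: str = ""
    parents: set[Curie] = field(default_factory=set)
    xrefs: set[Curie] = field(default_factory=set)


FactTarget = Union[str, Curie, LiteralValue]
Fact = tuple[RelationKind, FactTarget]


@dataclass
class Individual:
    """An A-Box individual: named instance with types and facts.

    Facts keep insertion order; literal-kind facts carry literals (or a
    unit CURIE for ``hasUnit``), object-kind facts carry individual ids or
    CURIEs.
    """

    id: str
    types: list[Curie] = field(default_factory=list)
    facts: list[Fact] = field(default_factory=list)
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def facts_of(self, kind: RelationKind) -> list[FactTarget]:
        return [t for k, t in self.facts if k is kind]


@dataclass
class ClassDecl:
    """A T-Box extension block: a new class with parents and optional
    equivalent-class data facts (notably ``hasVTKTypeID value n``)."""

    name: str
    parents: list[Curie] = field(default_factory=list)
    equivalents: list[Fact] = field(default_factory=list)
    facts: list[Fact] = field(default_factory=list)
    annotations: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Fragment:
    """A parsed piece of a meta-model: class extensions + individuals."""

    classes: dict[str, ClassDecl] = field(default_factory=dict)
    individuals: dict[str, Individual] = field(default_factory=dict)

    def merge(self, other: "Fragment") -> "Fragment":
        out = Fragment(dict(self.classes), dict(self.individuals))
        out.classes.update(other.classes)
        out.individuals.update(other.individuals)
        return out


# --------------------------------------------------------------------------
# hierarchy
# --------------------------------------------------------------------------

ROOT = Curie("owl", "Thing")


class ClassHierarchy:
    """Class nodes keyed by CURIE plus named individuals.

    The parent graph must stay acyclic; :meth:`validate` checks this by
    topological sort and that no parent reference dangles.
    """

    def __init__(self):
        self.nodes: dict[Curie, ClassNode] = {}
        self.individuals: dict[str, Individual] = {}
        self._by_local: dict[str, Curie] = {}

    # -- construction ------------------------------------------------------

    def add_class(
        self,
        id: Curie | str,
        parents: Iterable[Curie | str] = (),
        label: str = "",
        xrefs: Iterable[Curie] = (),
    ) -> ClassNode:
        cid = id if isinstance(id, Curie) else Curie.parse(id)
        node = self.nodes.get(cid)
        if node is None:
            node = ClassNode(cid, label or cid.local_id)
            self.nodes[cid] = node
            self._by_local.setdefault(cid.local_id, cid)
        node.parents.update(
            p if isinstance(p, Curie) else Curie.parse(p) for p in parents
        )
        node.xrefs.update(xrefs)
        return node

    def add_individual(self, ind: Individual) -> Individual:
        self.individuals[ind.id] = ind
        return ind

    def merge_fragment(self, frag: Fragment) -> None:
        for decl in frag.classes.values():
            node = self.add_class(Curie.parse(decl.name), decl.parents)
            for key, val in decl.annotations:
                if key == "xref":
                    node.xrefs.add(Curie.parse(val))
        for ind in frag.individuals.values():
            self.add_individual(ind)
        self.validate()

    # -- lookup ------------------------------------------------------------

    def resolve(self, name: Curie | str) -> Curie:
        """Resolve a CURIE or bare class name to a known class CURIE."""
        if isinstance(name, Curie):
            if name in self.nodes:
                return name
            raise UnresolvedClassError(str(name))
        if ":" in name:
            return self.resolve(Curie.parse(name))
        try:
            return self._by_local[name]
        except KeyError:
            raise UnresolvedClassError(name) from None

    def __contains__(self, name) -> bool:
        try:
            self.resolve(name)
        except UnresolvedClassError:
            return False
        return True

    # -- closure -----------------------------------------------------------

    def is_subclass_of(self, child: Curie | str, ancestor: Curie | str) -> bool:
        """True iff *ancestor* is reachable from *child* via parent links
        (reflexive)."""
        c = self.resolve(child)
        a = self.resolve(ancestor)
        seen: set[Curie] = set()
        stack = [c]
        while stack:
            cur = stack.pop()
            if cur == a:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            node = self.nodes.get(cur)
            if node is not None:
                stack.extend(node.parents)
        return False

    def ancestors(self, name: Curie | str) -> set[Curie]:
        c = self.resolve(name)
        out: set[Curie] = set()
        stack = list(self.nodes[c].parents)
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            node = self.nodes.get(cur)
            if node is not None:
                stack.extend(node.parents)
        return out

    def validate(self) -> None:
        """Raise if the parent graph dangles or cycles."""
        ts = TopologicalSorter()
        for cid, node in self.nodes.items():
            for p in node.parents:
                if p not in self.nodes:
                    raise UnresolvedClassError(f"dangling parent {p} of {cid}")
            ts.add(cid, *node.parents)
        try:
            ts.prepare()
        except CycleError as e:
            raise ManchesterParseError(f"class hierarchy cycle: {e.args[1]}")

    # -- qualities ---------------------------------------------------------

    def resolve_quality(self, individual_id: str, quality_class: Curie | str) -> Quality:
        """Follow an individual's ``has_Quality`` facts to the quality
        individual typed by *quality_class* and return its value.

        The value kind is discriminated by which data relation the quality
        individual carries (``has*Value`` = actual, ``has*ValueTarget`` =
        target).  Exactly one actual value is allowed per quality class.
        """
        from . import units

        try:
            ind = self.individuals[individual_id]
        except KeyError:
            raise QualityAbsentError(f"no individual {individual_id!r}") from None
        qc = self.resolve(quality_class) if quality_class in self else (
            quality_class if isinstance(quality_class, Curie) else Curie.parse(quality_class)
        )

        matches: list[Quality] = []
        for target in ind.facts_of(RelationKind.HAS_QUALITY):
            q = self.individuals.get(target) if isinstance(target, str) else None
            if q is None:
                continue
            if not any(self._type_matches(t, qc) for t in q.types):
                continue
            unit = None
            for u in q.facts_of(RelationKind.HAS_UNIT):
                unit = units.unit_curie(u)
            for kind, val in q.facts:
                if kind in _ACTUAL_KINDS:
                    matches.append(Quality(qc, val, "actual", unit))
                elif kind in _TARGET_KINDS:
                    matches.append(Quality(qc, val, "target", unit))
        actuals = [m for m in matches if m.value_kind == "actual"]
        if len(actuals) > 1:
            raise AmbiguousQualityError(
                f"{individual_id!r} has {len(actuals)} actual values for {qc}"
            )
        if actuals:
            return actuals[0]
        if matches:
            return matches[0]
        raise QualityAbsentError(f"{individual_id!r} has no {qc} quality")

    def _type_matches(self, t: Curie, qc: Curie) -> bool:
        if t == qc:
            return True
        if t in self and qc in self:
            return self.is_subclass_of(t, qc)
        return t.local_id == qc.local_id

    # -- misc --------------------------------------------------------------

    def copy(self) -> "ClassHierarchy":
        out = ClassHierarchy()
        for cid, node in self.nodes.items():
            out.add_class(cid, node.parents, node.label, node.xrefs)
        for ind in self.individuals.values():
            out.add_individual(
                Individual(ind.id, list(ind.types), list(ind.facts), list(ind.annotations))
            )
        return out

    def structurally_equal(self, other: "ClassHierarchy") -> bool:
        if set(self.nodes) != set(other.nodes):
            return False
        for cid, node in self.nodes.items():
            o = other.nodes[cid]
            if node.parents != o.parents or node.xrefs != o.xrefs:
                return False
        if set(self.individuals) != set(other.individuals):
            return False
        for iid, ind in self.individuals.items():
            o = other.individuals[iid]
            if ind.types != o.types or sorted(map(repr, ind.facts)) != sorted(map(repr, o.facts)):
                return False
        return True


# --------------------------------------------------------------------------
# bundled CBO subset
# --------------------------------------------------------------------------

_CORE_EDGES: list[tuple[str, str]] = [
    # (class, parent); universal root first
    ("CBO:CBO_Object", "owl:Thing"),
    ("CBO:CBO_Process", "owl:Thing"),
    # how objects occupy space
    ("CBO:PhysicalEntityType", "CBO:CBO_Object"),
    ("CBO:CorpuscularEntity", "CBO:PhysicalEntityType"),
    ("CBO:ContinuousEntity", "CBO:PhysicalEntityType"),
    ("CBO:DiffuseEntity", "CBO:PhysicalEntityType"),
    # what objects are, biologically
    ("CBO:BioEntityType", "CBO:CBO_Object"),
    ("CBO:Cell", "CBO:BioEntityType"),
    ("CBO:Field", "CBO:BioEntityType"),
    ("CBO:ExtracellularMatrix", "CBO:BioEntityType"),
    ("CBO:Medium", "CBO:BioEntityType"),
    # the model universe and its bookkeeping qualities
    ("CBO:System", "CBO:CBO_Object"),
    ("CBO:SystemQuality", "CBO:CBO_Object"),
    ("CBO:ComputationalPlatform", "CBO:SystemQuality"),
    ("CBO:SystemPixelDistanceScale", "CBO:SystemQuality"),
    ("CBO:DiscreteExtent", "CBO:SystemQuality"),
    ("CBO:ContinuousExtent", "CBO:SystemQuality"),
    ("CBO:BoundaryCondition", "CBO:SystemQuality"),
    ("CBO:SystemDimensionality", "CBO:SystemQuality"),
    ("CBO:TemporalInterval", "CBO:SystemQuality"),
    ("CBO:VTK_FileRoot", "CBO:SystemQuality"),
    ("CBO:VTK_InitialCondition", "CBO:SystemQuality"),
    ("CBO:VTK_FileTimeStep", "CBO:TemporalInterval"),
    # per-object qualities
    ("CBO:PhysicalObjectQuality", "CBO:CBO_Object"),
    ("CBO:Volume", "CBO:PhysicalObjectQuality"),
    ("CBO:Surface", "CBO:PhysicalObjectQuality"),
    ("CBO:Location", "CBO:PhysicalObjectQuality"),
    ("CBO:Fill", "CBO:PhysicalObjectQuality"),
    ("CBO:ProcessQuality", "CBO:CBO_Object"),
    # cell processes
    ("CBO:CellProcess", "CBO:CBO_Process"),
    ("CBO:CellGrowth", "CBO:CellProcess"),
    ("CBO:CellDivision", "CBO:CellProcess"),
    ("CBO:CellDeath", "CBO:CellProcess"),
    ("CBO:Necrosis", "CBO:CellDeath"),
    ("CBO:Apoptosis", "CBO:CellDeath"),
    ("CBO:CellCellAdhesion", "CBO:CellProcess"),
    ("CBO:PhenotypicChange", "CBO:CellProcess"),
    ("CBO:Chemotaxis", "CBO:CellProcess"),
    ("CBO:Secretion", "CBO:CellProcess"),
    ("CBO:Consumption", "CBO:CellProcess"),
    # field / molecule / matrix processes
    ("CBO:FieldProcess", "CBO:CBO_Process"),
    ("CBO:Diffusion", "CBO:FieldProcess"),
    ("CBO:Decay", "CBO:FieldProcess"),
    ("CBO:Advection", "CBO:FieldProcess"),
    ("CBO:MoleculeProcess", "CBO:CBO_Process"),
    ("CBO:ExtracellularMatrixProcess", "CBO:CBO_Process"),
    # existential physical processes
    ("CBO:FundamentalPhysicalProcess", "CBO:CBO_Process"),
    ("CBO:BarrierCrossing", "CBO:FundamentalPhysicalProcess"),
    ("CBO:ObjectCreation", "CBO:FundamentalPhysicalProcess"),
    ("CBO:ObjectDestruction", "CBO:FundamentalPhysicalProcess"),
    ("CBO:ObjectMovement", "CBO:FundamentalPhysicalProcess"),
]


def load_core_hierarchy() -> ClassHierarchy:
    """Return the bundled CBO subset (fresh, structurally equal each call)."""
    h = ClassHierarchy()
    h.add_class(ROOT, label="Thing")
    for cls, parent in _CORE_EDGES:
        h.add_class(Curie.parse(cls), [Curie.parse(parent)])
    h.validate()
    return h


def is_subclass_of(h: ClassHierarchy, child: Curie | str, ancestor: Curie | str) -> bool:
    """Functional alias for :meth:`ClassHierarchy.is_subclass_of`."""
    return h.is_subclass_of(child, ancestor)


def resolve_quality(h: ClassHierarchy, individual_id: str, quality_class: Curie | str) -> Quality:
    """Functional alias for :meth:`ClassHierarchy.resolve_quality`."""
    return h.resolve_quality(individual_id, quality_class)


# --------------------------------------------------------------------------
# constrained Manchester dialect
# --------------------------------------------------------------------------

_BLOCK_RE = re.compile(r"\b(Class|Individual):")
_CLAUSE_RE = re.compile(r"\b(Types|Facts|SubClassOf|EquivalentTo|Annotations):")
# straight or typographic double quotes (the printed listing mixes them)
_QUOTE_CHARS = "\"“”"
_QUOTED_RE = re.compile(f"[{_QUOTE_CHARS}]([^{_QUOTE_CHARS}]*)[{_QUOTE_CHARS}]")

_VALID_CLAUSES = {
    "Class": ("SubClassOf", "EquivalentTo", "Facts", "Annotations"),
    "Individual": ("Types", "Facts", "Annotations"),
}


def _line_of(text: str, pos: int) -> int:
    return text.count("\n", 0, pos) + 1


def _split_commas(body: str) -> list[str]:
    """Split a clause body on commas outside quotes; drop empty items."""
    items, buf, in_quote = [], [], False
    for ch in body:
        if ch in _QUOTE_CHARS:
            in_quote = not in_quote
            buf.append(ch)
        elif ch == "," and not in_quote:
            items.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    items.append("".join(buf))
    return [i.strip() for i in items if i.strip()]


def _relation(token: str, line: int) -> RelationKind:
    name = token.split(":", 1)[1] if token.startswith("CBO:") else token
    kind = _RELATION_BY_NAME.get(name)
    if kind is None:
        raise ManchesterParseError(f"unknown relation {token!r}", line)
    return kind


def _coerce_literal(kind: RelationKind, raw: str, quoted: bool, line: int) -> FactTarget:
    from . import units

    if kind in (RelationKind.HAS_INT_VALUE, RelationKind.HAS_INT_VALUE_TARGET,
                RelationKind.HAS_VTK_TYPE_ID):
        try:
            return int(raw)
        except ValueError:
            raise DialectError(f"{kind.value} needs an integer, got {raw!r}", line)
    if kind in (RelationKind.HAS_FLOAT_VALUE, RelationKind.HAS_FLOAT_VALUE_TARGET):
        try:
            return float(raw)
        except ValueError:
            raise DialectError(f"{kind.value} needs a float, got {raw!r}", line)
    if kind is RelationKind.HAS_UNIT:
        if units.is_known(raw):
            return units.unit_curie(raw)
        return Curie.parse(raw, default_prefix="UO")
    return raw  # hasStringValue


def _parse_fact(item: str, line: int) -> Fact:
    parts = item.split(None, 1)
    if len(parts) != 2:
        raise ManchesterParseError(f"fact needs relation and target: {item!r}", line)
    rel_tok, target_tok = parts
    kind = _relation(rel_tok, line)
    m = _QUOTED_RE.fullmatch(target_tok.strip())
    quoted = m is not None
    raw = m.group(1) if quoted else target_tok.strip()
    if kind.is_literal:
        return kind, _coerce_literal(kind, raw, quoted, line)
    if quoted:
        raise DialectError(
            f"literal {raw!r} in object-relation position ({kind.value})", line
        )
    # object relation: an individual id or a CURIE target
    return kind, raw


def _parse_equivalent(item: str, line: int) -> Fact:
    # `CBO:hasVTKTypeID value 1` (data restriction) or a plain class CURIE
    parts = item.split()
    if len(parts) == 3 and parts[1] == "value":
        kind = _relation(parts[0], line)
        if not kind.is_literal:
            raise DialectError(f"{kind.value} is not a data relation", line)
        m = _QUOTED_RE.fullmatch(parts[2])
        raw = m.group(1) if m else parts[2]
        return kind, _coerce_literal(kind, raw, m is not None, line)
    if len(parts) == 1:
        return RelationKind.EQUIVALENT_TO, Curie.parse(parts[0])
    raise ManchesterParseError(f"bad EquivalentTo item {item!r}", line)


def _parse_annotation(item: str, line: int) -> tuple[str, str]:
    parts = item.split(None, 1)
    if len(parts) != 2:
        raise ManchesterParseError(f"annotation needs key and value: {item!r}", line)
    key, val = parts
    m = _QUOTED_RE.fullmatch(val.strip())
    return key, (m.group(1) if m else val.strip())


def parse_manchester(text: str) -> Fragment:
    """Parse the constrained Manchester dialect into a :class:`Fragment`.

    The parser is whitespace- and line-folding-insensitive: block and
    clause keywords may appear anywhere, as in the printed listings whose
    line breaks fall mid-clause.  Unknown CURIE prefixes are preserved
    opaquely.  Straight and typographic double quotes are both accepted.
    """
    frag = Fragment()
    blocks = list(_BLOCK_RE.finditer(text))
    # anything before the first block must be blank or comments
    head = text[: blocks[0].start()] if blocks else text
    for ln in head.splitlines():
        if ln.strip() and not ln.strip().startswith("#"):
            raise ManchesterParseError(
                f"content outside any block: {ln.strip()!r}", _line_of(text, text.find(ln))
            )
    for i, m in enumerate(blocks):
        start = m.end()
        end = blocks[i + 1].start() if i + 1 < len(blocks) else len(text)
        body = text[start:end]
        block_kind = m.group(1)
        line = _line_of(text, m.start())

        clauses = list(_CLAUSE_RE.finditer(body))
        name = body[: clauses[0].start()] if clauses else body
        name = name.strip()
        if not name or len(name.split()) != 1:
            raise ManchesterParseError(
                f"{block_kind} block needs a single name, got {name!r}", line
            )

        decl = ClassDecl(name) if block_kind == "Class" else Individual(name)
        for j, cm in enumerate(clauses):
            cstart = cm.end()
            cend = clauses[j + 1].start() if j + 1 < len(clauses) else len(body)
            cname = cm.group(1)
            cline = _line_of(text, start + cm.start())
            if cname not in _VALID_CLAUSES[block_kind]:
                raise ManchesterParseError(
                    f"{cname}: clause not allowed in {block_kind} block", cline
                )
            items = _split_commas(body[cstart:cend])
            if cname == "SubClassOf":
                decl.parents.extend(Curie.parse(i) for i in items)
            elif cname == "Types":
                decl.types.extend(Curie.parse(i) for i in items)
            elif cname == "EquivalentTo":
                decl.equivalents.extend(_parse_equivalent(i, cline) for i in items)
            elif cname == "Facts":
                decl.facts.extend(_parse_fact(i, cline) for i in items)
            elif cname == "Annotations":
                decl.annotations.extend(_parse_annotation(i, cline) for i in items)
        if block_kind == "Class":
            frag.classes[name] = decl
        else:
            frag.individuals[name] = decl
    return frag


def _fmt_literal(kind: RelationKind, value: FactTarget) -> str:
    if kind is RelationKind.HAS_UNIT:
        if isinstance(value, Curie):
            return f'"{value.local_id}"'
        return f'"{value}"'
    if isinstance(value, bool):
        raise SerializationError(f"cannot serialize boolean literal {value!r}")
    if isinstance(value, int):
        return f'"{value}"'
    if isinstance(value, float):
        s = repr(value)
        if s.endswith(".0"):
            s = s[:-2]
        return f'"{s}"'
    if isinstance(value, str):
        return f'"{value}"'
    raise SerializationError(f"unserializable literal {value!r} for {kind.value}")


def _fmt_fact(kind: RelationKind, target: FactTarget) -> str:
    prefix = "CBO:" if kind is not RelationKind.HAS_QUALITY else ""
    name = kind.value
    if kind is RelationKind.HAS_QUALITY:
        return f"has_Quality {target}"
    if kind.is_literal:
        return f"{prefix}{name} {_fmt_literal(kind, target)}"
    return f"{name} {target}"


def serialize_manchester(frag: Fragment) -> str:
    """Render a fragment in the dialect: classes then individuals, each
    alphabetical by name; facts in insertion order.  Deterministic."""
    _check_closed(frag)
    out: list[str] = []
    for name in sorted(frag.classes):
        decl = frag.classes[name]
        out.append(f"Class: {name}")
        if decl.parents:
            out.append("    SubClassOf: " + ", ".join(str(p) for p in decl.parents))
        if decl.equivalents:
            items = []
            for kind, val in decl.equivalents:
                if kind is RelationKind.EQUIVALENT_TO:
                    items.append(str(val))
                else:
                    items.append(f"CBO:{kind.value} value {_fmt_literal(kind, val)}")
            out.append("    EquivalentTo: " + ", ".join(items))
        if decl.annotations:
            out.append(
                "    Annotations: "
                + ", ".join(f'{k} "{v}"' for k, v in decl.annotations)
            )
        if decl.facts:
            out.append("    Facts: " + ", ".join(_fmt_fact(k, t) for k, t in decl.facts))
        out.append("")
    for name in sorted(frag.individuals):
        ind = frag.individuals[name]
        out.append(f"Individual: {name}")
        if ind.types:
            out.append("    Types: " + ", ".join(str(t) for t in ind.types))
        if ind.annotations:
            out.append(
                "    Annotations: "
                + ", ".join(f'{k} "{v}"' for k, v in ind.annotations)
            )
        if ind.facts:
            out.append("    Facts: " + ", ".join(_fmt_fact(k, t) for k, t in ind.facts))
        out.append("")
    return "\n".join(out)


def _check_closed(frag: Fragment) -> None:
    for ind in frag.individuals.values():
        for kind, target in ind.facts:
            if kind is RelationKind.HAS_QUALITY and isinstance(target, str):
                if target not in frag.individuals:
                    raise SerializationError(
                        f"dangling has_Quality target {target!r} in {ind.id!r}"
                    )
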