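"""Core hierarchy, subclass closure, Manchester dialect, quality resolution."""

import random

import networkx as nx
import pytest

from cbokit import metamodel as mm
from cbokit import units
from cbokit.errors import (
    AmbiguousQualityError,
    DialectError,
    ManchesterParseError,
    QualityAbsentError,
    UnresolvedClassError,
)
from cbokit.ontology import (
    ROOT,
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

# the published series-link listing, with the hard line folding of the
# printed page (keywords mid-line, values split from their relations)
FOLDED_LISTING = """
Individual: TumorGrowthWithAngiogenesis  Types: System  Facts:   has_Quality
use_case_1_extent,   has_Quality
systemPix2DistSc,   has_Quality
    TumorGrowthWithAngiogenesis_VTK_InitialFile,   has_Quality
    TumorGrowthWithAgniogenesis_VTK_FileTimeStep,   has_Quality tumorGrowthWithAngiogenesis_VTK_FileRoot Individual: tumorGrowthWithAngiogenesis_VTK_FileRoot  Types: CBO:VTK_FileRoot  Facts: hasStringValue
“use_case_1" Individual: TumorGrowthWithAngiogenesis_VTK_InitialFile  Types: CBO:VTK_InitialCondition  Facts: hasStringValue
“use_case_1_0000000000.vtk" Individual:
  TumorGrowthWithAgniogenesis_VTK_FileTimeStep   Types: CBO:VTK_FileTimeStep   Facts: CBO:hasFloatValue
“1",           CBO:hasUnit
“minute"
"""


class TestCoreHierarchy:
    def test_object_and_process_are_the_two_roots(self, core_hierarchy):
        children = [
            cid for cid, node in core_hierarchy.nodes.items() if ROOT in node.parents
        ]
        assert sorted(c.local_id for c in children) == ["CBO_Object", "CBO_Process"]

    @pytest.mark.parametrize(
        "child, ancestor",
        [
            ("CorpuscularEntity", "PhysicalEntityType"),
            ("Necrosis", "CBO_Process"),
            ("Necrosis", "CellDeath"),
            ("VTK_FileTimeStep", "TemporalInterval"),
            ("ComputationalPlatform", "SystemQuality"),
            ("Cell", "CBO_Object"),
        ],
    )
    def test_subclass_paths(self, core_hierarchy, child, ancestor):
        assert core_hierarchy.is_subclass_of(child, ancestor)

    def test_reflexive_and_not_symmetric(self, core_hierarchy):
        assert core_hierarchy.is_subclass_of("Cell", "Cell")
        assert not core_hierarchy.is_subclass_of("CBO_Object", "Cell")

    def test_idempotent(self):
        assert load_core_hierarchy().structurally_equal(load_core_hierarchy())

    def test_unknown_class_raises(self, core_hierarchy):
        with pytest.raises(UnresolvedClassError):
            core_hierarchy.is_subclass_of("NoSuchClass", "CBO_Object")

    def test_bundled_scenario_classes_resolve(self, core_hierarchy):
        from cbokit import simulate as sim

        for name in ("tumor_angiogenesis_mini", "two_cell_toy"):
            model = sim.make_scenario(name).model
            for p in model.prototypes.values():
                assert p.bio_parent in core_hierarchy
            for s in model.processes.values():
                assert s.process_class in core_hierarchy


class TestSubclassClosureOracle:
    def test_matches_graph_reachability_on_random_dags(self):
        """Transitive subclass closure equals independent reachability on
        random DAGs (parents always point to earlier nodes, so acyclic)."""
        rng = random.Random(42)
        for _ in range(20):
            n = rng.randint(2, 50)
            h = ClassHierarchy()
            g = nx.DiGraph()
            names = [Curie("T", f"n{i}") for i in range(n)]
            h.add_class(names[0])
            g.add_node(names[0])
            for i in range(1, n):
                parents = rng.sample(names[:i], k=min(i, rng.randint(1, 3)))
                h.add_class(names[i], parents)
                g.add_node(names[i])
                for p in parents:
                    g.add_edge(names[i], p)
            h.validate()
            for _ in range(20):
                a, b = rng.choice(names), rng.choice(names)
                assert h.is_subclass_of(a, b) == nx.has_path(g, a, b)


class TestManchesterParse:
    def test_published_listing_with_printed_line_folding(self):
        frag = parse_manchester(FOLDED_LISTING)
        sysind = frag.individuals["TumorGrowthWithAngiogenesis"]
        assert [t.local_id for t in sysind.types] == ["System"]
        assert len(sysind.facts_of(RelationKind.HAS_QUALITY)) == 5
        step = frag.individuals["TumorGrowthWithAgniogenesis_VTK_FileTimeStep"]
        assert step.facts_of(RelationKind.HAS_FLOAT_VALUE) == [1.0]
        assert step.facts_of(RelationKind.HAS_UNIT) == [units.unit_curie("minute")]
        root = frag.individuals["tumorGrowthWithAngiogenesis_VTK_FileRoot"]
        assert root.facts_of(RelationKind.HAS_STRING_VALUE) == ["use_case_1"]

    def test_empty_string_gives_empty_fragment(self):
        frag = parse_manchester("")
        assert not frag.classes and not frag.individuals

    def test_malformed_block_reports_line_number(self):
        text = "Individual: a b\n    Types: CBO:System\n"
        with pytest.raises(ManchesterParseError) as err:
            parse_manchester(text)
        assert err.value.line == 1

    def test_literal_in_object_position_is_dialect_error(self):
        text = 'Individual: x\n    Facts: has_Quality "literal"\n'
        with pytest.raises(DialectError):
            parse_manchester(text)

    def test_unknown_prefix_is_preserved_opaquely(self):
        frag = parse_manchester("Class: Foo\n    SubClassOf: ZZZ:Bar\n")
        assert frag.classes["Foo"].parents == [Curie("ZZZ", "Bar")]


def _random_fragment(rng: random.Random) -> Fragment:
    frag = Fragment()
    for i in range(rng.randint(0, 3)):
        decl = ClassDecl(f"Cls{i}")
        decl.parents = [Curie("CBO", rng.choice(["Cell", "Field", "CellGrowth"]))]
        if rng.random() < 0.5:
            decl.equivalents.append((RelationKind.HAS_VTK_TYPE_ID, rng.randint(1, 9)))
        if rng.random() < 0.5:
            decl.annotations.append(("xref", f"GO:{rng.randint(0, 99999):07d}"))
        frag.classes[decl.name] = decl
    quality_ids = []
    for i in range(rng.randint(1, 4)):
        qid = f"qual{i}"
        kind = rng.choice(
            [RelationKind.HAS_INT_VALUE, RelationKind.HAS_FLOAT_VALUE,
             RelationKind.HAS_STRING_VALUE, RelationKind.HAS_FLOAT_VALUE_TARGET]
        )
        if kind is RelationKind.HAS_INT_VALUE:
            val = rng.randint(-100, 100)
        elif kind is RelationKind.HAS_STRING_VALUE:
            val = rng.choice(["use_case_1", "abc def", "x_1.vtk"])
        else:
            val = rng.uniform(-10, 10)
        facts = [(kind, val)]
        if rng.random() < 0.6:
            facts.append((RelationKind.HAS_UNIT, units.unit_curie(
                rng.choice(["micrometer", "minute", "hour"]))))
        frag.individuals[qid] = Individual(
            qid, [Curie("CBO", rng.choice(["Volume", "SystemPixelDistanceScale"]))],
            facts,
        )
        quality_ids.append(qid)
    for i in range(rng.randint(0, 2)):
        ind = Individual(f"ind{i}", [Curie("CBO", "System")])
        for qid in rng.sample(quality_ids, k=rng.randint(0, len(quality_ids))):
            ind.facts.append((RelationKind.HAS_QUALITY, qid))
        frag.individuals[ind.id] = ind
    return frag


class TestManchesterRoundTrip:
    def test_parse_serialize_identity_on_random_fragments(self):
        rng = random.Random(7)
        for _ in range(30):
            frag = _random_fragment(rng)
            text = serialize_manchester(frag)
            back = parse_manchester(text)
            assert set(back.classes) == set(frag.classes)
            for name, decl in frag.classes.items():
                b = back.classes[name]
                assert b.parents == decl.parents
                assert b.equivalents == decl.equivalents
                assert b.annotations == decl.annotations
            assert set(back.individuals) == set(frag.individuals)
            for name, ind in frag.individuals.items():
                b = back.individuals[name]
                assert b.types == ind.types
                assert b.facts == ind.facts

    def test_serialize_deterministic(self):
        frag = _random_fragment(random.Random(3))
        assert serialize_manchester(frag) == serialize_manchester(frag)

    def test_empty_fragment_serializes_to_empty(self):
        assert serialize_manchester(Fragment()) == ""


class TestResolveQuality:
    def test_pixel_distance_scale_of_use_case(self, use_case_fragment):
        h = load_core_hierarchy()
        h.merge_fragment(use_case_fragment)
        q = h.resolve_quality("TumorGrowthWithAngiogenesis", "SystemPixelDistanceScale")
        assert q.value == 4.44
        assert q.unit == units.unit_curie("micrometer")
        assert q.value_kind == "actual"

    def test_time_step_of_use_case(self, use_case_fragment):
        h = load_core_hierarchy()
        h.merge_fragment(use_case_fragment)
        q = h.resolve_quality("TumorGrowthWithAngiogenesis", "VTK_FileTimeStep")
        assert (q.value, q.unit) == (1.0, units.unit_curie("minute"))

    def test_target_only_quality_is_kind_target(self):
        h = load_core_hierarchy()
        h.add_individual(Individual(
            "vol", [Curie("CBO", "Volume")],
            [(RelationKind.HAS_FLOAT_VALUE_TARGET, 25.0)],
        ))
        h.add_individual(Individual(
            "cell1", [Curie("CBO", "Cell")],
            [(RelationKind.HAS_QUALITY, "vol")],
        ))
        q = h.resolve_quality("cell1", "Volume")
        assert q.value_kind == "target" and q.value == 25.0

    def test_absent_quality_raises(self, use_case_fragment):
        h = load_core_hierarchy()
        h.merge_fragment(use_case_fragment)
        with pytest.raises(QualityAbsentError):
            h.resolve_quality("TumorGrowthWithAngiogenesis", "Volume")

    def test_two_actual_values_is_ambiguous(self):
        h = load_core_hierarchy()
        for qid in ("v1", "v2"):
            h.add_individual(Individual(
                qid, [Curie("CBO", "Volume")], [(RelationKind.HAS_FLOAT_VALUE, 1.0)],
            ))
        h.add_individual(Individual(
            "c", [Curie("CBO", "Cell")],
            [(RelationKind.HAS_QUALITY, "v1"), (RelationKind.HAS_QUALITY, "v2")],
        ))
        with pytest.raises(AmbiguousQualityError):
            h.resolve_quality("c", "Volume")


class TestUnits:
    def test_si_conversions(self):
        assert units.to_si(4.44, "micrometer") == pytest.approx(4.44e-6)
        assert units.convert(600, "minute", "hour") == pytest.approx(10.0)

    def test_dimension_guard(self):
        with pytest.raises(Exception):
            units.convert(1.0, "minute", "micrometer")
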