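"""Cell geometry, contacts, conditional processes, fields, time series."""

import numpy as np
import pytest

from cbokit import analysis, units
from cbokit import metamodel as mm
from cbokit import simulate as sim
from cbokit.analysis import (
    ContactMap,
    cell_geometry,
    check_spatial_exclusivity,
    contact_map,
    field_statistics,
    instantiate_conditional_processes,
    per_cell_field_mean,
)
from cbokit.errors import InconsistencyError, MappingError
from cbokit.ontology import Curie, Quality
from cbokit.vtkio import CenterSnapshot, LatticeSnapshot

UM = units.unit_curie("micrometer")


def scale_q(v):
    return Quality(Curie("CBO", "SystemPixelDistanceScale"), float(v), "actual", UM)


def lattice(ids, fields=None):
    ids = np.asarray(ids, dtype=np.int32)
    types = (ids > 0).astype(np.int32)  # one type for all cells
    return LatticeSnapshot(dims=ids.shape, cell_id=ids, cell_type=types,
                           fields=fields or {})


def random_label_lattice(rng, dim=10, n_labels=4):
    ids = rng.integers(0, n_labels + 1, size=(dim, dim, dim)).astype(np.int32)
    return lattice(ids)


def brute_force_faces(ids, boundary=("wall",) * 3):
    """Exhaustive pairwise face scan (the oracle for contact_map)."""
    from collections import Counter

    faces = Counter()
    nx_, ny_, nz_ = ids.shape
    for x in range(nx_):
        for y in range(ny_):
            for z in range(nz_):
                a = int(ids[x, y, z])
                for axis, (dx, dy, dz) in enumerate(
                    [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
                ):
                    nxp, nyp, nzp = x + dx, y + dy, z + dz
                    dims = (nx_, ny_, nz_)
                    if (nxp, nyp, nzp)[axis] < dims[axis]:
                        b = int(ids[nxp, nyp, nzp])
                        if a != b:
                            faces[tuple(sorted((a, b)))] += 1
                # boundary faces at both ends of each axis
                for axis, coord, dim in ((0, x, nx_), (1, y, ny_), (2, z, nz_)):
                    if boundary[axis] == "wall":
                        if coord == 0:
                            faces[tuple(sorted((a, ContactMap.BOUNDARY)))] += 1
                        if coord == dim - 1:
                            faces[tuple(sorted((a, ContactMap.BOUNDARY)))] += 1
                    elif coord == 0 and dim > 1:
                        b = int(ids.take(dim - 1, axis=axis)[
                            tuple(c for i, c in enumerate((x, y, z)) if i != axis)])
                        if a != b:
                            faces[tuple(sorted((a, b)))] += 1
    return faces


class TestCellGeometry:
    def test_single_voxel_at_use_case_scale(self):
        ids = np.zeros((3, 3, 3), int)
        ids[1, 1, 1] = 1
        recs = cell_geometry(lattice(ids), scale_q(4.44))
        (r,) = recs
        assert r.volume == pytest.approx(87.528384)
        assert r.surface == pytest.approx(6 * 4.44**2)
        assert r.voxel_count == 1
        assert r.centroid == pytest.approx((1.5 * 4.44,) * 3)

    def test_cube_cell(self):
        ids = np.zeros((4, 4, 4), int)
        ids[1:3, 1:3, 1:3] = 1
        (r,) = cell_geometry(lattice(ids), scale_q(1.0))
        assert (r.volume, r.surface, r.fragment_count) == (8.0, 24.0, 1)

    def test_all_medium_lattice_gives_no_records(self):
        assert cell_geometry(lattice(np.zeros((3, 3, 3), int)), scale_q(1)) == []

    def test_fragmented_cell_counted_once(self):
        ids = np.zeros((5, 1, 1), int)
        ids[0] = ids[4] = 1
        (r,) = cell_geometry(lattice(ids), scale_q(1.0))
        assert r.voxel_count == 2 and r.fragment_count == 2

    def test_2d_lattice_uses_implied_unit_thickness(self):
        ids = np.zeros((5, 5, 1), int)
        ids[1:3, 1:3, 0] = 1
        (r,) = cell_geometry(lattice(ids), scale_q(2.0))
        assert r.volume == pytest.approx(4 * 2.0**2)  # count * scale^2 * 1

    def test_inconsistent_type_rejected(self):
        snap = LatticeSnapshot(dims=(2, 1, 1), cell_id=np.array([1, 1]),
                               cell_type=np.array([1, 2]))
        with pytest.raises(InconsistencyError):
            cell_geometry(snap, scale_q(1))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(23)
        ids = random_label_lattice(rng, dim=6, n_labels=3).cell_id
        base = {r.cell_id: r for r in cell_geometry(lattice(ids), scale_q(1.0))}
        rot = np.rot90(ids, k=1, axes=(0, 1)).copy()
        rotated = {r.cell_id: r for r in cell_geometry(lattice(rot), scale_q(1.0))}
        assert set(base) == set(rotated)
        for cid in base:
            assert rotated[cid].volume == base[cid].volume
            assert rotated[cid].surface == base[cid].surface
            # rot90 about z maps (x, y) -> (ny-1-y, x); voxel centers shift accordingly
            x, y, z = base[cid].centroid
            assert rotated[cid].centroid == pytest.approx((ids.shape[1] - y, x, z))


class TestContactMap:
    def test_two_adjacent_voxels(self):
        ids = np.zeros((2, 1, 1), int)
        ids[0], ids[1] = 1, 2
        cm = contact_map(lattice(ids))
        assert cm.get(1, 2) == 1 == cm.get(2, 1)

    def test_matches_brute_force_on_random_lattices(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            snap = random_label_lattice(rng)
            cm = contact_map(snap)
            oracle = brute_force_faces(snap.cell_id)
            assert dict(cm.items()) == {k: v for k, v in oracle.items() if v}

    def test_periodic_boundary_matches_brute_force(self):
        rng = np.random.default_rng(37)
        boundary = ("periodic", "wall", "periodic")
        snap = random_label_lattice(rng, dim=6)
        cm = contact_map(snap, boundary)
        oracle = brute_force_faces(snap.cell_id, boundary)
        assert dict(cm.items()) == {k: v for k, v in oracle.items() if v}

    def test_surface_decomposition_identity(self):
        """surface(a) = (faces to other cells + medium + boundary) x scale^2."""
        rng = np.random.default_rng(41)
        for _ in range(10):
            snap = random_label_lattice(rng, dim=8)
            s = 1.7
            cm = contact_map(snap)
            for r in cell_geometry(snap, scale_q(s), contacts=cm):
                assert r.surface == pytest.approx(cm.total_faces(r.cell_id) * s * s)

    def test_volume_conservation(self):
        rng = np.random.default_rng(43)
        snap = random_label_lattice(rng)
        recs = cell_geometry(snap, scale_q(1.0))
        medium = int(np.sum(snap.cell_id == 0))
        assert sum(r.voxel_count for r in recs) + medium == snap.n_points

    def test_self_contact_undefined(self):
        with pytest.raises(KeyError):
            ContactMap().get(1, 1)


@pytest.fixture
def adhesion_model():
    m = mm.MetaModel()
    m.system = mm.define_system("AdhTest", (6, 6, 6), scale_q(1.0))
    mm.define_prototype(m, "Medium", "Medium", "Continuous", 0)
    mm.define_prototype(m, "TumorCell", "Cell", "Corpuscular", 1)
    mm.define_prototype(m, "HypoxicTumorCell", "Cell", "Corpuscular", 2)
    mm.define_process(m, "H_T_Adh", "CellCellAdhesion",
                      ["HypoxicTumorCell", "TumorCell"],
                      condition="contact_required")
    return m


def snap_with(idmap: dict[tuple, tuple[int, int]], dims=(6, 6, 6)):
    ids = np.zeros(dims, np.int32)
    types = np.zeros(dims, np.int32)
    for pos, (cid, tid) in idmap.items():
        ids[pos] = cid
        types[pos] = tid
    return LatticeSnapshot(dims=dims, cell_id=ids, cell_type=types)


class TestConditionalProcesses:
    def test_adhesion_iff_contact(self, adhesion_model):
        touching = snap_with({(2, 2, 2): (1, 1), (3, 2, 2): (2, 2)})
        out = instantiate_conditional_processes(adhesion_model, touching)
        assert [(i.process, tuple(sorted(i.participants))) for i in out] == [
            ("H_T_Adh", (1, 2))
        ]
        assert out[0].magnitude == pytest.approx(1.0)  # one shared face x 1^2

        apart = snap_with({(1, 1, 1): (1, 1), (4, 4, 4): (2, 2)})
        assert instantiate_conditional_processes(adhesion_model, apart) == []

    def test_same_prototype_pair_does_not_match(self, adhesion_model):
        both_tumor = snap_with({(2, 2, 2): (1, 1), (3, 2, 2): (2, 1)})
        assert instantiate_conditional_processes(adhesion_model, both_tumor) == []

    def test_count_matches_brute_force_on_random_lattices(self, adhesion_model):
        rng = np.random.default_rng(47)
        for _ in range(20):
            ids = rng.integers(0, 7, size=(6, 6, 6)).astype(np.int32)
            types = np.where(ids == 0, 0, (ids - 1) % 2 + 1).astype(np.int32)
            snap = LatticeSnapshot(dims=ids.shape, cell_id=ids, cell_type=types)
            out = instantiate_conditional_processes(adhesion_model, snap)
            got = {tuple(sorted(i.participants)) for i in out}
            # oracle: exhaustive scan for contacting (type1, type2) pairs
            want = set()
            faces = brute_force_faces(ids)
            tmap = snap.type_of_cells()
            for (a, b), n in faces.items():
                if a > 0 and b > 0 and n and {tmap[a], tmap[b]} == {1, 2}:
                    want.add((a, b))
            assert got == want

    def test_unary_always_process_per_matching_cell(self, adhesion_model):
        mm.define_process(adhesion_model, "T_Growth", "CellGrowth", ["TumorCell"])
        snap = snap_with({(1, 1, 1): (1, 1), (3, 3, 3): (2, 1), (5, 5, 5): (3, 2)})
        out = instantiate_conditional_processes(adhesion_model, snap)
        growth = [i for i in out if i.process == "T_Growth"]
        assert sorted(i.participants[0] for i in growth) == [1, 2]

    def test_unmapped_type_id_raises(self, adhesion_model):
        snap = snap_with({(1, 1, 1): (1, 9)})
        with pytest.raises(MappingError):
            instantiate_conditional_processes(adhesion_model, snap)


class TestSpatialExclusivity:
    def test_lattice_vacuously_valid(self):
        ids = np.ones((2, 2, 2), int)
        assert check_spatial_exclusivity(lattice(ids)) == []

    def test_overlapping_spheres_flagged(self):
        snap = CenterSnapshot(points=[(0, 0, 0), (1.0, 0, 0)], radius=[1, 1],
                              cell_id=[1, 2], cell_type=[1, 1])
        violations = check_spatial_exclusivity(snap, tolerance=0.05)
        assert len(violations) == 1
        assert violations[0][:2] == (1, 2)

    def test_touching_spheres_not_flagged(self):
        snap = CenterSnapshot(points=[(0, 0, 0), (2.0, 0, 0)], radius=[1, 1],
                              cell_id=[1, 2], cell_type=[1, 1])
        assert check_spatial_exclusivity(snap, tolerance=0.05) == []


class TestFieldStatistics:
    def test_uniform_field(self):
        ids = np.zeros((4, 4, 4), int)
        ids[1:3, 1:3, 1:3] = 1
        snap = lattice(ids, fields={"c": np.full((4, 4, 4), 0.25)})
        mn, mx, mean, mass = field_statistics(snap, "c", scale_q(2.0))
        assert (mn, mx, mean) == (0.25, 0.25, 0.25)
        assert mass == pytest.approx(0.25 * 64 * 8.0)
        assert per_cell_field_mean(snap, "c") == {1: 0.25}

    def test_per_cell_mean_matches_brute_force(self):
        rng = np.random.default_rng(53)
        ids = rng.integers(0, 4, size=(7, 7, 7)).astype(np.int32)
        f = rng.random((7, 7, 7))
        snap = lattice(ids, fields={"c": f})
        means = per_cell_field_mean(snap, "c")
        for cid in np.unique(ids):
            if cid == 0:
                continue
            assert means[int(cid)] == pytest.approx(float(f[ids == cid].mean()))

    def test_no_cells_gives_empty_mapping(self):
        snap = lattice(np.zeros((3, 3, 3), int), fields={"c": np.ones((3, 3, 3))})
        assert per_cell_field_mean(snap, "c") == {}

    def test_unknown_field_raises(self):
        with pytest.raises(KeyError):
            field_statistics(lattice(np.zeros((2, 2, 2), int)), "nope")


class TestTimeSeries:
    def test_single_snapshot_series(self, tmp_path):
        scen = sim.make_scenario("two_cell_toy")
        sim.run(scen, tmp_path, seed=0, n_steps=0)
        ts = analysis.build_timeseries(scen.model, tmp_path)
        assert len(ts.times) == 1 and ts.events == []
        assert len(ts.records[0]) == 2

    def test_events_match_simulator_ground_truth(self, mini_run):
        scen, out, events = mini_run
        ts = analysis.build_timeseries(scen.model, out)
        inferred = {(ev.time, ev.kind, ev.ids) for ev in ts.events}
        truth = {(float(s), k, ids) for s, k, ids in events}
        assert inferred == truth
        assert any(k == "division" for _, k, _ in events)
        assert any(k == "phenotype_change" for _, k, _ in events)

    def test_necrotic_target_volume_drops_half_per_step(self, tmp_path):
        """Starving the lattice drives cells necrotic; their recovered
        target-volume quality then decreases by 0.5 each step."""
        scen = sim.make_scenario("tumor_angiogenesis_mini")
        scen.initial_fields = dict(scen.initial_fields, Nutrient=0.05)
        sim.run(scen, tmp_path, seed=3, n_steps=8, output_every=1)
        ts = analysis.build_timeseries(scen.model, tmp_path)
        necrotic_tid = scen.model.prototypes["NecroticTumorCell"].vtk_type_id
        traj: dict[int, list[float]] = {}
        for recs in ts.records:
            for r in recs:
                if r.type_id == necrotic_tid and r.target_qualities:
                    traj.setdefault(r.cell_id, []).append(
                        r.target_qualities[0].value)
        assert traj, "no necrotic cells appeared"
        for values in traj.values():
            diffs = np.diff(values)
            assert np.allclose(diffs, -0.5)
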