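"""Structure/trajectory I/O, selection grammar, and the pore frame."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import porekinetics as pk
from porekinetics.model import SelectionSyntaxError, select


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

class TestSelectionGrammar:
    def test_resid_range_and_heavy_spans_all_chains(self, cone_pore):
        model, _ = cone_pore
        sel = select(model, "resid 3-5 and heavy")
        resids = {model.atoms[i].resid for i in sel.indices}
        assert resids == {3, 4, 5}

    def test_gate_selection_excludes_hydrogens(self, five_atom_model):
        # add a hydrogen to check the heavy keyword
        from porekinetics.model import AtomRecord, MolecularModel
        atoms = five_atom_model.atoms + [
            AtomRecord(6, "H", "H", "GLY", 394, "A", np.array([0.0, -1.0, 0.0]))]
        m = MolecularModel(atoms)
        sel = select(m, "resid 394-398 and heavy")
        assert all(m.atoms[i].element != "H" for i in sel.indices)
        assert len(sel) == 5

    def test_ca_name_combination(self, straight_helix):
        model, _ = straight_helix
        sel = select(model, "name CA and resid 10-20")
        assert len(sel) == 11
        assert all(model.atoms[i].name == "CA" for i in sel.indices)

    def test_degenerate_range_warns_and_is_empty(self, five_atom_model):
        with pytest.warns(UserWarning):
            sel = select(five_atom_model, "resid 10-5")
        assert len(sel) == 0

    def test_unknown_chain_warns_empty(self, five_atom_model):
        with pytest.warns(UserWarning):
            sel = select(five_atom_model, "chain Z")
        assert len(sel) == 0

    @pytest.mark.parametrize("expr", ["resid", "name and", "resid 1-2 bogus",
                                      "(resid 1", ""])
    def test_syntax_errors_carry_position(self, five_atom_model, expr):
        with pytest.raises(SelectionSyntaxError):
            select(five_atom_model, expr)

    def test_resolution_is_idempotent_and_order_stable(self, straight_helix):
        model, _ = straight_helix
        expr = "resid 5-12 17-20 and backbone or name CA"
        a = select(model, expr).indices
        b = select(model, expr).indices
        assert np.array_equal(a, b)
        assert np.all(np.diff(a) > 0)

    def test_boolean_operators(self, straight_helix):
        model, _ = straight_helix
        full = select(model, "all")
        inv = select(model, "not name CA")
        ca = select(model, "ca")
        assert len(inv) + len(ca) == len(full)


# ---------------------------------------------------------------------------
# pore frame
# ---------------------------------------------------------------------------

class TestPoreFrame:
    def _two_ring_model(self):
        spec = pk.RingPoreSpec(z_planes=[0.0, 20.0], ring_radius_at_z=[5.0, 5.0],
                               atoms_per_ring=16, atom_radius=1.5,
                               resids=[398, 358])
        model, _ = spec_model = pk.generate_ring_pore(spec)
        return model

    def test_axis_from_gate_to_filter(self):
        model = self._two_ring_model()
        frame = pk.build_pore_frame(model, "resid 398", "resid 358")
        assert np.allclose(frame.origin, [0, 0, 0], atol=1e-9)
        assert np.allclose(frame.axis, [0, 0, 1], atol=1e-9)

    def test_equivariance_under_rigid_rotation(self):
        model = self._two_ring_model()
        R = Rotation.from_euler("xyz", [30, -20, 45], degrees=True).as_matrix()
        shift = np.array([3.0, -7.0, 11.0])
        moved = model.with_coords(model.coords @ R.T + shift)
        f0 = pk.build_pore_frame(model, "resid 398", "resid 358")
        f1 = pk.build_pore_frame(moved, "resid 398", "resid 358")
        assert np.allclose(f1.origin, R @ f0.origin + shift, atol=1e-9)
        assert np.allclose(f1.axis, R @ f0.axis, atol=1e-9)

    def test_coincident_centroids_degenerate(self):
        spec = pk.RingPoreSpec(z_planes=[0.0, 0.4], ring_radius_at_z=[5.0, 5.0],
                               atoms_per_ring=16, atom_radius=1.5,
                               resids=[398, 358])
        model, _ = pk.generate_ring_pore(spec)
        with pytest.raises(ValueError, match="degenerate"):
            pk.build_pore_frame(model, "resid 398", "resid 358")

    def test_projection_splits_axial_and_radial(self, axis_frame):
        z, r = axis_frame.project(np.array([[3.0, 4.0, 7.0]]))
        assert z[0] == pytest.approx(7.0)
        assert r[0] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

class TestStructureIO:
    def test_pdb_round_trip_preserves_resids(self, five_atom_model, tmp_path):
        p = tmp_path / "five.pdb"
        pk.write_structure(five_atom_model, p)
        back = pk.read_structure(p)
        assert len(back) == 5
        assert [a.resid for a in back.atoms] == [394, 394, 394, 394, 398]
        assert np.abs(back.coords - five_atom_model.coords).max() < 1e-3

    def test_cross_format_pdb_mmcif_agree(self, straight_helix, tmp_path):
        model, _ = straight_helix
        pdb, cif = tmp_path / "h.pdb", tmp_path / "h.cif"
        pk.write_structure(model, pdb)
        pk.write_structure(model, cif)
        a = pk.read_structure(pdb)
        b = pk.read_structure(cif)
        assert len(a) == len(b) == len(model)
        assert np.abs(a.coords - b.coords).max() < 1e-3

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\n_nonsense 1 2 3\n")
        with pytest.raises(ValueError):
            pk.read_structure(bad, format="mmCIF")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pk.read_structure(tmp_path / "nope.pdb")

    def test_altloc_collapsed_to_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00"
            "           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00"
            "           C\n"
            "END\n")
        m = pk.read_structure(pdb)
        assert len(m) == 1
        assert m.atoms[0].xyz[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# trajectory and ion-trace I/O
# ---------------------------------------------------------------------------

class TestTrajectoryIO:
    def test_xtc_round_trip(self, five_atom_model, tmp_path):
        import MDAnalysis as mda

        top = tmp_path / "top.pdb"
        pk.write_structure(five_atom_model, top)
        rng = np.random.default_rng(0)
        frames = [five_atom_model.coords + rng.normal(0, 0.5, (5, 3))
                  for _ in range(4)]
        xtc = tmp_path / "r1.xtc"
        u = mda.Universe(str(top))
        u.dimensions = [50, 50, 50, 90, 90, 90]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(xtc), 5) as w:
                for pos in frames:
                    u.atoms.positions = pos
                    w.write(u.atoms)
        ens = pk.read_trajectory([xtc], five_atom_model, frame_interval=0.5)
        assert ens.n_replicas == 1
        assert ens.replicas[0].shape == (4, 5, 3)
        assert np.abs(ens.replicas[0] - np.array(frames)).max() < 0.02

    def test_atom_count_mismatch_raises(self, five_atom_model, straight_helix,
                                        tmp_path):
        import MDAnalysis as mda

        other, _ = straight_helix
        top = tmp_path / "other.pdb"
        pk.write_structure(other, top)
        xtc = tmp_path / "o.xtc"
        u = mda.Universe(str(top))
        u.dimensions = [90, 90, 90, 90, 90, 90]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(xtc), len(other)) as w:
                w.write(u.atoms)
        with pytest.raises(ValueError, match="atoms"):
            pk.read_trajectory([xtc], five_atom_model)

    def test_ion_trace_tsv_round_trip(self, tmp_path):
        spec = pk.LangevinSpec(n_ions=2, duration=2.0, dt=0.01, seed=5,
                               sample_every=10)
        ts, _ = pk.simulate_ion_langevin(spec)
        path = tmp_path / "traces.tsv"
        pk.write_ion_traces(ts, path, xy=ts.meta["xy"])
        back = pk.read_ion_traces(path)
        assert len(back) == 2
        for a, b in zip(ts, back):
            assert a.ion_id == b.ion_id
            assert np.abs(a.z - b.z).max() < 1e-6
            assert np.abs(a.r_offset - b.r_offset).max() < 1e-6

    def test_tsv_dialect_header(self, tmp_path):
        spec = pk.LangevinSpec(n_ions=1, duration=1.0, dt=0.01, seed=1,
                               sample_every=20)
        ts, _ = pk.simulate_ion_langevin(spec)
        path = tmp_path / "t.tsv"
        pk.write_ion_traces(ts, path)
        first = path.read_text().splitlines()[0]
        assert first == "time_ns\tion_id\tx\ty\tz"

    def test_tsv_ensemble_needs_no_topology(self, tmp_path):
        spec = pk.LangevinSpec(n_ions=2, duration=2.0, dt=0.01, seed=2,
                               sample_every=10)
        ts, _ = pk.simulate_ion_langevin(spec)
        p = tmp_path / "r1.tsv"
        pk.write_ion_traces(ts, p)
        ens = pk.read_trajectory([p])
        assert ens.topology is None
        assert ens.n_replicas == 1
        assert len(ens.ion_traces[0]) == 2
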