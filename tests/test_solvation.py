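"""Density/PMF inversion, hydration, coordination, and H-bond criteria."""

import numpy as np
import pytest

import porekinetics as pk
from porekinetics.constants import kT
from porekinetics.model import AtomRecord, MolecularModel
from porekinetics.solvation import ion_density_profile, pmf_from_density

from conftest import make_trace


def metropolis_samples(u_table, z_range, n_samples, seed, kt=kT()):
    """Independent-chain Metropolis sampler of exp(-U/kT); the oracle used
    to test Boltzmann inversion, deliberately separate from the package."""
    zk = np.array([p[0] for p in u_table])
    uk = np.array([p[1] for p in u_table])

    def U(z):
        return np.interp(z, zk, uk)

    rng = np.random.default_rng(seed)
    n_chains = 2000
    burn, keep = 300, int(np.ceil(n_samples / n_chains))
    z = rng.uniform(z_range[0], z_range[1], n_chains)
    u = U(z)
    out = np.empty((keep, n_chains))
    for step in range(burn + keep):
        prop = z + rng.normal(0, 6.0, n_chains)
        inside = (prop >= z_range[0]) & (prop <= z_range[1])
        up = np.where(inside, U(prop), np.inf)
        acc = rng.uniform(size=n_chains) < np.exp(-(up - u) / kt)
        z = np.where(acc, prop, z)
        u = np.where(acc, up, u)
        if step >= burn:
            out[step - burn] = z
    return out.ravel()[:n_samples]


DOUBLE_BARRIER = [(-25.0, 0.0), (-14.0, 0.0), (-11.0, 2.0), (-9.0, 2.0),
                  (-6.0, 0.0), (6.0, 0.0), (9.0, 2.0), (11.0, 2.0),
                  (14.0, 0.0), (25.0, 0.0)]


class TestDensityProfile:
    def test_uniform_samples_flat_density(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(-10, 10, 200000)
        tr = make_trace(np.sort(z))
        dens = ion_density_profile([tr], np.arange(-10, 10.1, 2.0), 12.0)
        rel = dens.density / np.nanmean(dens.density)
        assert np.nanmax(np.abs(rel - 1)) < 0.05

    def test_all_samples_in_one_bin_delta(self):
        tr = make_trace(np.full(100, 3.1), t=np.arange(100.0))
        dens = ion_density_profile([tr], np.arange(0, 10.1, 2.0), 12.0)
        assert np.count_nonzero(dens.counts) == 1
        assert np.isnan(dens.density[dens.counts == 0]).all()

    def test_radial_cutoff_excludes_offset_samples(self):
        tr = make_trace(np.zeros(10), t=np.arange(10.0), r=np.full(10, 13.0))
        dens = ion_density_profile([tr], np.arange(-2, 2.1, 1.0), 12.0)
        assert dens.counts.sum() == 0
        assert np.isnan(dens.density).all()


class TestPMF:
    def test_uniform_density_zero_free_energy(self):
        rng = np.random.default_rng(0)
        tr = make_trace(np.sort(rng.uniform(-10, 10, 500000)))
        dens = ion_density_profile([tr], np.arange(-10, 10.1, 2.0), 12.0)
        prof = pmf_from_density(dens, reference_window=(-10, 10))
        assert np.nanmax(np.abs(prof.F)) < 0.01

    def test_ten_to_one_ratio_gives_kt_ln_ten(self):
        # -kT ln 10 at 298 K = 1.364 kcal/mol
        z = np.concatenate([np.full(10000, -5.0), np.full(1000, 5.0)])
        tr = make_trace(z, t=np.arange(len(z), dtype=float))
        dens = ion_density_profile([tr], np.array([-10.0, 0.0, 10.0]), 12.0)
        prof = pmf_from_density(dens, reference_window=(-10.0, 0.0))
        assert prof.F[1] == pytest.approx(1.364, abs=0.002)

    def test_density_scale_invariance(self):
        rng = np.random.default_rng(3)
        z = np.sort(rng.normal(0, 5, 20000))
        tr1 = make_trace(z)
        tr3 = [make_trace(z, ion_id=f"i{k}") for k in range(3)]  # 3x the counts
        bins = np.arange(-12, 12.1, 2.0)
        p1 = pmf_from_density(ion_density_profile([tr1], bins, 12.0),
                              reference_window=(-2, 2))
        p3 = pmf_from_density(ion_density_profile(tr3, bins, 12.0),
                              reference_window=(-2, 2))
        assert np.allclose(p1.F, p3.F, equal_nan=True, atol=1e-9)

    def test_double_barrier_recovered_from_metropolis(self):
        samples = metropolis_samples(DOUBLE_BARRIER, (-25, 25), 10 ** 6, seed=5)
        tr = make_trace(np.asarray(samples), t=np.arange(len(samples), dtype=float))
        bins = np.arange(-25.0, 25.5, 0.5)
        dens = ion_density_profile([tr], bins, 12.0)
        prof = pmf_from_density(dens, reference_window=(-4.0, 4.0))
        for apex in (-10.0, 10.0):
            i = np.argmin(np.abs(prof.z_bins - apex))
            assert prof.F[i] == pytest.approx(2.0, abs=0.1)

    def test_linear_tilt_correction_removes_field_term(self):
        # density from a pure linear potential; corrected PMF is flat
        qv, span = -2.0, 20.0
        u_table = [(-10.0, 0.0), (10.0, -qv)]  # F = -dU/dz = qv/span
        samples = metropolis_samples(u_table, (-10, 10), 400000, seed=2)
        tr = make_trace(np.asarray(samples), t=np.arange(len(samples),
                                                         dtype=float))
        dens = ion_density_profile([tr], np.arange(-10, 10.5, 1.0), 12.0)
        prof = pmf_from_density(dens, reference_window=(-2, 2),
                                tilt_correction={"qv_kcal": qv, "span": span})
        inner = np.abs(prof.z_bins) < 8
        assert np.nanmax(np.abs(prof.F[inner])) < 0.05

    def test_fully_masked_density_refused(self):
        tr = make_trace(np.zeros(5), t=np.arange(5.0), r=np.full(5, 20.0))
        dens = ion_density_profile([tr], np.arange(-2, 2.1, 1.0), 12.0)
        with pytest.raises(ValueError):
            pmf_from_density(dens, reference_window=(-2, 2))


class TestHydration:
    def test_known_cylinder_count_exact(self, axis_frame):
        model, truth = pk.generate_solvation_snapshot(15, 12.0, 0, 2.8, seed=4)
        prof = pk.hydration_profile([model], axis_frame, 12.0,
                                    np.array([-10.0, 10.0]))
        assert prof.mean_waters[0] == truth["n_in_cylinder"]

    def test_decoys_beyond_cutoff_excluded(self, axis_frame):
        model, _ = pk.generate_solvation_snapshot(8, 12.0, 0, 2.8, seed=6,
                                                  n_decoys=20)
        prof = pk.hydration_profile([model], axis_frame, 12.0,
                                    np.array([-10.0, 10.0]))
        assert prof.mean_waters[0] == 8

    def test_waterless_system_zero_and_dry(self, axis_frame):
        model, _ = pk.generate_solvation_snapshot(0, 12.0, 0, 2.8, seed=0,
                                                  n_decoys=0)
        with pytest.warns(UserWarning):
            prof = pk.hydration_profile([model], axis_frame, 12.0,
                                        np.arange(-10, 10.1, 5.0))
        assert np.all(prof.mean_waters == 0)
        assert np.all(prof.dry)


class TestCoordination:
    def test_constructed_shell_count(self):
        model, _ = pk.generate_solvation_snapshot(10, 12.0, 6, 2.8, seed=1)
        out = pk.coordination_number([model], "element K", 3.5)
        assert out["per_frame"] == [[6]]

    def test_cutoff_below_shell_gives_zero(self):
        model, _ = pk.generate_solvation_snapshot(10, 12.0, 6, 2.8, seed=1)
        out = pk.coordination_number([model], "element K", 2.0)
        assert out["per_frame"] == [[0]]

    def test_waters_lost_is_bulk_minus_site(self):
        assert pk.waters_lost(6.0, 3.0) == 3.0
        assert pk.waters_lost(6.0, 4.0) == 2.0


class TestHBonds:
    def _hydroxyl(self, serial, resid, o_pos, h_pos):
        return [AtomRecord(serial, "OH", "O", "TYR", resid, "A",
                           np.asarray(o_pos, float)),
                AtomRecord(serial + 1, "HH", "H", "TYR", resid, "A",
                           np.asarray(h_pos, float))]

    def test_ideal_linear_bond_counts_once(self):
        atoms = self._hydroxyl(1, 1, [0, 0, 0], [0.96, 0, 0]) + \
            self._hydroxyl(3, 2, [2.8, 0, 0], [2.8 + 0.96, 0, 0])
        m = MolecularModel(atoms)
        out = pk.hbond_stats([m], ["resid 1 and name OH"],
                             ["resid 2 and name OH"])
        assert out["total_per_frame"] == [1]

    def test_distance_beyond_cutoff_no_bond(self):
        atoms = self._hydroxyl(1, 1, [0, 0, 0], [0.96, 0, 0]) + \
            self._hydroxyl(3, 2, [3.6, 0, 0], [4.56, 0, 0])
        m = MolecularModel(atoms)
        out = pk.hbond_stats([m], ["resid 1 and name OH"],
                             ["resid 2 and name OH"])
        assert out["total_per_frame"] == [0]

    def test_bent_geometry_rejected_by_angle(self):
        # donor H pointing away: angle D-H...A far below 150 degrees
        atoms = self._hydroxyl(1, 1, [0, 0, 0], [-0.96, 0, 0]) + \
            self._hydroxyl(3, 2, [2.8, 0, 0], [3.76, 0, 0])
        m = MolecularModel(atoms)
        out = pk.hbond_stats([m], ["resid 1 and name OH"],
                             ["resid 2 and name OH"])
        assert out["total_per_frame"] == [0]

    def test_hydroxyl_ring_double_credit_mean_two(self):
        pos = [np.array([0.0, 0, 0]), np.array([2.8, 0, 0]),
               np.array([2.8, 2.8, 0]), np.array([0, 2.8, 0.0])]
        atoms = []
        for i, p in enumerate(pos):
            nxt = pos[(i + 1) % 4]
            h = p + 0.96 * (nxt - p) / np.linalg.norm(nxt - p)
            atoms += self._hydroxyl(2 * i + 1, i + 1, p, h)
        m = MolecularModel(atoms)
        groups = [f"resid {i + 1} and name OH" for i in range(4)]
        out = pk.hbond_stats([m], groups, groups)
        assert out["mean_per_group"] == pytest.approx(2.0)
        assert all(v == pytest.approx(2.0)
                   for v in out["per_group_mean"].values())

    def test_no_hydrogens_falls_back_to_distance(self):
        atoms = [AtomRecord(1, "OH", "O", "TYR", 1, "A", np.zeros(3)),
                 AtomRecord(2, "OH", "O", "TYR", 2, "A",
                            np.array([2.8, 0.0, 0.0]))]
        m = MolecularModel(atoms)
        with pytest.warns(UserWarning, match="distance-only"):
            out = pk.hbond_stats([m], ["resid 1"], ["resid 2"])
        assert out["total_per_frame"] == [1]
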