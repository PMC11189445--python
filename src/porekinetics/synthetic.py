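"""Synthetic fixtures with analytically known ground truth.

Every generator here returns its ground truth alongside the data, so each
analysis stage (pore profiling, permeation counting, PMF inversion, helix
geometry, hydration, G-V fitting) can be exercised without any external
input. The Langevin ion generator abstracts the applied-field MD design the
analyses target: non-interacting cations drifting through a membrane span
under a constant field (default -500 mV across a 36 Å span, 500 ns, three
replicas, K+), with a periodic simulation cell along z.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import T_DEFAULT, kT, voltage_to_kcal
from .model import AtomRecord, MolecularModel
from .traces import IonTrace, IonTraceSet

__all__ = [
    "RingPoreSpec",
    "LangevinSpec",
    "GVCurve",
    "generate_ring_pore",
    "simulate_ion_langevin",
    "generate_kinked_helix",
    "generate_solvation_snapshot",
    "generate_gv_data",
]


# ---------------------------------------------------------------------------
# Ring-built pseudo-atom pores (oracle for the pore profiler)
# ---------------------------------------------------------------------------

@dataclass
class RingPoreSpec:
    """Stacked rings of pseudo-atoms with an analytically known pore radius."""

    z_planes: Sequence[float]
    ring_radius_at_z: Sequence[float]
    atoms_per_ring: int = 24
    atom_radius: float = 1.5
    element: str = "C"
    resids: Sequence[int] | None = None

    def __post_init__(self):
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        self.ring_radius_at_z = np.asarray(self.ring_radius_at_z, dtype=float)
        if len(self.z_planes) != len(self.ring_radius_at_z):
            raise ValueError("z_planes and ring_radius_at_z must have equal length")
        if len(self.z_planes) > 1 and not np.all(np.diff(self.z_planes) > 0):
            raise ValueError("z_planes must be strictly increasing")
        if np.any(self.ring_radius_at_z <= self.atom_radius):
            raise ValueError("ring_radius_at_z must exceed atom_radius everywhere")
        if self.atoms_per_ring < 12:
            raise ValueError("atoms_per_ring must be >= 12 (sparser rings break "
                             "the dense-ring inscribed-radius formula)")


def generate_ring_pore(spec: RingPoreSpec
                       ) -> tuple[MolecularModel, Callable[[np.ndarray], np.ndarray]]:
    """Build a ring-pore model and its analytic inscribed-radius profile.

    Atoms are placed uniformly on each ring (staggered between rings by the
    golden angle so the stack is not trivially aligned). The returned
    callable gives, for any z on the axis, the exact inscribed-sphere radius
    for an on-axis probe: ``min over rings sqrt(R_i^2 + (z - z_i)^2) - a``.
    With >= 12 atoms per ring the on-axis centre is the true optimum, so at
    a ring plane the profile equals ``ring_radius - atom_radius``.
    """
    atoms = []
    serial = 0
    resids = spec.resids if spec.resids is not None else range(1, len(spec.z_planes) + 1)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k, (z, rr, resid) in enumerate(zip(spec.z_planes, spec.ring_radius_at_z, resids)):
        phase = k * golden
        for j in range(spec.atoms_per_ring):
            theta = phase + 2.0 * math.pi * j / spec.atoms_per_ring
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=f"X{j + 1}", element=spec.element,
                resname="RNG", resid=int(resid), chain="A",
                xyz=np.array([rr * math.cos(theta), rr * math.sin(theta), z]),
                vdw_radius=spec.atom_radius))
    model = MolecularModel(atoms, title="ring pore", source_format="synthetic")

    z_planes = spec.z_planes.copy()
    radii = spec.ring_radius_at_z.copy()
    a = spec.atom_radius

    def analytic_profile(z):
        zz = np.atleast_1d(np.asarray(z, dtype=float))
        d = np.sqrt(radii[:, None] ** 2 + (zz[None, :] - z_planes[:, None]) ** 2)
        out = d.min(axis=0) - a
        return out if np.ndim(z) else float(out[0])

    return model, analytic_profile


# ---------------------------------------------------------------------------
# Overdamped Langevin cation traces under an applied field
# ---------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Overdamped 1-D ion dynamics in a periodic cell with a membrane span.

    The applied voltage acts only inside ``membrane_span`` as a constant
    force q*V/span; ``pmf_shape`` is an optional piecewise-linear free-energy
    table (z -> kcal/mol). The default diffusion constant is the bulk K+
    value, a documented stand-in rather than a fitted quantity.
    """

    n_ions: int = 10
    duration: float = 500.0          # ns
    dt: float = 0.02                 # ns
    diffusion_D: float = 196.0       # Å^2/ns (bulk K+)
    voltage: float = -500.0          # mV
    membrane_span: tuple[float, float] = (-18.0, 18.0)
    pmf_shape: Sequence[tuple[float, float]] | None = None
    domain_length: float = 140.0     # Å, periodic in z
    temperature: float = T_DEFAULT
    charge_e: float = 1.0
    seed: int = 0
    sample_every: int = 1
    xy_jitter_sd: float = 0.8        # Å, radial-offset filler

    def __post_init__(self):
        z_lo, z_hi = self.membrane_span
        if z_hi <= z_lo:
            raise ValueError("membrane_span must be (z_lo, z_hi) with z_hi > z_lo")
        span = z_hi - z_lo
        if self.domain_length <= span:
            raise ValueError("domain_length must exceed the membrane span width")
        dt_max = 0.01 * span ** 2 / self.diffusion_D
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt} ns violates the stability bound; use dt <= {dt_max:.4g} ns")
        if self.duration <= 0 or self.n_ions < 1:
            raise ValueError("duration must be > 0 and n_ions >= 1")


def _piecewise_force(pmf: Sequence[tuple[float, float]] | None
                     ) -> Callable[[np.ndarray], np.ndarray]:
    if not pmf:
        return lambda z: np.zeros_like(z)
    pts = np.asarray(sorted(pmf), dtype=float)
    zk, uk = pts[:, 0], pts[:, 1]
    slopes = np.diff(uk) / np.diff(zk)

    def force(z):
        # F = -dU/dz on each linear piece; zero outside the table
        idx = np.searchsorted(zk, z, side="right") - 1
        f = np.zeros_like(z)
        inside = (idx >= 0) & (idx < len(slopes))
        f[inside] = -slopes[idx[inside]]
        return f

    return force


def simulate_ion_langevin(spec: LangevinSpec) -> tuple[IonTraceSet, float]:
    """Simulate non-interacting cations and return traces + expected flux.

    Dynamics: ``z <- z + (D*F(z)/kT)*dt + sqrt(2*D*dt)*eta`` with
    ``eta ~ N(0,1)``; the field force q*V/span applies only inside the
    membrane span; z is wrapped over the periodic domain for force
    evaluation but the stored traces keep the unwrapped coordinate.

    The second return value is the drift-based expected number of complete
    domain crossings per ion, ``v_bar * duration / L`` with the
    domain-averaged drift velocity ``v_bar = D*q*V/(kT*L)`` (negative means
    net flux toward -z). It equates the spatial and temporal averages of the
    drift, which is exact when the force is uniform over the domain (flat
    intrinsic PMF, membrane span ~ the whole domain); with a narrow span or
    a non-flat ``pmf_shape`` transport through the force-free region is
    diffusion-limited and the returned value is only the linear-response
    estimate.
    """
    rng = np.random.default_rng(spec.seed)
    z_lo, z_hi = spec.membrane_span
    span = z_hi - z_lo
    L = spec.domain_length
    kt = kT(spec.temperature)
    f_field = voltage_to_kcal(spec.voltage, spec.charge_e) / span  # kcal/mol/Å
    pmf_force = _piecewise_force(spec.pmf_shape)

    n_steps = int(round(spec.duration / spec.dt))
    z = rng.uniform(-L / 2, L / 2, size=spec.n_ions)
    offset = np.zeros(spec.n_ions)  # accumulated unwrap offset, multiples of L
    pref = spec.diffusion_D * spec.dt / kt
    noise_sd = math.sqrt(2.0 * spec.diffusion_D * spec.dt)

    n_samples = n_steps // spec.sample_every + 1
    zs = np.empty((n_samples, spec.n_ions))
    ts = np.empty(n_samples)
    zs[0] = z + offset
    ts[0] = 0.0
    k = 1
    for step in range(1, n_steps + 1):
        inside = (z >= z_lo) & (z <= z_hi)
        F = pmf_force(z)
        F[inside] += f_field
        z = z + pref * F + noise_sd * rng.standard_normal(spec.n_ions)
        # periodic wrap, retaining the unwrapped copy via the offset
        wrap_hi = z >= L / 2
        wrap_lo = z < -L / 2
        z[wrap_hi] -= L
        offset[wrap_hi] += L
        z[wrap_lo] += L
        offset[wrap_lo] -= L
        if step % spec.sample_every == 0:
            zs[k] = z + offset
            ts[k] = step * spec.dt
            k += 1

    xy = rng.normal(0.0, spec.xy_jitter_sd, size=(2, n_samples, spec.n_ions))
    traces = []
    for i in range(spec.n_ions):
        r = np.hypot(xy[0, :, i], xy[1, :, i])
        traces.append(IonTrace(ion_id=f"ion{i + 1}", t=ts[:k].copy(),
                               z=zs[:k, i].copy(), r_offset=r[:k]))
    v_bar = spec.diffusion_D * voltage_to_kcal(spec.voltage, spec.charge_e) / (kt * L)
    expected_crossings = v_bar * spec.duration / L
    trace_set = IonTraceSet(
        traces=traces, duration=spec.duration, voltage=spec.voltage,
        meta={"seed": spec.seed, "domain_length": L, "membrane_span": (z_lo, z_hi),
              "diffusion_D": spec.diffusion_D, "expected_crossings_per_ion":
              expected_crossings,
              "xy": {f"ion{i + 1}": (xy[0, :k, i], xy[1, :k, i])
                     for i in range(spec.n_ions)}})
    return trace_set, expected_crossings


# ---------------------------------------------------------------------------
# Ideal / kinked / partially unwound helices (oracle for helix geometry)
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
PHI_HELIX, PSI_HELIX = -57.0, -47.0
PHI_EXT, PSI_EXT = -120.0, 130.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position d with |cd|=bond, angle(bcd), dihedral(abcd)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(dih),
                   bond * math.sin(ang) * math.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def generate_kinked_helix(n_res: int, kink_after: int = 0, bend_deg: float = 0.0,
                          unwound_tail: int = 0) -> tuple[MolecularModel, dict]:
    """Build an ideal poly-ALA α-helix backbone with an optional mid-helix
    kink and an extended (unwound) C-terminal tail.

    Backbone N/CA/C/O atoms are chained with standard bond geometry at
    (φ, ψ) = (-57°, -47°); the final ``unwound_tail`` residues use the
    extended (-120°, 130°) conformation. ``bend_deg`` rigidly rotates the
    segment after residue ``kink_after`` (1-based) about an axis through
    that residue's Cα perpendicular to the pre-kink helix axis.

    Returns the model and a ground-truth dict with the bend angle, tail
    length, and the 1-based indices of tail residues.
    """
    if not (0 <= unwound_tail < n_res):
        raise ValueError("unwound_tail must satisfy 0 <= tail < n_res")
    if not (0.0 <= bend_deg <= 90.0):
        raise ValueError("bend_deg must be within [0, 90] degrees")
    phi = np.full(n_res, PHI_HELIX)
    psi = np.full(n_res, PSI_HELIX)
    if unwound_tail:
        phi[n_res - unwound_tail:] = PHI_EXT
        psi[n_res - unwound_tail:] = PSI_EXT
        psi[n_res - unwound_tail - 1] = PSI_HELIX  # last helical residue keeps its psi

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    O = np.empty((n_res, 3))
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], _BOND_C_N, _ANG_CA_C_N, psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], _BOND_N_CA, _ANG_C_N_CA, 180.0)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], _BOND_CA_C, _ANG_N_CA_C,
                               phi[i + 1])
    for i in range(n_res):
        # carbonyl O trans to the next N (psi + 180), in the peptide plane
        O[i] = _place_atom(N[i], CA[i], C[i], _BOND_C_O, _ANG_CA_C_O, psi[i] + 180.0)

    if bend_deg > 0 and 0 < kink_after < n_res:
        pre = CA[:kink_after]
        axis = _principal_axis(pre)
        perp = np.array([1.0, 0.0, 0.0])
        perp = perp - (perp @ axis) * axis
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([0.0, 1.0, 0.0])
            perp = perp - (perp @ axis) * axis
        perp /= np.linalg.norm(perp)
        Rm = _rotation_matrix(perp, math.radians(bend_deg))
        pivot = CA[kink_after - 1]
        for arr in (N, CA, C, O):
            sl = slice(kink_after, n_res)
            arr[sl] = (arr[sl] - pivot) @ Rm.T + pivot

    atoms = []
    serial = 0
    for i in range(n_res):
        for nm, pos, el in (("N", N[i], "N"), ("CA", CA[i], "C"),
                            ("C", C[i], "C"), ("O", O[i], "O")):
            serial += 1
            atoms.append(AtomRecord(serial=serial, name=nm, element=el,
                                    resname="ALA", resid=i + 1, chain="A",
                                    xyz=pos.copy()))
    model = MolecularModel(atoms, title="kinked helix", source_format="synthetic")
    truth = {
        "bend_deg": float(bend_deg),
        "kink_after": int(kink_after),
        "unwound_tail": int(unwound_tail),
        "tail_resids": list(range(n_res - unwound_tail + 1, n_res + 1)),
    }
    return model, truth


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (pts[-1] - pts[0]) < 0:  # orient N -> C
        axis = -axis
    return axis


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(axis * angle).as_matrix()


# ---------------------------------------------------------------------------
# Solvation snapshots with known water counts
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def generate_solvation_snapshot(n_waters_in_cylinder: int, cylinder_radius: float,
                                n_first_shell: int, shell_radius: float,
                                seed: int = 0, ion_z: float = 0.0,
                                z_extent: float = 10.0, n_decoys: int = 12,
                                shell_gap: float = 1.5) -> tuple[MolecularModel, dict]:
    """One K+ on the pore axis plus water oxygens with exact known counts.

    Exactly ``n_first_shell`` oxygens sit on a sphere of ``shell_radius``
    around the ion; the remaining in-cylinder waters are placed inside the
    axial cylinder (radius ``cylinder_radius``, |z - ion_z| <= z_extent) but
    at least ``shell_gap`` Å outside the shell; ``n_decoys`` extra waters sit
    just outside the cylinder to exercise the radial cutoff.
    """
    if shell_radius >= cylinder_radius:
        raise ValueError("shell_radius must be smaller than cylinder_radius")
    if n_first_shell > n_waters_in_cylinder:
        raise ValueError("n_first_shell cannot exceed n_waters_in_cylinder")
    rng = np.random.default_rng(seed)
    ion_pos = np.array([0.0, 0.0, ion_z])

    positions = []
    if n_first_shell:
        pts = _fibonacci_sphere(n_first_shell)
        from scipy.spatial.transform import Rotation
        pts = pts @ Rotation.random(random_state=rng).as_matrix().T
        positions.extend(ion_pos + shell_radius * pts)

    n_rest = n_waters_in_cylinder - n_first_shell
    excl = shell_radius + shell_gap
    placed = 0
    attempts = 0
    while placed < n_rest:
        attempts += 1
        if attempts > 10000 * max(n_rest, 1):
            raise ValueError("cannot pack the requested waters into the cylinder")
        r = cylinder_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        z = ion_z + rng.uniform(-z_extent, z_extent)
        p = np.array([r * math.cos(th), r * math.sin(th), z])
        if np.linalg.norm(p - ion_pos) <= excl:
            continue
        positions.append(p)
        placed += 1

    decoys = []
    for _ in range(n_decoys):
        r = rng.uniform(cylinder_radius + 0.5, cylinder_radius + 3.0)
        th = rng.uniform(0, 2 * math.pi)
        z = ion_z + rng.uniform(-z_extent, z_extent)
        decoys.append(np.array([r * math.cos(th), r * math.sin(th), z]))

    atoms = [AtomRecord(serial=1, name="K", element="K", resname="K",
                        resid=1, chain="I", xyz=ion_pos)]
    resid = 0
    for p in list(positions) + decoys:
        resid += 1
        atoms.append(AtomRecord(serial=len(atoms) + 1, name="O", element="O",
                                resname="HOH", resid=resid, chain="W", xyz=p))
    model = MolecularModel(atoms, title="solvation snapshot", source_format="synthetic")
    truth = {
        "ion_index": 0, "ion_z": float(ion_z),
        "n_in_cylinder": int(n_waters_in_cylinder),
        "n_first_shell": int(n_first_shell),
        "n_decoys": int(n_decoys),
        "cylinder_radius": float(cylinder_radius),
        "shell_radius": float(shell_radius),
        "z_extent": float(z_extent),
    }
    return model, truth


# ---------------------------------------------------------------------------
# Boltzmann-shaped activation (G-V) data
# ---------------------------------------------------------------------------

@dataclass
class GVCurve:
    """Normalized tail-current activation data: G/Gmax per voltage."""

    voltages: np.ndarray
    normalized_conductance: np.ndarray
    n_sweeps: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.normalized_conductance = np.asarray(self.normalized_conductance,
                                                 dtype=float)
        if len(self.voltages) != len(self.normalized_conductance):
            raise ValueError("voltages and normalized_conductance lengths differ")
        g = self.normalized_conductance
        if np.any(g < -0.05) or np.any(g > 1.05):
            raise ValueError("normalized conductance outside [-0.05, 1.05]")


#: Conditioning-pulse grid used by the activation protocol: -20..-110 mV, 10 mV steps.
DEFAULT_GV_VOLTAGES = tuple(range(-20, -111, -10))


def boltzmann(v, v_half, slope_k):
    """Single Boltzmann activation: G/Gmax = 1 / (1 + exp((V - V1/2)/k))."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / slope_k))


def generate_gv_data(v_half: float, slope_k: float,
                     voltages: Sequence[float] = DEFAULT_GV_VOLTAGES,
                     noise_sd: float = 0.0, seed: int = 0,
                     n_sweeps: int = 1) -> GVCurve:
    """Boltzmann-shaped G-V data with Gaussian noise, clipped to [-0.05, 1.05]."""
    if slope_k <= 0:
        raise ValueError("slope_k must be > 0")
    rng = np.random.default_rng(seed)
    v = np.asarray(voltages, dtype=float)
    g = boltzmann(v, v_half, slope_k)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, size=len(v))
    g = np.clip(g, -0.05, 1.05)
    return GVCurve(voltages=v, normalized_conductance=g, n_sweeps=n_sweeps,
                   meta={"true_v_half": v_half, "true_k": slope_k,
                         "noise_sd": noise_sd, "seed": seed})
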