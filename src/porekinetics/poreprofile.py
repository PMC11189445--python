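"""Inscribed-sphere pore-radius profiling along the channel axis.

At each slice z along the pore axis the profiler finds the largest sphere
centred in that plane that touches no atom: it maximises

    f(c) = min_i ( |c - x_i| - R_i )

over in-plane centres c, where R_i are per-atom van der Waals radii. The
maximisation uses simulated annealing seeded from the previous slice's
centre (the classic marching strategy of pore-profiling tools), followed by
a local simplex polish. Twice the radius at a constriction is the reported
gate diameter, i.e. the solvent-accessible-pathway convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import WATER_RESNAMES
from .model import BACKBONE_NAMES, MolecularModel, PoreFrame, select

__all__ = [
    "RadiusSet",
    "PoreProfile",
    "HOLE_SIMPLE_RADII",
    "BONDI_RADII",
    "assign_radii",
    "compute_profile",
    "gate_metrics",
]


@dataclass
class RadiusSet:
    """Van der Waals radii by element, with per-atom-name overrides."""

    by_element: dict[str, float]
    by_atom_name: dict[str, float] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self):
        for sym, r in {**self.by_element, **self.by_atom_name}.items():
            if not (0.2 < r < 3.0):
                raise ValueError(f"radius for {sym!r} out of range (0.2, 3.0): {r}")

    def lookup(self, element: str, atom_name: str) -> float | None:
        if atom_name.upper() in self.by_atom_name:
            return self.by_atom_name[atom_name.upper()]
        return self.by_element.get(element.upper())


#: The 'simple' radius set traditionally shipped with pore-profiling tools.
HOLE_SIMPLE_RADII = RadiusSet(
    by_element={"C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "P": 2.10, "H": 1.00},
    name="simple")

#: Bondi (1964) van der Waals radii — the documented alternative set.
BONDI_RADII = RadiusSet(
    by_element={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20},
    name="bondi")


@dataclass
class PoreProfile:
    """Radius and centre of the inscribed sphere on a uniform z grid."""

    z_grid: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray           # (n, 2) in-plane centre, pore-frame coords
    converged: np.ndarray           # bool per slice
    radius_set: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        steps = np.diff(self.z_grid)
        if len(steps) and not np.allclose(steps, steps[0], atol=1e-9):
            raise ValueError("z_grid must be uniform and ascending")

    def radius_at(self, z: float) -> float:
        return float(np.interp(z, self.z_grid, self.radius))

    def min_radius(self, z_window: tuple[float, float] | None = None
                   ) -> tuple[float, float]:
        """(z, radius) of the smallest converged radius, optionally windowed."""
        mask = self.converged.copy()
        if z_window is not None:
            mask &= (self.z_grid >= z_window[0]) & (self.z_grid <= z_window[1])
        if not mask.any():
            raise ValueError("no converged slices in the requested window")
        idx = np.flatnonzero(mask)[np.argmin(self.radius[mask])]
        return float(self.z_grid[idx]), float(self.radius[idx])


def assign_radii(model: MolecularModel, radius_set: RadiusSet = HOLE_SIMPLE_RADII,
                 exclude_solvent: bool = True) -> MolecularModel:
    """Populate per-atom vdW radii; optionally drop waters first.

    Raises if any retained atom resolves to no radius, naming the offenders.
    """
    atoms = []
    unresolved = []
    for a in model.atoms:
        if exclude_solvent and a.resname.upper() in WATER_RESNAMES:
            continue
        r = radius_set.lookup(a.element, a.name)
        if r is None:
            unresolved.append(f"{a.chain}/{a.resname}{a.resid}/{a.name} ({a.element})")
        else:
            atoms.append(replace(a, vdw_radius=r))
    if unresolved:
        raise ValueError(
            f"radius set {radius_set.name!r} cannot resolve: " + ", ".join(unresolved))
    if not atoms:
        raise ValueError("no atoms left after solvent exclusion")
    out = MolecularModel(atoms, title=model.title, source_format=model.source_format,
                         validate=False)
    return out


def _clearance(c_xy: np.ndarray, z: float, pts: np.ndarray, radii: np.ndarray) -> float:
    d = np.sqrt((pts[:, 0] - c_xy[0]) ** 2 + (pts[:, 1] - c_xy[1]) ** 2
                + (pts[:, 2] - z) ** 2)
    return float(np.min(d - radii))


def _anneal_slice(z: float, seed_xy: np.ndarray, pts: np.ndarray, radii: np.ndarray,
                  n_steps: int, start_T: float, cool_rate: float,
                  rng: np.random.Generator,
                  max_shift: float = 2.0) -> tuple[np.ndarray, float]:
    # the search is confined to within max_shift of the marching seed so the
    # probe cannot escape through the channel wall into bulk
    c = seed_xy.copy()
    f = _clearance(c, z, pts, radii)
    best_c, best_f = c.copy(), f
    T = start_T
    for _ in range(n_steps):
        prop = c + rng.normal(0.0, 0.2 + 0.5 * T, size=2)
        if np.linalg.norm(prop - seed_xy) > max_shift:
            T *= cool_rate
            continue
        fp = _clearance(prop, z, pts, radii)
        if fp > f or rng.uniform() < np.exp((fp - f) / max(T, 1e-9)):
            c, f = prop, fp
            if f > best_f:
                best_c, best_f = c.copy(), f
        T *= cool_rate
    res = minimize(lambda p: -_clearance(p, z, pts, radii), best_c,
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    if (-res.fun > best_f
            and np.linalg.norm(res.x - seed_xy) <= max_shift):
        best_c, best_f = res.x, -res.fun
    return best_c, best_f


def compute_profile(model: MolecularModel, frame: PoreFrame,
                    z_range: tuple[float, float], step: float = 0.25,
                    anneal: dict | None = None,
                    neighbor_cutoff: float = 15.0,
                    bulk_radius: float = 15.0) -> PoreProfile:
    """Inscribed-sphere radius profile over ``z_range`` in the pore frame.

    Marching proceeds outward from the gate plane (z = 0) in both
    directions, each slice's optimisation seeded from its neighbour's centre
    (the first from the frame axis). Slices with no atoms within
    ``neighbor_cutoff`` are reported at ``bulk_radius`` and flagged
    unconverged.

    ``anneal`` keys: n_steps (2000), start_T (1.0), cool_rate (0.995),
    seed (0); all echoed into ``meta``.
    """
    opts = {"n_steps": 2000, "start_T": 1.0, "cool_rate": 0.995, "seed": 0,
            "max_shift": 2.0}
    if anneal:
        opts.update(anneal)
    radii = np.array([a.vdw_radius if a.vdw_radius is not None else np.nan
                      for a in model.atoms])
    if np.isnan(radii).any():
        raise ValueError("model has atoms without vdw radii; run assign_radii first")
    pts = frame.to_frame(model.coords)  # columns: x, y, z (pore frame)

    z_lo, z_hi = z_range
    n_lo = int(np.ceil((0.0 - z_lo) / step))
    n_hi = int(np.ceil((z_hi - 0.0) / step))
    z_grid = np.arange(-n_lo, n_hi + 1) * step
    n = len(z_grid)
    radius = np.empty(n)
    centers = np.empty((n, 2))
    converged = np.ones(n, dtype=bool)
    rng = np.random.default_rng(opts["seed"])

    # march from the gate plane z = 0 when it lies in range, else from the
    # grid end nearest to it
    i0 = int(np.clip(n_lo, 0, n - 1))
    order = [i0]
    for d in range(1, max(i0, n - 1 - i0) + 1):
        if i0 + d < n:
            order.append(i0 + d)
        if i0 - d >= 0:
            order.append(i0 - d)

    seeds = {i0: np.zeros(2)}
    for idx in order:
        z = z_grid[idx]
        near = np.abs(pts[:, 2] - z) < neighbor_cutoff
        seed_xy = seeds.get(idx, np.zeros(2))
        if not near.any():
            radius[idx] = bulk_radius
            centers[idx] = seed_xy
            converged[idx] = False
        else:
            c, f = _anneal_slice(z, seed_xy, pts[near], radii[near],
                                 opts["n_steps"], opts["start_T"],
                                 opts["cool_rate"], rng, opts["max_shift"])
            if f > bulk_radius:
                radius[idx] = bulk_radius
                centers[idx] = c
                converged[idx] = False
            else:
                radius[idx] = max(f, 0.0)
                centers[idx] = c
        for nb in (idx + 1, idx - 1):
            if 0 <= nb < n and nb not in seeds:
                seeds[nb] = centers[idx]

    keep = (z_grid >= z_lo - 1e-9) & (z_grid <= z_hi + 1e-9)
    return PoreProfile(z_grid=z_grid[keep], radius=radius[keep],
                       center_xy=centers[keep], converged=converged[keep],
                       radius_set="", meta={"step": step, **opts})


def _sidechain_z(model: MolecularModel, frame: PoreFrame, resid: int) -> float | None:
    idx = [i for i, a in enumerate(model.atoms)
           if a.resid == resid and a.element.upper() != "H"
           and a.name.upper() not in BACKBONE_NAMES]
    if not idx:  # glycine or pseudo-atoms: fall back to all heavy atoms
        idx = [i for i, a in enumerate(model.atoms)
               if a.resid == resid and a.element.upper() != "H"]
    if not idx:
        return None
    z, _ = frame.project(model.coords[idx])
    return float(np.mean(z))


def gate_metrics(profile: PoreProfile, model: MolecularModel, frame: PoreFrame,
                 residues: Sequence[int], window: float = 2.0) -> dict:
    """Constriction diameter near each residue's side-chain position.

    For each residue the z position is the projected centroid of its
    side-chain heavy atoms; the diameter is twice the profile radius at the
    nearest local constriction within ``window`` Å of that z (the window
    minimum when no interior local minimum exists). Missing residues get a
    ``None`` marker rather than failing the whole call.
    """
    out = {}
    r = profile.radius
    interior_min = np.zeros(len(r), dtype=bool)
    if len(r) > 2:
        interior_min[1:-1] = (r[1:-1] <= r[:-2]) & (r[1:-1] <= r[2:])
        # grid boundaries count when they are one-sided minima
        interior_min[0] = r[0] <= r[1]
        interior_min[-1] = r[-1] <= r[-2]
    for resid in residues:
        z = _sidechain_z(model, frame, resid)
        if z is None:
            out[resid] = None
            continue
        in_win = np.abs(profile.z_grid - z) <= window
        if not in_win.any():
            out[resid] = None
            continue
        cand = in_win & interior_min & profile.converged
        if cand.any():
            idx_c = np.flatnonzero(cand)
            idx = idx_c[np.argmin(np.abs(profile.z_grid[idx_c] - z))]
        else:
            idx_w = np.flatnonzero(in_win)
            idx = idx_w[np.argmin(r[idx_w])]
        out[resid] = {"z": float(profile.z_grid[idx]),
                      "diameter": float(2.0 * r[idx])}
    return out
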