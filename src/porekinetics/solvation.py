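"""Axial free energy, hydration, coordination, and hydrogen-bond statistics.

The free-energy profile is a direct Boltzmann inversion of the binned ion
density along the pore axis, F(z) = -kT ln(rho(z)/rho_ref). Under an
applied field this is a field-tilted profile, not an equilibrium PMF; an
optional linear correction (q*V/span) can remove the tilt. Hydration is
counted as water oxygens inside an axial cylinder (default 12 Å radius),
coordination as water oxygens within a first-shell cutoff of the ion
(default 3.5 Å, near the first K+-O RDF minimum), and hydrogen bonds by the
common geometric criterion (donor-acceptor <= 3.5 Å, D-H···A >= 150°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import WATER_RESNAMES, kT as kT_of
from .model import MolecularModel, PoreFrame, Selection, select
from .traces import IonTrace

__all__ = [
    "DensityProfile",
    "FreeEnergyProfile",
    "HydrationProfile",
    "ion_density_profile",
    "pmf_from_density",
    "hydration_profile",
    "coordination_number",
    "hbond_stats",
]


@dataclass
class DensityProfile:
    """Binned in-cylinder ion density along z (masked bins are NaN)."""

    z_centers: np.ndarray
    density: np.ndarray        # counts / (bin volume * total samples)
    counts: np.ndarray
    radial_cutoff: float


@dataclass
class FreeEnergyProfile:
    """Axial free energy from Boltzmann-inverted ion density."""

    z_bins: np.ndarray
    F: np.ndarray              # kcal/mol, NaN where unsampled
    kT: float
    reference_window: tuple[float, float]
    tilt_corrected: bool = False


@dataclass
class HydrationProfile:
    """Mean water-oxygen count per axial bin inside the cylinder."""

    z_bins: np.ndarray
    mean_waters: np.ndarray
    cylinder_radius: float
    dry: np.ndarray = field(default=None)  # mean < 1 flags wetting/dewetting

    def __post_init__(self):
        if self.dry is None:
            self.dry = self.mean_waters < 1.0


def ion_density_profile(traces: Sequence[IonTrace], z_bins: np.ndarray,
                        radial_cutoff: float = 12.0) -> DensityProfile:
    """Bin in-cylinder ion samples along z, normalised to a density.

    ``z_bins`` are uniform bin edges. Bins with zero counts are masked
    (NaN density), never imputed.
    """
    z_bins = np.asarray(z_bins, dtype=float)
    widths = np.diff(z_bins)
    if len(widths) == 0 or not np.allclose(widths, widths[0]):
        raise ValueError("z_bins must be uniform bin edges")
    z_all = np.concatenate([tr.z for tr in traces])
    r_all = np.concatenate([tr.r_offset for tr in traces])
    if z_all.size == 0:
        raise ValueError("no samples in traces")
    sel = r_all <= radial_cutoff
    counts, _ = np.histogram(z_all[sel], bins=z_bins)
    total = counts.sum()
    centers = 0.5 * (z_bins[:-1] + z_bins[1:])
    if total == 0:
        density = np.full(len(counts), np.nan)
    else:
        vol = np.pi * radial_cutoff ** 2 * widths[0]
        density = counts / (vol * total)
        density[counts == 0] = np.nan
    return DensityProfile(z_centers=centers, density=density, counts=counts,
                          radial_cutoff=radial_cutoff)


def pmf_from_density(density: DensityProfile, kT: float = kT_of(),
                     reference_window: tuple[float, float] = (-30.0, -20.0),
                     tilt_correction: dict | None = None) -> FreeEnergyProfile:
    """F(z) = -kT ln(rho/rho_ref), zero-referenced over a window.

    ``tilt_correction`` (optional) removes the applied-field linear term
    before referencing: pass ``{"qv_kcal": q*V in kcal/mol, "span": Å}`` and
    optionally ``"z_ref"`` (default 0). The field force q*V/span along +z
    contributes a potential -q*V*(z - z_ref)/span to the tilted profile,
    which is subtracted (i.e. q*V*(z - z_ref)/span is added back). The
    profile is invariant to any positive scaling of the density, since the
    reference cancels it.
    """
    rho = density.density
    if np.all(np.isnan(rho)):
        raise ValueError("density is fully masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = -kT * np.log(rho)
    tilt = False
    if tilt_correction is not None:
        z_ref = tilt_correction.get("z_ref", 0.0)
        slope = tilt_correction["qv_kcal"] / tilt_correction["span"]
        F = F + slope * (density.z_centers - z_ref)
        tilt = True
    lo, hi = reference_window
    ref_mask = (density.z_centers >= lo) & (density.z_centers <= hi) & ~np.isnan(F)
    if not ref_mask.any():
        raise ValueError("reference window contains no sampled bins")
    F = F - np.nanmean(F[ref_mask])
    return FreeEnergyProfile(z_bins=density.z_centers, F=F, kT=kT,
                             reference_window=(lo, hi), tilt_corrected=tilt)


def _water_oxygen_indices(model: MolecularModel) -> np.ndarray:
    return np.array([i for i, a in enumerate(model.atoms)
                     if a.resname.upper() in WATER_RESNAMES
                     and a.element.upper() == "O"], dtype=int)


def hydration_profile(frames: Sequence[MolecularModel], frame: PoreFrame,
                      cylinder_radius: float = 12.0,
                      z_bins: np.ndarray | None = None) -> HydrationProfile:
    """Mean water-oxygen count per axial bin inside the pore cylinder.

    Waters are recognised by resname (HOH/WAT/TIP3/SOL conventions). Bins
    with mean < 1 are flagged dry, expressing transient wetting/dewetting.
    """
    if z_bins is None:
        z_bins = np.arange(-30.0, 30.1, 2.0)
    z_bins = np.asarray(z_bins, dtype=float)
    totals = np.zeros(len(z_bins) - 1)
    n_frames = 0
    warned = False
    for snap in frames:
        n_frames += 1
        widx = _water_oxygen_indices(snap)
        if len(widx) == 0:
            warned = True
            continue
        z, r = frame.project(snap.coords[widx])
        inside = r <= cylinder_radius
        counts, _ = np.histogram(z[inside], bins=z_bins)
        totals += counts
    if warned:
        warnings.warn("some frames contain no water oxygens; zero counts recorded")
    mean = totals / max(n_frames, 1)
    centers = 0.5 * (z_bins[:-1] + z_bins[1:])
    return HydrationProfile(z_bins=centers, mean_waters=mean,
                            cylinder_radius=cylinder_radius)


def coordination_number(frames: Sequence[MolecularModel], ion_expr: str = "element K",
                        shell_cutoff: float = 3.5, frame: PoreFrame | None = None,
                        z_bins: np.ndarray | None = None) -> dict:
    """First-shell water count per ion per frame, plus mean vs ion z.

    Returns ``per_frame`` (list of per-ion counts per frame), ``mean`` (the
    grand mean), and when a pore frame is given, ``z_centers``/``mean_vs_z``
    (mean coordination binned by the ion's axial position). The
    "waters lost" at a site is the bulk mean minus the site mean; see
    :func:`waters_lost`.
    """
    per_frame = []
    zs, ns = [], []
    for snap in frames:
        ions = select(snap, ion_expr)
        widx = _water_oxygen_indices(snap)
        counts = []
        wpos = snap.coords[widx] if len(widx) else np.empty((0, 3))
        for i in ions.indices:
            pos = snap.coords[i]
            n = int(np.sum(np.linalg.norm(wpos - pos, axis=1) <= shell_cutoff)) \
                if len(widx) else 0
            counts.append(n)
            if frame is not None:
                z, _ = frame.project(pos)
                zs.append(float(z))
                ns.append(n)
        per_frame.append(counts)
    flat = [c for fr in per_frame for c in fr]
    out = {"per_frame": per_frame,
           "mean": float(np.mean(flat)) if flat else np.nan}
    if frame is not None and zs:
        if z_bins is None:
            z_bins = np.arange(-30.0, 30.1, 2.0)
        z_bins = np.asarray(z_bins, dtype=float)
        zs, ns = np.array(zs), np.array(ns, dtype=float)
        sums, _ = np.histogram(zs, bins=z_bins, weights=ns)
        cnts, _ = np.histogram(zs, bins=z_bins)
        with np.errstate(invalid="ignore"):
            mean_vs_z = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out["z_centers"] = 0.5 * (z_bins[:-1] + z_bins[1:])
        out["mean_vs_z"] = mean_vs_z
    return out


def waters_lost(bulk_mean: float, site_mean: float) -> float:
    """Coordinating waters lost at a site relative to bulk."""
    return bulk_mean - site_mean


def _resolve_groups(model: MolecularModel, groups) -> list[Selection]:
    out = []
    for g in groups:
        out.append(g if isinstance(g, Selection) else select(model, g))
    return out


def hbond_stats(frames: Sequence[MolecularModel], donor_groups, acceptor_groups,
                d_cutoff: float = 3.5, angle_cutoff: float = 150.0,
                h_bond_max: float = 1.25) -> dict:
    """Mean hydrogen-bond count per group over frames.

    ``donor_groups``/``acceptor_groups`` are selection expressions (or
    resolved Selections) whose atoms are donor/acceptor heavy atoms. A bond
    exists iff the donor-acceptor heavy distance is <= ``d_cutoff`` and,
    when the donor carries hydrogens (any H within ``h_bond_max`` Å in the
    same residue), the best D-H···A angle is >= ``angle_cutoff``. Models
    without hydrogens fall back to the distance criterion with a warning.
    Each bond is credited to both partner groups, so a hydroxyl ring where
    every group donates one and accepts one averages 2.0 per group.

    Returns ``per_group_mean`` (list parallel to donor_groups + acceptor
    groups merged by identity) and ``mean_per_group`` (their average), plus
    the raw per-frame total.
    """
    if not frames:
        raise ValueError("no frames given")
    first = frames[0]
    donors = _resolve_groups(first, donor_groups)
    acceptors = _resolve_groups(first, acceptor_groups)

    group_keys = [g.expression for g in donors + acceptors]
    credit = {k: 0.0 for k in group_keys}
    totals = []
    warned_no_h = False

    for snap in frames:
        dsel = _resolve_groups(snap, [g.expression for g in donors])
        asel = _resolve_groups(snap, [g.expression for g in acceptors])
        coords = snap.coords
        h_idx = [i for i, a in enumerate(snap.atoms) if a.element.upper() == "H"]
        h_by_res = {}
        for i in h_idx:
            a = snap.atoms[i]
            h_by_res.setdefault((a.chain, a.resid), []).append(i)
        n_bonds_frame = 0
        for gi, ds in enumerate(dsel):
            for di in ds.indices:
                datom = snap.atoms[di]
                dh = [i for i in h_by_res.get((datom.chain, datom.resid), [])
                      if np.linalg.norm(coords[i] - coords[di]) <= h_bond_max]
                for gj, asel_j in enumerate(asel):
                    for ai in asel_j.indices:
                        aatom = snap.atoms[ai]
                        if ai == di or (aatom.chain == datom.chain
                                        and aatom.resid == datom.resid):
                            continue
                        dist = np.linalg.norm(coords[ai] - coords[di])
                        if dist > d_cutoff:
                            continue
                        if dh:
                            best = 0.0
                            for hi in dh:
                                v1 = coords[di] - coords[hi]
                                v2 = coords[ai] - coords[hi]
                                c = (v1 @ v2) / (np.linalg.norm(v1)
                                                 * np.linalg.norm(v2))
                                best = max(best,
                                           np.degrees(np.arccos(np.clip(c, -1, 1))))
                            if best < angle_cutoff:
                                continue
                        else:
                            warned_no_h = True
                        n_bonds_frame += 1
                        credit[group_keys[gi]] += 1.0
                        credit[group_keys[len(dsel) + gj]] += 1.0
        totals.append(n_bonds_frame)
    if warned_no_h:
        warnings.warn("donors without hydrogens: distance-only criterion used")
    n_frames = len(frames)
    per_group = {k: v / n_frames for k, v in credit.items()}
    return {"per_group_mean": per_group,
            "mean_per_group": float(np.mean(list(per_group.values()))),
            "total_per_frame": totals}
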