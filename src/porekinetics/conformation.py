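"""Superposition, RMSD/RMSF, helix bend, helicity, and charge displacement.

Trajectory frames are aligned by least-squares (Kabsch) superposition on a
stated backbone selection — by default the transmembrane-helix backbone
ranges used for the MD analyses (residues 140-166, 173-195, 209-242,
253-287, 297-324, 369-401) — before computing RMSD series and per-atom
RMSF. Helix axes come from the principal component of Cα coordinates;
helicity uses an explicit, configurable α-helix criterion combining the
i -> i+4 carbonyl-amide contact with backbone dihedral windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import TrajectoryEnsemble
from .model import MolecularModel, Selection, select

__all__ = [
    "SuperpositionResult",
    "HelixGeometry",
    "TM_BACKBONE_EXPR",
    "superpose_kabsch",
    "fluctuation_profiles",
    "helix_axes_and_bend",
    "helicity_profile",
    "charge_displacement",
]

#: Transmembrane-helix backbone ranges used to align MD trajectories.
TM_BACKBONE_EXPR = ("resid 140-166 173-195 209-242 253-287 297-324 369-401 "
                    "and backbone")


@dataclass
class SuperpositionResult:
    """Optimal rigid-body transform of mobile onto reference."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # Å
    rmsd: float               # Å, over the selection after transform
    selection_used: Selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class HelixGeometry:
    """Two helix-segment axes and the bend angle between them."""

    segment_a: tuple[int, int]
    segment_b: tuple[int, int]
    axis_a: np.ndarray
    axis_b: np.ndarray
    bend_angle: float          # degrees, in [0, 180]
    helical_mask: np.ndarray | None = None


def _pair_atoms(mobile: MolecularModel, reference: MolecularModel,
                expr: str) -> tuple[np.ndarray, np.ndarray]:
    sm = select(mobile, expr)
    sr = select(reference, expr)
    key_m = {(mobile.atoms[i].chain, mobile.atoms[i].resid, mobile.atoms[i].name): i
             for i in sm.indices}
    key_r = {(reference.atoms[i].chain, reference.atoms[i].resid,
              reference.atoms[i].name): i for i in sr.indices}
    shared = sorted(set(key_m) & set(key_r))
    only_m = set(key_m) - set(key_r)
    only_r = set(key_r) - set(key_m)
    if only_m or only_r:
        sample = list(only_m)[:5] + list(only_r)[:5]
        raise ValueError(
            f"selection pairs unequally: {len(only_m)} mobile-only and "
            f"{len(only_r)} reference-only atoms (e.g. {sample})")
    if not shared:
        raise ValueError(f"selection {expr!r} matches no paired atoms")
    mi = np.array([key_m[k] for k in shared])
    ri = np.array([key_r[k] for k in shared])
    return mi, ri


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    cm = mobile_xyz.mean(axis=0)
    cr = ref_xyz.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_xyz - cr, mobile_xyz - cm)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = rssd / np.sqrt(len(mobile_xyz))
    return R, t, float(rmsd)


def superpose_kabsch(mobile: MolecularModel, reference: MolecularModel,
                     selection_expr: str = TM_BACKBONE_EXPR) -> SuperpositionResult:
    """Least-squares optimal rigid superposition over a paired selection.

    Atoms are paired by (chain, resid, name); unmatched atoms raise a
    pairing error listing examples. Weights are uniform.
    """
    mi, ri = _pair_atoms(mobile, reference, selection_expr)
    R, t, rmsd = _kabsch(mobile.coords[mi], reference.coords[ri])
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               selection_used=Selection(selection_expr, mi))


def fluctuation_profiles(traj: TrajectoryEnsemble,
                         align_expr: str = TM_BACKBONE_EXPR,
                         measure_expr: str = "ca") -> dict:
    """Per-replica RMSD series and per-atom RMSF after alignment.

    Every frame is Kabsch-aligned to the topology reference on
    ``align_expr``; the RMSD series and RMSF are computed over
    ``measure_expr``. RMSF_i = sqrt(<|r_i - <r_i>|^2>). A chain-averaged
    RMSF maps symmetry-equivalent residues across chains by (resid, name)
    and reports mismatches instead of dropping them silently.
    """
    if traj.topology is None:
        raise ValueError("fluctuation profiles need a topology-bearing ensemble")
    top = traj.topology
    align_idx = select(top, align_expr).indices
    meas_idx = select(top, measure_expr).indices
    if len(align_idx) < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    ref = top.coords

    rmsd_series = []
    rmsf_list = []
    for rep in traj.replicas:
        n_frames = rep.shape[0]
        if n_frames < 2:
            warnings.warn("single-frame replica: RMSF is identically zero")
        aligned = np.empty((n_frames, len(meas_idx), 3))
        series = np.empty(n_frames)
        for f in range(n_frames):
            R, t, _ = _kabsch(rep[f][align_idx], ref[align_idx])
            moved = rep[f] @ R.T + t
            aligned[f] = moved[meas_idx]
            series[f] = np.sqrt(np.mean(np.sum((moved[meas_idx]
                                                - ref[meas_idx]) ** 2, axis=1)))
        mean_pos = aligned.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
        rmsd_series.append(series)
        rmsf_list.append(rmsf)
    rmsf_arr = np.mean(rmsf_list, axis=0)

    # chain averaging over symmetry-equivalent residues
    by_key: dict[tuple, list[float]] = {}
    for pos, i in enumerate(meas_idx):
        a = top.atoms[i]
        by_key.setdefault((a.resid, a.name), []).append(rmsf_arr[pos])
    n_chains = len(top.chains)
    mismatched = sorted(k for k, v in by_key.items()
                        if len(v) != n_chains and n_chains > 1)
    chain_avg = {k: float(np.mean(v)) for k, v in by_key.items()}
    return {
        "rmsd_series": rmsd_series,
        "time_ns": [np.arange(len(s)) * traj.frame_interval for s in rmsd_series],
        "rmsf": rmsf_arr,
        "rmsf_atoms": meas_idx,
        "rmsf_chain_averaged": chain_avg,
        "chain_average_mismatches": mismatched,
    }


def _segment_ca(model: MolecularModel, lo: int, hi: int) -> np.ndarray:
    idx = [i for i, a in enumerate(model.atoms)
           if a.name.upper() == "CA" and lo <= a.resid <= hi]
    return model.coords[idx]


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (pts[-1] - pts[0]) < 0:  # orient N -> C
        axis = -axis
    return axis


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Segment axis: principal component of one-turn-smoothed Cα positions.

    A 4-residue moving average (one helical turn is 3.6 residues) collapses
    the Cα spiral onto the helix axis before the principal-component fit;
    raw-Cα PCA carries a phase-dependent tilt of a few degrees for
    non-integer turn counts.
    """
    if len(ca) >= 6:
        kernel = np.ones(4) / 4.0
        sm = np.stack([np.convolve(ca[:, d], kernel, mode="valid")
                       for d in range(3)], axis=1)
    else:
        sm = ca
    axis = _principal_axis(sm)
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def helix_axes_and_bend(model: MolecularModel, segment_a: tuple[int, int],
                        segment_b: tuple[int, int]) -> HelixGeometry:
    """Bend angle between two helix segments (resid ranges, inclusive).

    Each segment axis is the principal component of its smoothed Cα
    coordinates, oriented N -> C; the bend is arccos(axis_a · axis_b). At
    least 5 Cα per segment are required for a well-defined axis.
    """
    pa = _segment_ca(model, *segment_a)
    pb = _segment_ca(model, *segment_b)
    if len(pa) < 5 or len(pb) < 5:
        raise ValueError("each segment needs >= 5 Cα atoms for a stable axis")
    axis_a = _helix_axis(pa)
    axis_b = _helix_axis(pb)
    angle = float(np.degrees(np.arccos(np.clip(axis_a @ axis_b, -1.0, 1.0))))
    return HelixGeometry(segment_a=tuple(segment_a), segment_b=tuple(segment_b),
                         axis_a=axis_a, axis_b=axis_b, bend_angle=angle)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


#: Dihedral windows defining the α-helical region of the Ramachandran map.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)


def helicity_profile(model: MolecularModel, residue_range: tuple[int, int],
                     chain: str | None = None, hbond_cutoff: float = 3.5,
                     phi_window: tuple[float, float] = PHI_WINDOW,
                     psi_window: tuple[float, float] = PSI_WINDOW) -> dict:
    """Per-residue helical assignment and contiguous non-helical runs.

    A residue is helical iff its available backbone dihedrals fall in the
    α-helical windows AND it participates in an i -> i+4 carbonyl-amide
    contact on either side (O(i)···N(i+4) or O(i-4)···N(i) within
    ``hbond_cutoff``); residues lacking both i±4 partners use the dihedral
    criterion alone. Residues with missing backbone atoms are marked
    indeterminate and excluded from runs. Run lengths are also reported in
    helical turns (length / 3.6).
    """
    lo, hi = residue_range
    chains = [chain] if chain else model.chains
    ch = chains[0]
    bb: dict[int, dict[str, np.ndarray]] = {}
    for i, a in enumerate(model.atoms):
        if a.chain == ch and lo <= a.resid <= hi and a.name.upper() in \
                ("N", "CA", "C", "O"):
            bb.setdefault(a.resid, {})[a.name.upper()] = model.coords[i]

    resids = list(range(lo, hi + 1))
    status: dict[int, str] = {}
    for r in resids:
        atoms = bb.get(r)
        if not atoms or any(n not in atoms for n in ("N", "CA", "C")):
            status[r] = "indeterminate"
            continue
        prev_c = bb.get(r - 1, {}).get("C")
        next_n = bb.get(r + 1, {}).get("N")
        checks = []
        if prev_c is not None:
            phi = _dihedral(prev_c, atoms["N"], atoms["CA"], atoms["C"])
            checks.append(phi_window[0] <= phi <= phi_window[1])
        if next_n is not None:
            psi = _dihedral(atoms["N"], atoms["CA"], atoms["C"], next_n)
            checks.append(psi_window[0] <= psi <= psi_window[1])
        if not checks:
            status[r] = "indeterminate"
            continue
        dihedral_ok = all(checks)

        hbond_checks = []
        o_i = atoms.get("O")
        n_fwd = bb.get(r + 4, {}).get("N")
        if o_i is not None and n_fwd is not None:
            hbond_checks.append(np.linalg.norm(n_fwd - o_i) <= hbond_cutoff)
        o_back = bb.get(r - 4, {}).get("O")
        if o_back is not None:
            hbond_checks.append(np.linalg.norm(atoms["N"] - o_back) <= hbond_cutoff)
        hbond_ok = any(hbond_checks) if hbond_checks else True

        status[r] = "helical" if (dihedral_ok and hbond_ok) else "non-helical"

    runs = []
    run_start = None
    for r in resids + [hi + 1]:
        if r <= hi and status.get(r) == "non-helical":
            if run_start is None:
                run_start = r
        else:
            if run_start is not None:
                length = r - run_start
                runs.append({"start": run_start, "end": r - 1, "length": length,
                             "turns": length / 3.6})
                run_start = None
    return {"status": status, "runs": runs,
            "helical_mask": np.array([status[r] == "helical" for r in resids])}


def charge_displacement(model_a: MolecularModel, model_b: MolecularModel,
                        labeled_positions: Sequence[tuple],
                        align_expr: str) -> dict:
    """Displacement of labelled atoms between two states after superposition.

    ``labeled_positions`` entries are (label, resid, atom_name) or
    (label, resid, atom_name, chain); model_b is superposed onto model_a on
    ``align_expr`` and each labelled atom's displacement vector and |Δ| are
    measured in model_a's frame. Missing atoms get a ``None`` marker.
    """
    sup = superpose_kabsch(model_b, model_a, align_expr)

    def find(model, resid, name, chain):
        for i, a in enumerate(model.atoms):
            if a.resid == resid and a.name.upper() == name.upper() and \
                    (chain is None or a.chain == chain):
                return i
        return None

    out = {}
    for entry in labeled_positions:
        label, resid, name = entry[0], entry[1], entry[2]
        chain = entry[3] if len(entry) > 3 else None
        ia = find(model_a, resid, name, chain)
        ib = find(model_b, resid, name, chain)
        if ia is None or ib is None:
            out[label] = None
            continue
        moved = sup.apply(model_b.coords[ib])
        delta = moved - model_a.coords[ia]
        out[label] = {"vector": delta, "magnitude": float(np.linalg.norm(delta))}
    return out
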