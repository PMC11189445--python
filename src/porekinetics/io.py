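"""Structure and trajectory input/output.

Structures are read with gemmi (PDB and mmCIF); multi-frame trajectories
(DCD/XTC/GRO) are decoded with MDAnalysis. A plain-text ion-trace TSV
dialect is supported for topology-free permeation analysis:

    time_ns<TAB>ion_id<TAB>x<TAB>y<TAB>z

one row per ion per frame, floats with at least 6 significant digits,
sorted by (time_ns, ion_id). x/y/z are pore-frame coordinates in Å.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AtomRecord, MolecularModel
from .traces import IonTrace, IonTraceSet

__all__ = [
    "TrajectoryEnsemble",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "read_ion_traces",
    "write_ion_traces",
]

ION_TRACE_HEADER = ["time_ns", "ion_id", "x", "y", "z"]


@dataclass
class TrajectoryEnsemble:
    """Replicated trajectory frames sharing one topology.

    ``replicas[i]`` is an (n_frames, n_atoms, 3) coordinate array in Å and
    ``box[i]`` the per-frame orthorhombic box lengths. For ion-trace TSV
    input there is no topology; the parsed traces live in ``ion_traces``.
    """

    replicas: list[np.ndarray] = field(default_factory=list)
    frame_interval: float = 1.0  # ns
    box: list[np.ndarray] = field(default_factory=list)
    topology: MolecularModel | None = None
    ion_traces: list[IonTraceSet] | None = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.topology is not None:
            n = len(self.topology)
            for i, rep in enumerate(self.replicas):
                if rep.shape[1] != n:
                    raise ValueError(
                        f"replica {i} has {rep.shape[1]} atoms, topology has {n}")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas) if self.replicas else len(self.ion_traces or [])

    def frame_model(self, replica: int, frame: int) -> MolecularModel:
        """The topology with the coordinates of one frame."""
        if self.topology is None:
            raise ValueError("ensemble has no topology")
        return self.topology.with_coords(self.replicas[replica][frame])


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _gemmi_format(fmt: str):
    import gemmi
    return {"PDB": gemmi.CoorFormat.Pdb,
            "mmCIF": gemmi.CoorFormat.Mmcif,
            "auto": gemmi.CoorFormat.Detect}[fmt]


def read_structure(path: str | os.PathLike, format: str = "auto") -> MolecularModel:
    """Read a PDB or mmCIF file into a :class:`MolecularModel`.

    Alternate conformers are collapsed to the highest-occupancy one (ties go
    to the first listed). Waters and ligands are retained; exclude them later
    with selections such as ``"not water"``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_gemmi_format(format))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models in file")
    gm = st[0]

    records: list[AtomRecord] = []
    best: dict[tuple, int] = {}   # (chain, resid, name) -> index into records
    serial = 0
    for chain in gm:
        for res in chain:
            for atom in res:
                serial += 1
                elem = atom.element.name.strip()
                if not elem:
                    elem = _infer_element(atom.name)
                rec = AtomRecord(
                    serial=serial, name=atom.name.strip(), element=elem,
                    resname=res.name.strip(), resid=res.seqid.num,
                    chain=chain.name, xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ, bfactor=atom.b_iso)
                key = (rec.chain, rec.resid, rec.name)
                if key in best:
                    prev = records[best[key]]
                    if rec.occupancy > prev.occupancy:  # tie keeps first listed
                        records[best[key]] = rec
                else:
                    best[key] = len(records)
                    records.append(rec)
    if not records:
        raise ValueError(f"{path.name}: file contains zero atoms")
    fmt = format
    if fmt == "auto":
        fmt = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    return MolecularModel(records, title=st.name or path.stem, source_format=fmt)


def _infer_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        raise ValueError("cannot infer element from empty atom name")
    lead = stripped.lstrip("0123456789")
    if len(lead) >= 2 and lead[:2].upper() in ("CL", "NA", "MG", "ZN", "FE", "BR", "SE"):
        return lead[:2].capitalize()
    return lead[0].upper()


def write_structure(model: MolecularModel, path: str | os.PathLike,
                    format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (by extension when ``format='auto'``)."""
    import gemmi

    path = Path(path)
    if format == "auto":
        format = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"

    st = gemmi.Structure()
    st.name = model.title or "model"
    gm = gemmi.Model("1")
    chains: dict[str, "gemmi.Chain"] = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        chain = chains[a.chain]
        if len(chain) == 0 or chain[-1].seqid.num != a.resid or chain[-1].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        atom.occ = a.occupancy
        atom.b_iso = a.bfactor
        res.add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    if format == "PDB":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(paths: Sequence[str | os.PathLike],
                    topology: MolecularModel | None = None,
                    frame_interval: float = 1.0) -> TrajectoryEnsemble:
    """Read replica trajectories into an ensemble.

    Each path is one replica. Coordinate formats (DCD/XTC/GRO/multi-model
    PDB) are decoded with MDAnalysis against ``topology``; ``.tsv`` paths are
    parsed as the ion-trace dialect and need no topology. Mixed formats
    across replicas are allowed, mixed atom counts are not.
    """
    paths = [Path(p) for p in paths]
    if all(p.suffix.lower() == ".tsv" for p in paths):
        sets = [read_ion_traces(p) for p in paths]
        return TrajectoryEnsemble(frame_interval=frame_interval, ion_traces=sets)
    if topology is None:
        raise ValueError("a topology model is required for coordinate trajectories")

    import MDAnalysis as mda

    replicas, boxes = [], []
    with tempfile.TemporaryDirectory() as tmp:
        top_pdb = Path(tmp) / "topology.pdb"
        write_structure(topology, top_pdb, format="PDB")
        for p in paths:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(top_pdb), str(p))
            if len(u.atoms) != len(topology):
                raise ValueError(
                    f"{p.name}: {len(u.atoms)} atoms, topology has {len(topology)}")
            frames, dims = [], []
            for ts in u.trajectory:
                frames.append(ts.positions.astype(float).copy())
                dims.append(np.array(ts.dimensions[:3], dtype=float)
                            if ts.dimensions is not None else np.zeros(3))
            replicas.append(np.array(frames))
            boxes.append(np.array(dims))
    return TrajectoryEnsemble(replicas=replicas, frame_interval=frame_interval,
                              box=boxes, topology=topology)


# ---------------------------------------------------------------------------
# Ion-trace TSV dialect
# ---------------------------------------------------------------------------

def read_ion_traces(path: str | os.PathLike) -> IonTraceSet:
    """Read the ion-trace TSV dialect into an :class:`IonTraceSet`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ION_TRACE_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing ion-trace columns {missing}")
    traces = []
    for ion_id, g in df.groupby("ion_id", sort=True):
        g = g.sort_values("time_ns")
        r = np.hypot(g["x"].to_numpy(float), g["y"].to_numpy(float))
        traces.append(IonTrace(ion_id=str(ion_id), t=g["time_ns"].to_numpy(float),
                               z=g["z"].to_numpy(float), r_offset=r))
    duration = float(df["time_ns"].max() - df["time_ns"].min()) if len(df) else None
    return IonTraceSet(traces=traces, duration=duration)


def write_ion_traces(trace_set: IonTraceSet, path: str | os.PathLike,
                     xy: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                     header_comments: Sequence[str] = ()) -> None:
    """Write traces in the ion-trace TSV dialect (deterministic formatting).

    ``xy`` optionally maps ion_id to explicit (x, y) arrays; otherwise x is
    the radial offset and y is zero, preserving r on round-trip.
    """
    rows = []
    for tr in trace_set:
        if xy and tr.ion_id in xy:
            x, y = xy[tr.ion_id]
        else:
            x, y = tr.r_offset, np.zeros_like(tr.r_offset)
        for i in range(len(tr)):
            rows.append((tr.t[i], tr.ion_id, x[i], y[i], tr.z[i]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(ION_TRACE_HEADER) + "\n")
        for t, ion, x, y, z in rows:
            fh.write(f"{t:.8g}\t{ion}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")
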