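"""In-memory molecular model, atom-selection grammar, and the pore-aligned frame.

The pore frame anchors Z = 0 at the mass-weighted centre of the
bundle-crossing lower gate (S6 residues 394-398 in HCN1 author numbering)
with +z pointing toward the selectivity filter, i.e. the extracellular side.
All downstream analyses (pore profile, ion projection, PMF, hydration) work
in this frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, PROTEIN_RESNAMES, WATER_RESNAMES

__all__ = [
    "AtomRecord",
    "MolecularModel",
    "Selection",
    "PoreFrame",
    "SelectionSyntaxError",
    "select",
    "build_pore_frame",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class AtomRecord:
    """One atom of a structural model, author numbering preserved."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    vdw_radius: float | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: xyz must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")


class MolecularModel:
    """An ordered collection of atoms from one structure or snapshot.

    Parameters
    ----------
    atoms
        Ordered atom records. ``(chain, resid, name)`` must be unique.
    title
        Free-text label carried into outputs.
    source_format
        One of ``{"PDB", "mmCIF", "synthetic"}``.
    """

    def __init__(self, atoms: Sequence[AtomRecord], title: str = "",
                 source_format: str = "synthetic", validate: bool = True):
        if len(atoms) == 0:
            raise ValueError("model must contain at least one atom")
        self.atoms = list(atoms)
        self.title = title
        self.source_format = source_format
        if validate:
            seen = set()
            for a in self.atoms:
                key = (a.chain, a.resid, a.name)
                if key in seen:
                    raise ValueError(f"duplicate atom (chain,resid,name)={key}")
                seen.add(key)
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (a live view is not guaranteed)."""
        if self._coords is None or self._coords.shape[0] != len(self.atoms):
            self._coords = np.array([a.xyz for a in self.atoms], dtype=float)
        return self._coords

    def with_coords(self, coords: np.ndarray) -> "MolecularModel":
        """A copy of this model with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularModel(atoms, title=self.title,
                              source_format=self.source_format, validate=False)

    def subset(self, indices: Iterable[int], title: str | None = None) -> "MolecularModel":
        idx = list(indices)
        return MolecularModel([self.atoms[i] for i in idx],
                              title=title if title is not None else self.title,
                              source_format=self.source_format, validate=False)

    def masses(self) -> np.ndarray:
        """Standard atomic masses per atom (unknown elements get 12.0)."""
        return np.array([ATOMIC_MASSES.get(a.element.upper(), 12.0) for a in self.atoms])

    @property
    def chains(self) -> list[str]:
        out, seen = [], set()
        for a in self.atoms:
            if a.chain not in seen:
                seen.add(a.chain)
                out.append(a.chain)
        return out


@dataclass
class Selection:
    """A resolved atom selection: the expression and the matched indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Selection grammar.
#
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | primitive
#   primitive:= "resid" range+ | "name" WORD+ | "chain" WORD+
#             | "resname" WORD+ | "element" WORD+
#             | "heavy" | "backbone" | "ca"/"calpha" | "water" | "protein" | "all"
#   range    := INT | INT "-" INT
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")
_KEYWORDS = {"resid", "name", "chain", "resname", "element",
             "heavy", "backbone", "ca", "calpha", "water", "protein", "all",
             "and", "or", "not", "(", ")"}
_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, expression: str, model: MolecularModel):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.i = 0
        self.model = model
        self.n = len(model)

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self):
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expression)

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}", self.pos())
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("expression ends unexpectedly", self.pos())
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionSyntaxError("missing closing parenthesis", self.pos())
            self.next()
            return mask
        return self.primitive()

    def _arguments(self) -> list[str]:
        args = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS:
                break
            args.append(self.next()[0])
        return args

    def primitive(self) -> np.ndarray:
        tok, pos = self.next()
        atoms = self.model.atoms
        if tok == "resid":
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError("'resid' requires at least one number or range", pos)
            mask = np.zeros(self.n, dtype=bool)
            for arg in args:
                m = _RANGE_RE.match(arg)
                if not m:
                    raise SelectionSyntaxError(f"bad resid range {arg!r}", pos)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    warnings.warn(f"degenerate resid range {arg!r} selects nothing")
                mask |= np.array([lo <= a.resid <= hi for a in atoms])
            return mask
        if tok == "name":
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError("'name' requires at least one atom name", pos)
            names = {a.upper() for a in args}
            return np.array([a.name.upper() in names for a in atoms])
        if tok == "chain":
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError("'chain' requires at least one chain id", pos)
            known = set(self.model.chains)
            for c in args:
                if c not in known:
                    warnings.warn(f"unknown chain {c!r}: empty subselection")
            chains = set(args)
            return np.array([a.chain in chains for a in atoms])
        if tok == "resname":
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError("'resname' requires at least one residue name", pos)
            names = {a.upper() for a in args}
            return np.array([a.resname.upper() in names for a in atoms])
        if tok == "element":
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError("'element' requires at least one symbol", pos)
            elems = {a.upper() for a in args}
            return np.array([a.element.upper() in elems for a in atoms])
        if tok == "heavy":
            return np.array([a.element.upper() != "H" for a in atoms])
        if tok == "backbone":
            return np.array([a.name.upper() in BACKBONE_NAMES for a in atoms])
        if tok in ("ca", "calpha"):
            return np.array([a.name.upper() == "CA" and a.element.upper() == "C"
                             for a in atoms])
        if tok == "water":
            return np.array([a.resname.upper() in WATER_RESNAMES for a in atoms])
        if tok == "protein":
            return np.array([a.resname.upper() in PROTEIN_RESNAMES for a in atoms])
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        raise SelectionSyntaxError(f"unknown token {tok!r}", pos)


def select(model: MolecularModel, expression: str) -> Selection:
    """Resolve a selection expression against a model.

    The grammar supports ``resid`` ranges, ``name``/``chain``/``resname``/
    ``element`` lists, the keywords ``heavy``, ``backbone``, ``ca``,
    ``water``, ``protein``, ``all``, and the boolean operators
    ``and``/``or``/``not`` with parentheses. Resolution is deterministic and
    order-preserving (indices ascend in file order); empty selections are
    allowed but trigger a warning.
    """
    mask = _Parser(expression, model).parse()
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(expression=expression, indices=indices)


@dataclass
class PoreFrame:
    """Pore-aligned reference frame: origin at the gate COM, +z extracellular."""

    origin: np.ndarray
    axis: np.ndarray
    gate_selection: Selection | None = None
    filter_selection: Selection | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-9:
            self.axis = self.axis / norm

    def project(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate z and radial offset r for points (…, 3) in Å."""
        rel = np.asarray(xyz, dtype=float) - self.origin
        z = rel @ self.axis
        perp = rel - np.multiply.outer(z, self.axis)
        return z, np.linalg.norm(perp, axis=-1)

    def basis(self) -> np.ndarray:
        """Orthonormal 3x3 basis whose last row is the pore axis."""
        a = self.axis
        seed = np.array([1.0, 0.0, 0.0])
        if abs(a @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ a) * a
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return np.vstack([e1, e2, a])

    def to_frame(self, xyz: np.ndarray) -> np.ndarray:
        """Full (x, y, z) coordinates in the pore frame."""
        return (np.asarray(xyz, dtype=float) - self.origin) @ self.basis().T


def _mass_centroid(model: MolecularModel, indices: np.ndarray) -> np.ndarray:
    m = model.masses()[indices]
    return (model.coords[indices] * m[:, None]).sum(axis=0) / m.sum()


def build_pore_frame(model: MolecularModel,
                     gate_expr: str = "resid 394-398 and heavy",
                     filter_expr: str = "resid 358-361 and heavy",
                     axis_agreement_deg: float = 5.0) -> PoreFrame:
    """Build the pore frame from gate and selectivity-filter selections.

    The origin is the mass-weighted centroid of the gate selection (Z = 0);
    the axis is the unit vector from there to the filter-selection centroid,
    so +z points extracellular. For near-symmetric models the axis is
    cross-checked against the principal axis of the combined selection and a
    warning is raised if the two disagree by more than
    ``axis_agreement_deg`` degrees.
    """
    gate = select(model, gate_expr)
    filt = select(model, filter_expr)
    if len(gate) == 0 or len(filt) == 0:
        raise ValueError("gate and filter selections must both be non-empty")
    origin = _mass_centroid(model, gate.indices)
    filter_centroid = _mass_centroid(model, filt.indices)
    delta = filter_centroid - origin
    dist = np.linalg.norm(delta)
    if dist < 1.0:
        raise ValueError(
            f"degenerate pore axis: gate and filter centroids {dist:.2f} Å apart")
    axis = delta / dist

    combined = np.concatenate([gate.indices, filt.indices])
    pts = model.coords[combined] - model.coords[combined].mean(axis=0)
    # principal axis of the combined selection; sign chosen toward the filter
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    principal = vt[0]
    if principal @ axis < 0:
        principal = -principal
    angle = np.degrees(np.arccos(np.clip(principal @ axis, -1.0, 1.0)))
    if angle > axis_agreement_deg:
        warnings.warn(
            f"pore axis and principal axis of gate+filter disagree by {angle:.1f}°")
    return PoreFrame(origin=origin, axis=axis,
                     gate_selection=gate, filter_selection=filt)
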