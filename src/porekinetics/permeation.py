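"""Ion-permeation event counting and single-channel conductance.

A permeation event is one complete traversal of the membrane-spanning pore:
an ion must cross from one outer compartment (above the upper threshold)
through the pore region to the other (below the lower threshold). The
counter is a three-compartment state machine with hysteresis so that
sub-threshold rattling never creates spurious events. Counts convert to
conductance as g = N*e / (T*|V|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import E_CHARGE
from .io import TrajectoryEnsemble
from .model import PoreFrame, select
from .traces import IonTrace, IonTraceSet

__all__ = [
    "PermeationEvent",
    "ConductanceEstimate",
    "project_ions",
    "detect_events",
    "estimate_conductance",
    "trace_statistics",
]

#: Default compartment thresholds, Å: approximate membrane interfaces.
DEFAULT_UPPER_Z = 18.0
DEFAULT_LOWER_Z = -18.0
DEFAULT_HYSTERESIS = 2.0


@dataclass
class PermeationEvent:
    """One complete traversal of the pore by one ion."""

    ion_id: str
    t_enter: float  # ns, first sample inside the pore compartment
    t_exit: float   # ns, first sample in the opposite outer compartment
    direction: str  # "inward" (+z -> -z) or "outward"

    def __post_init__(self):
        if self.t_exit <= self.t_enter:
            raise ValueError("t_exit must be > t_enter")
        if self.direction not in ("inward", "outward"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class ConductanceEstimate:
    """Per-replica event counts converted to conductance with spread."""

    events_per_replica: list[int]
    duration: float          # ns
    voltage: float           # mV
    g_per_replica: np.ndarray  # pS
    g_mean: float            # pS
    g_spread: float          # pS
    spread_convention: str   # population_sd | sample_sd | sem


def project_ions(traj: TrajectoryEnsemble, frame: PoreFrame | None = None,
                 species: str = "element K") -> list[IonTraceSet]:
    """Project ion coordinates of every replica into the pore frame.

    For topology-bearing ensembles the gate/filter frame is rebuilt per
    frame (the channel COM drifts), the projected z is unwrapped per ion
    across periodic images, and r_offset is the perpendicular distance to
    the axis. Ion-trace TSV ensembles are already in frame coordinates and
    pass through unchanged.
    """
    if traj.ion_traces is not None:
        return traj.ion_traces
    if traj.topology is None:
        raise ValueError("ensemble has neither topology nor parsed ion traces")
    if frame is None:
        raise ValueError("a PoreFrame is required for coordinate trajectories")
    ions = select(traj.topology, species)
    if len(ions) == 0:
        raise ValueError(f"species selection {species!r} matched no atoms")
    gate_idx = frame.gate_selection.indices if frame.gate_selection is not None else None
    filt_idx = (frame.filter_selection.indices
                if frame.filter_selection is not None else None)
    masses = traj.topology.masses()

    out = []
    for r, rep in enumerate(traj.replicas):
        n_frames = rep.shape[0]
        z = np.empty((n_frames, len(ions)))
        roff = np.empty((n_frames, len(ions)))
        box_z = traj.box[r][:, 2] if len(traj.box) > r and traj.box[r].size else None
        for f in range(n_frames):
            coords = rep[f]
            if gate_idx is not None and filt_idx is not None:
                mg = masses[gate_idx]
                origin = (coords[gate_idx] * mg[:, None]).sum(0) / mg.sum()
                mf = masses[filt_idx]
                fc = (coords[filt_idx] * mf[:, None]).sum(0) / mf.sum()
                axis = fc - origin
                axis = axis / np.linalg.norm(axis)
                fr = PoreFrame(origin=origin, axis=axis)
            else:
                fr = frame
            zz, rr_ = fr.project(coords[ions.indices])
            z[f], roff[f] = zz, rr_
        # unwrap projected z per ion across periodic images
        if box_z is not None and np.all(box_z > 0):
            dz = np.diff(z, axis=0)
            L = box_z[1:, None]
            jumps = np.round(dz / L)
            z[1:] -= np.cumsum(jumps * L, axis=0)
        t = np.arange(n_frames) * traj.frame_interval
        traces = [IonTrace(ion_id=f"ion{ions.indices[i] + 1}", t=t.copy(),
                           z=z[:, i].copy(), r_offset=roff[:, i].copy())
                  for i in range(len(ions))]
        out.append(IonTraceSet(traces=traces,
                               duration=(n_frames - 1) * traj.frame_interval))
    return out


_ABOVE, _PORE, _BELOW = 1, 0, -1


def detect_events(traces: Sequence[IonTrace],
                  upper_gate_z: float = DEFAULT_UPPER_Z,
                  lower_gate_z: float = DEFAULT_LOWER_Z,
                  hysteresis: float = DEFAULT_HYSTERESIS) -> list[PermeationEvent]:
    """Count complete permeation events with a hysteretic state machine.

    An ion leaves an outer compartment only by crossing the threshold offset
    inward by ``hysteresis``; an event is recorded on the first sample in
    the opposite outer compartment. Re-entries that return to the same side
    count nothing; traversals still in progress at the trace end are
    discarded. Direction "inward" is +z -> -z (extracellular to
    intracellular under hyperpolarisation).
    """
    if upper_gate_z <= lower_gate_z:
        raise ValueError("upper_gate_z must exceed lower_gate_z")
    if hysteresis < 0:
        raise ValueError("hysteresis must be >= 0")
    enter_from_above = upper_gate_z - hysteresis
    enter_from_below = lower_gate_z + hysteresis

    all_z = [tr.z for tr in traces if len(tr)]
    if all_z:
        zmin = min(z.min() for z in all_z)
        zmax = max(z.max() for z in all_z)
        if zmax < upper_gate_z or zmin > lower_gate_z:
            warnings.warn("a compartment threshold lies outside the sampled z "
                          "range; complete traversals cannot be observed there")

    events: list[PermeationEvent] = []
    for tr in traces:
        state = None
        entry_side = None
        t_enter = None
        for t, z in zip(tr.t, tr.z):
            if state is None:
                state = _ABOVE if z > upper_gate_z else (_BELOW if z < lower_gate_z
                                                         else _PORE)
                continue
            if state == _ABOVE:
                if z < lower_gate_z:       # skipped through in one step
                    state = _BELOW
                    if entry_side == _ABOVE and t_enter is not None:
                        events.append(PermeationEvent(tr.ion_id, t_enter, t, "inward"))
                    entry_side, t_enter = None, None
                elif z < enter_from_above:
                    state, entry_side, t_enter = _PORE, _ABOVE, t
            elif state == _BELOW:
                if z > upper_gate_z:
                    state = _ABOVE
                    if entry_side == _BELOW and t_enter is not None:
                        events.append(PermeationEvent(tr.ion_id, t_enter, t, "outward"))
                    entry_side, t_enter = None, None
                elif z > enter_from_below:
                    state, entry_side, t_enter = _PORE, _BELOW, t
            else:  # in the pore
                if z > upper_gate_z:
                    if entry_side == _BELOW and t_enter is not None:
                        events.append(PermeationEvent(tr.ion_id, t_enter, t, "outward"))
                    state, entry_side, t_enter = _ABOVE, None, None
                elif z < lower_gate_z:
                    if entry_side == _ABOVE and t_enter is not None:
                        events.append(PermeationEvent(tr.ion_id, t_enter, t, "inward"))
                    state, entry_side, t_enter = _BELOW, None, None
    return events


def net_crossings(traces: Sequence[IonTrace], domain_length: float,
                  upper_gate_z: float = DEFAULT_UPPER_Z,
                  lower_gate_z: float = DEFAULT_LOWER_Z,
                  hysteresis: float = DEFAULT_HYSTERESIS) -> list[int]:
    """Signed complete crossings per ion for periodic-domain traces.

    Unwrapped traces are folded back into ``[-L/2, L/2)`` and run through
    :func:`detect_events`; outward (+z) traversals count +1, inward -1.
    The outer compartments should be several step-displacements thick,
    otherwise traversals that jump the periodic boundary in one sample are
    missed.
    """
    L = domain_length
    out = []
    for tr in traces:
        zw = (tr.z + L / 2) % L - L / 2
        ev = detect_events([IonTrace(tr.ion_id, tr.t, zw, tr.r_offset)],
                           upper_gate_z, lower_gate_z, hysteresis)
        out.append(sum(1 if e.direction == "outward" else -1 for e in ev))
    return out


def conductance_pS(n_events: float, duration_ns: float, voltage_mv: float) -> float:
    """g = N*e / (T*|V|) in picosiemens."""
    return n_events * E_CHARGE / (duration_ns * 1e-9 * abs(voltage_mv) * 1e-3) * 1e12


def estimate_conductance(events_per_replica: Sequence[int], duration: float,
                         voltage: float,
                         spread_convention: str = "population_sd"
                         ) -> ConductanceEstimate:
    """Convert per-replica event counts to single-channel conductance.

    The printed-style summary is the arithmetic mean of per-replica
    conductances with, by default, the population standard deviation as the
    spread (for counts {5, 4, 6} over 500 ns at 500 mV this gives
    3.20 ± 0.52 pS); ``sample_sd`` and ``sem`` are available.
    """
    if len(events_per_replica) == 0:
        raise ValueError("events_per_replica must be non-empty")
    if duration <= 0 or voltage == 0:
        raise ValueError("duration must be > 0 and voltage non-zero")
    g = np.array([conductance_pS(n, duration, voltage) for n in events_per_replica])
    if spread_convention == "population_sd":
        spread = float(np.std(g, ddof=0))
    elif spread_convention == "sample_sd":
        spread = float(np.std(g, ddof=1)) if len(g) > 1 else 0.0
    elif spread_convention == "sem":
        spread = (float(np.std(g, ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0)
    else:
        raise ValueError(f"unknown spread convention {spread_convention!r}")
    return ConductanceEstimate(
        events_per_replica=list(events_per_replica), duration=duration,
        voltage=voltage, g_per_replica=g, g_mean=float(np.mean(g)),
        g_spread=spread, spread_convention=spread_convention)


def trace_statistics(traces: Sequence[IonTrace],
                     filter_window: tuple[float, float],
                     pause_site_z: float, pause_radius: float = 2.0,
                     offset_cutoff: float = 2.0,
                     pore_window: tuple[float, float] = (DEFAULT_LOWER_Z,
                                                         DEFAULT_UPPER_Z),
                     offset_zbin: float = 2.0) -> dict:
    """Dwell, occupancy, and axial-offset statistics for a trace set.

    Returns a dict with:

    ``max_dwell_ns``
        per-ion longest contiguous residence within ``pause_radius`` of
        ``pause_site_z`` (captures pauses at a sticky site).
    ``occupancy_fractions``
        fraction of frames with 0 / 1 / 2 / >=3 ions inside
        ``filter_window`` ("one-ion" vs "two-ion" filter occupancy).
    ``axial_fraction_below_cutoff``
        fraction of in-pore samples with radial offset below
        ``offset_cutoff``.
    ``offset_histogram``
        per-z-bin histogram (bin edges included) of radial offsets.
    """
    if filter_window[1] <= filter_window[0] or pore_window[1] <= pore_window[0]:
        raise ValueError("windows must be (lo, hi) with hi > lo")

    max_dwell = {}
    for tr in traces:
        near = np.abs(tr.z - pause_site_z) <= pause_radius
        best = 0.0
        i = 0
        while i < len(near):
            if near[i]:
                j = i
                while j + 1 < len(near) and near[j + 1]:
                    j += 1
                best = max(best, tr.t[j] - tr.t[i])
                i = j + 1
            else:
                i += 1
        max_dwell[tr.ion_id] = float(best)

    occupancy = {"0": 0.0, "1": 0.0, "2": 0.0, ">=3": 0.0}
    if traces:
        t_ref = traces[0].t
        counts = np.zeros(len(t_ref), dtype=int)
        for tr in traces:
            if len(tr) != len(t_ref) or not np.allclose(tr.t, t_ref):
                raise ValueError("occupancy statistics need a shared time grid")
            counts += ((tr.z >= filter_window[0]) & (tr.z <= filter_window[1]))
        n = len(t_ref)
        occupancy = {"0": float(np.mean(counts == 0)),
                     "1": float(np.mean(counts == 1)),
                     "2": float(np.mean(counts == 2)),
                     ">=3": float(np.mean(counts >= 3))}

    z_all = np.concatenate([tr.z for tr in traces]) if traces else np.empty(0)
    r_all = (np.concatenate([tr.r_offset for tr in traces])
             if traces else np.empty(0))
    in_pore = (z_all >= pore_window[0]) & (z_all <= pore_window[1])
    frac = float(np.mean(r_all[in_pore] < offset_cutoff)) if in_pore.any() else np.nan

    z_edges = np.arange(pore_window[0], pore_window[1] + offset_zbin, offset_zbin)
    r_edges = np.arange(0.0, max(10.0, offset_cutoff * 2) + 0.5, 0.5)
    hist, _, _ = (np.histogram2d(z_all[in_pore], r_all[in_pore],
                                 bins=[z_edges, r_edges])
                  if in_pore.any() else (np.zeros((len(z_edges) - 1,
                                                   len(r_edges) - 1)), None, None))
    return {
        "max_dwell_ns": max_dwell,
        "occupancy_fractions": occupancy,
        "axial_fraction_below_cutoff": frac,
        "offset_histogram": {"z_edges": z_edges, "r_edges": r_edges, "counts": hist},
    }
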