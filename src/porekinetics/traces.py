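"""Per-ion time series of axial position in the pore frame."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["IonTrace", "IonTraceSet"]


@dataclass
class IonTrace:
    """Time series for one ion: time (ns), unwrapped pore-frame z (Å), and
    radial offset from the pore axis (Å)."""

    ion_id: str
    t: np.ndarray
    z: np.ndarray
    r_offset: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.r_offset = np.asarray(self.r_offset, dtype=float)
        if not (len(self.t) == len(self.z) == len(self.r_offset)):
            raise ValueError(f"ion {self.ion_id}: t/z/r_offset lengths differ")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"ion {self.ion_id}: t must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"ion {self.ion_id}: z contains non-finite values")
        if np.any(self.r_offset < 0):
            raise ValueError(f"ion {self.ion_id}: r_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class IonTraceSet:
    """A set of ion traces from one replica, with optional metadata."""

    traces: list[IonTrace]
    duration: float | None = None   # ns
    voltage: float | None = None    # mV
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __getitem__(self, i):
        return self.traces[i]
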