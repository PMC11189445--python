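"""Single-Boltzmann fitting of normalized tail-current activation curves.

The activation curve of a hyperpolarization-activated channel is fitted
with G/Gmax = 1 / (1 + exp((V - V1/2)/k)), where V is the conditioning
pulse, V1/2 the half-maximal activation voltage and k the slope factor
(both in mV). Normalized data fix Gmax = 1; a free-Gmax mode is available
for raw tail amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import GVCurve, boltzmann

__all__ = ["BoltzmannFit", "fit_boltzmann"]


@dataclass
class BoltzmannFit:
    v_half: float            # mV
    slope_k: float           # mV, > 0
    residual_sse: float
    covariance: np.ndarray   # 2x2 (or 3x3 with free Gmax)
    gmax: float = 1.0

    def predict(self, v):
        return self.gmax * boltzmann(v, self.v_half, self.slope_k)


def fit_boltzmann(curve: GVCurve, init: dict | None = None,
                  free_gmax: bool = False) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a G-V curve.

    Auto-initialisation takes v_half as the voltage whose G is nearest 0.5
    and k = 8 mV. Requires at least 4 distinct voltages spanning both sides
    of the midpoint; flat data raise a degenerate-fit error.
    """
    v = curve.voltages
    g = curve.normalized_conductance
    if len(np.unique(v)) < 4:
        raise ValueError("need at least 4 distinct voltages")
    if np.ptp(g) < 0.05:
        raise ValueError("degenerate fit: data are flat (ptp < 0.05)")
    if init is None:
        v0 = float(v[np.argmin(np.abs(g - 0.5 * (g.max() + g.min())))])
        k0 = 8.0
    else:
        v0, k0 = float(init["v_half"]), float(init["k"])
    if not (g.min() < 0.5 < g.max()) and not free_gmax:
        # midpoint outside the sampled range: the fit may extrapolate badly
        pass

    try:
        if free_gmax:
            popt, pcov = curve_fit(
                lambda vv, vh, k, gm: gm * boltzmann(vv, vh, k),
                v, g, p0=[v0, k0, max(g.max(), 1e-3)],
                bounds=([-np.inf, 1e-3, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=10000)
            vh, k, gm = popt
        else:
            popt, pcov = curve_fit(
                lambda vv, vh, k: boltzmann(vv, vh, k),
                v, g, p0=[v0, k0],
                bounds=([-np.inf, 1e-3], [np.inf, np.inf]), maxfev=10000)
            vh, k = popt
            gm = 1.0
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit did not converge (init v_half={v0}, k={k0})") from exc
    resid = g - gm * boltzmann(v, vh, k)
    return BoltzmannFit(v_half=float(vh), slope_k=float(k),
                        residual_sse=float(np.sum(resid ** 2)),
                        covariance=pcov, gmax=float(gm))
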