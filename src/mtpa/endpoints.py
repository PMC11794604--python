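"""Target-occupancy and PK exposure endpoints over a steady-state window.

TO% is the bound fraction of total target, 100 * DT / (T + DT), read at the
instants where the drug concentration at the evaluation site reaches its
trough and peak within the final (steady-state) dosing interval.  Plasma
C_min / C_max / AUC_ss are reported alongside; they characterize exposure
but are not fed to the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .model_core import Trajectory

__all__ = [
    "EndpointRecord", "target_occupancy", "pk_endpoints",
    "label_binary", "label_multi",
]


@dataclass(frozen=True)
class EndpointRecord:
    site: str
    to_at_cmin: float      # percent
    to_at_cmax: float      # percent
    c_min: float           # plasma trough, nM
    c_max: float           # plasma peak, nM
    auc_ss: float          # plasma exposure over the window, nM*h
    converged: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def target_occupancy(free_target: float, complex_: float) -> float:
    """TO% = 100 * bound / (free + bound).

    Both inputs zero is undefined (no target present); returns the 0
    sentinel with a warning.
    """
    if free_target < 0 or complex_ < 0:
        raise ValueError("negative target or complex concentration")
    total = free_target + complex_
    if total == 0:
        warnings.warn("target occupancy undefined (no target present); "
                      "returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return 100.0 * complex_ / total


def pk_endpoints(traj: Trajectory, site: str = "plasma") -> EndpointRecord:
    """Endpoints over the trajectory's steady-state window.

    ``c_min``/``c_max``/``auc_ss`` always describe plasma; the occupancy
    pair is read at the times where the *site's own* drug concentration is
    lowest / highest inside the window (for plasma these coincide with the
    plasma trough and peak).
    """
    win = traj.window_view()
    if len(win.time) < 2:
        raise ValueError("empty steady-state window")
    plasma = win.drug("plasma")
    c_min = float(plasma.min())
    c_max = float(plasma.max())
    auc = float(np.trapezoid(plasma, win.time))
    site_drug = win.drug(site)
    i_min = int(np.argmin(site_drug))
    i_max = int(np.argmax(site_drug))
    free = win.free_target(site)
    cplx = win.complex(site)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        to_min = float(target_occupancy(free[i_min], cplx[i_min]))
        to_max = float(target_occupancy(free[i_max], cplx[i_max]))
    return EndpointRecord(site=site, to_at_cmin=to_min, to_at_cmax=to_max,
                          c_min=c_min, c_max=c_max, auc_ss=auc,
                          converged=traj.converged)


def label_binary(to_at_cmin: float) -> str:
    """'optimal' iff TO% at the steady-state trough strictly exceeds 90."""
    return "optimal" if to_at_cmin > 90.0 else "non_optimal"


def label_multi(to_at_cmin: float) -> str:
    """Three-band label: low (<=50), medium (50, 90], high (>90)."""
    if to_at_cmin <= 50.0:
        return "low"
    if to_at_cmin <= 90.0:
        return "medium"
    return "high"
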