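"""Dose regimens and the forcing they induce on the linear system.

IV doses enter the venous plasma: a bolus as an initial condition
``C_vp(0) = dose / V_vp``, an infusion as a constant mass input rate.  An
oral dose is absorbed first-order into the *gut intracellular water* with
rate ``Dose * Ka * exp(-Ka t)`` (mg/h), so first-pass through the portal
vein and liver emerges from the network itself rather than from a
bioavailability parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LinearSystem

__all__ = ["DoseRegimen", "Forcing", "apply_dose", "po_depot_system"]

ROUTES = ("iv_bolus", "iv_infusion", "po")


class DosingError(ValueError):
    """Inconsistent dose regimen."""


@dataclass(frozen=True)
class DoseRegimen:
    """One administration: route, amount/rate, and kinetic constants.

    ``dose`` (mg) applies to ``iv_bolus`` and ``po``; ``rate`` (mg/h) and the
    optional stop time ``t_stop`` (h) to ``iv_infusion`` (no stop time means
    the infusion runs for the whole simulated horizon); ``ka`` (1/h) is the
    first-order absorption constant required for ``po``.
    """

    route: str
    dose: float | None = None
    rate: float | None = None
    ka: float | None = None
    t_stop: float | None = None

    def __post_init__(self):
        if self.route not in ROUTES:
            raise DosingError(f"unknown route {self.route!r}")
        if self.route in ("iv_bolus", "po"):
            if self.dose is None or self.dose < 0:
                raise DosingError(f"{self.route} requires a nonnegative dose")
            if self.rate is not None:
                raise DosingError(f"{self.route} takes no infusion rate")
        if self.route == "po" and not (self.ka and self.ka > 0):
            raise DosingError("po requires Ka > 0")
        if self.route == "iv_infusion":
            if self.rate is None or self.rate < 0:
                raise DosingError("iv_infusion requires a nonnegative rate")
            if self.dose is not None:
                raise DosingError("iv_infusion takes a rate, not a dose")
            if self.t_stop is not None and self.t_stop <= 0:
                raise DosingError("t_stop must be > 0")


@dataclass(frozen=True)
class Forcing:
    """Concentration-space forcing ``f(t)`` (mg/L/h per state).

    ``kind`` is one of ``none`` (homogeneous), ``constant`` (``g`` up to
    ``t_stop``), or ``exponential`` (``g * exp(-ka t)``); ``g`` already
    carries the 1/volume factor of the receiving state.
    """

    kind: str
    g: np.ndarray
    ka: float | None = None
    t_stop: float | None = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            shape = self.g.shape + t.shape
            return np.zeros(shape) if t.ndim else np.zeros(self.g.shape)
        if self.kind == "constant":
            on = 1.0 if self.t_stop is None else (t < self.t_stop).astype(float)
            return np.multiply.outer(self.g, on) if t.ndim else self.g * on
        # exponential
        e = np.exp(-self.ka * t)
        return np.multiply.outer(self.g, e) if t.ndim else self.g * e


def apply_dose(system: LinearSystem, regimen: DoseRegimen):
    """Initial state and forcing function for a regimen on an assembled system.

    The administered mass is conserved exactly: initial amount plus the time
    integral of the volume-weighted forcing equals the nominal dose (bolus,
    PO) or ``rate * duration`` (infusion).
    """
    n = system.n
    y0 = np.zeros(n)
    if regimen.route == "iv_bolus":
        y0[system.i_vp] = regimen.dose / system.volumes[system.i_vp]
        return y0, Forcing("none", np.zeros(n))
    if regimen.route == "iv_infusion":
        g = np.zeros(n)
        g[system.i_vp] = regimen.rate / system.volumes[system.i_vp]
        return y0, Forcing("constant", g, t_stop=regimen.t_stop)
    # po: Dose * Ka * exp(-Ka t) into gut IW
    g = np.zeros(n)
    g[system.i_gut_iw] = (
        regimen.dose * regimen.ka / system.volumes[system.i_gut_iw]
    )
    return y0, Forcing("exponential", g, ka=regimen.ka)


def po_depot_system(system: LinearSystem, regimen: DoseRegimen):
    """Depot-state equivalent of the analytic oral forcing (solver cross-check).

    Returns ``(A_aug, y0_aug)`` for the ``(n+1)``-state system in which the
    last state is the gut-lumen amount (mg) decaying at ``Ka`` into the gut
    IW.  Its first ``n`` concentration trajectories coincide with the
    analytic-forcing solution to solver precision.
    """
    if regimen.route != "po":
        raise DosingError("depot form only applies to the po route")
    n = system.n
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = system.A
    A[n, n] = -regimen.ka
    A[system.i_gut_iw, n] = regimen.ka / system.volumes[system.i_gut_iw]
    y0 = np.zeros(n + 1)
    y0[n] = regimen.dose
    return A, y0
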