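"""Numerical integration, derived metrics, and closed-form oracles.

The assembled model is linear and time-invariant, which gives us two fully
independent solution routes:

* a stiff ODE integrator (``scipy.integrate.solve_ivp``, BDF with the exact
  constant Jacobian) producing dense trajectories, and
* closed forms — the matrix exponential for trajectories, the steady-state
  solve ``A C = -f`` for constant infusion, and the dominant eigenmode (or
  the flip-flop particular solution) for the terminal phase after a single
  dose.

The derived quantities follow the standard definitions: the tissue
concentration is the amount-weighted mean over the four subcompartments; the
partition coefficient ``Kp(t)`` divides it by the venous plasma
concentration (the accessible surrogate of systemic plasma); the
distribution volume ``Vd(t)`` divides the total amount in the body by
``C_vp * BW``.  After a single dose to an open system, ``Vd(t)`` plateaus at
``Vdss`` once every compartment decays with the common terminal slope — the
pseudo-steady state.

By default the portal-vein blood amounts are counted in ``Vd(t)`` together
with the venous and arterial pools: only then does the closed-system null
case give exactly ``Vdss = 1 L/kg`` at density 1.  The variant that omits
the portal pool (as the bare reading of the definition would) is available
via ``include_portal=False``; the difference is about ``V_portal / BW``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, linalg

from .dosing import DoseRegimen, Forcing, apply_dose
from .model import SUBCOMPARTMENTS, LinearSystem

__all__ = [
    "SimulationResult",
    "DerivedMetrics",
    "PseudoSteadyState",
    "ConvergenceError",
    "simulate",
    "solution_expm",
    "tissue_concentration",
    "kp_profile",
    "vd_profile",
    "detect_pseudo_steady_state",
    "terminal_mode",
    "vdss_closed_form",
    "kpss_closed_form",
    "derived_metrics",
    "write_results",
]

#: Default solver tolerances: stiff integrator, tight because the derived
#: ratios (Kp, Vd) amplify small trajectory errors late in the decay.
RTOL = 1e-9
ATOL = 1e-12  # mg/L


class ConvergenceError(RuntimeError):
    """No (pseudo-)steady state found within the simulated horizon."""


@dataclass
class SimulationResult:
    """Trajectories on the output grid: ``C[state, time]`` in mg/L."""

    t: np.ndarray
    C: np.ndarray
    system: LinearSystem
    regimen: DoseRegimen
    diagnostics: dict = field(default_factory=dict)

    def state(self, compartment: str, sub: str) -> np.ndarray:
        return self.C[self.system.state_index[(compartment, sub)]]

    @property
    def C_vp(self) -> np.ndarray:
        return self.C[self.system.i_vp]

    def total_mass(self) -> np.ndarray:
        return self.system.volumes @ self.C


def _default_grid(t_end: float, n_points: int, t_min: float) -> np.ndarray:
    """Log-spaced grid resolving both the first minutes and the terminal
    phase, with t = 0 prepended."""
    return np.concatenate([[0.0], np.geomspace(t_min, t_end, n_points)])


def simulate(
    system: LinearSystem,
    regimen: DoseRegimen,
    t_end: float,
    *,
    grid: np.ndarray | None = None,
    n_points: int = 300,
    t_min: float = 1e-3,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate ``dC/dt = A C + f(t)`` on a (default log-spaced) output grid.

    An infusion stop time splits the integration into two legs so the forcing
    discontinuity never sits inside a solver step.  Concentrations in
    ``[-atol, 0)`` are clamped to zero; anything more negative raises.
    """
    if t_end <= 0:
        raise ValueError("horizon t_end must be > 0")
    y0, forcing = apply_dose(system, regimen)
    t_eval = _default_grid(t_end, n_points, min(t_min, t_end / 10)) if grid is None \
        else np.asarray(grid, dtype=float)
    A = system.A

    def rhs(t, y):
        return A @ y + forcing(t)

    def jac(t, y):
        return A

    breaks = [0.0, t_end]
    if forcing.t_stop is not None and 0 < forcing.t_stop < t_end:
        breaks = [0.0, forcing.t_stop, t_end]

    ts, Cs = [], []
    y = y0
    nfev = 0
    for a, b in zip(breaks[:-1], breaks[1:]):
        chunk = t_eval[(t_eval >= a) & (t_eval <= b)]
        chunk = np.unique(np.concatenate([[a], chunk, [b]]))
        sol = integrate.solve_ivp(
            rhs, (a, b), y, method=method, t_eval=chunk,
            rtol=rtol, atol=atol, jac=jac,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        nfev += sol.nfev
        keep = np.isin(sol.t, t_eval)
        ts.append(sol.t[keep])
        Cs.append(sol.y[:, keep])
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    C = np.concatenate(Cs, axis=1)
    t, iu = np.unique(t, return_index=True)
    C = C[:, iu]

    low = C.min()
    if low < -atol * 10:
        raise RuntimeError(f"negative concentration {low:.3e} mg/L beyond tolerance")
    C = np.where(C < 0, 0.0, C)

    diag = {"nfev": nfev, "method": method, "rtol": rtol, "atol": atol}
    if system.is_closed:
        m = system.volumes @ C
        m0 = system.mass(y0) + _administered_mass(system, regimen, t[-1])
        if m0 > 0:
            diag["mass_drift_rel"] = float(np.max(np.abs(m - m[-1])) / m0)
    return SimulationResult(t=t, C=C, system=system, regimen=regimen,
                            diagnostics=diag)


def _administered_mass(system: LinearSystem, regimen: DoseRegimen, t: float) -> float:
    if regimen.route == "iv_bolus":
        return 0.0  # already in y0
    if regimen.route == "iv_infusion":
        dur = t if regimen.t_stop is None else min(t, regimen.t_stop)
        return regimen.rate * dur
    return regimen.dose * (1 - np.exp(-regimen.ka * t))


# ------------------------------------------------------------- expm oracle

def solution_expm(
    system: LinearSystem, regimen: DoseRegimen, times: np.ndarray
) -> np.ndarray:
    """Closed-form trajectories via the matrix exponential.

    Homogeneous doses use ``C(t) = e^{At} C(0)``; forced regimens use the
    standard augmented-matrix form so no quadrature is involved.  Serves as
    the independent oracle for :func:`simulate`.
    """
    times = np.asarray(times, dtype=float)
    y0, forcing = apply_dose(system, regimen)
    n = system.n
    out = np.empty((n, times.size))
    if forcing.kind == "none":
        for k, t in enumerate(times):
            out[:, k] = linalg.expm(system.A * t) @ y0
        return out
    if forcing.kind == "exponential":
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = system.A
        M[:n, n] = forcing.g
        M[n, n] = -forcing.ka
        z0 = np.concatenate([y0, [1.0]])
        for k, t in enumerate(times):
            out[:, k] = (linalg.expm(M * t) @ z0)[:n]
        return out
    # constant (infusion), possibly with a stop time
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = system.A
    M[:n, n] = forcing.g
    z0 = np.concatenate([y0, [1.0]])
    ts = forcing.t_stop
    for k, t in enumerate(times):
        if ts is None or t <= ts:
            out[:, k] = (linalg.expm(M * t) @ z0)[:n]
        else:
            y_stop = (linalg.expm(M * ts) @ z0)[:n]
            out[:, k] = linalg.expm(system.A * (t - ts)) @ y_stop
    return out


# ------------------------------------------------------------------ metrics

def tissue_concentration(result: SimulationResult, tissue: str) -> np.ndarray:
    """Amount-weighted tissue concentration over IW, EW, TP, TC (mg/L)."""
    sys_ = result.system
    idx = sys_.tissue_indices(tissue)
    V = sys_.volumes[idx]
    return (V @ result.C[idx]) / V.sum()


def kp_profile(result: SimulationResult, tissue: str) -> np.ndarray:
    """Tissue/venous-plasma partition coefficient ``Kp(t)``.

    Where the venous plasma concentration is zero the ratio is undefined and
    reported as NaN (not as zero).
    """
    ct = tissue_concentration(result, tissue)
    cvp = result.C_vp
    with np.errstate(divide="ignore", invalid="ignore"):
        kp = np.where(cvp > 0, ct / np.where(cvp > 0, cvp, 1.0), np.nan)
    return kp


def _vd_from_states(system: LinearSystem, C: np.ndarray,
                    include_portal: bool) -> np.ndarray:
    """Vd (L/kg) for a state vector or state x time matrix."""
    w = system.volumes.copy()
    if not include_portal:
        for sub in ("plasma", "cells"):
            w[system.state_index[("portal", sub)]] = 0.0
    amount = w @ C
    cvp = C[system.i_vp] if C.ndim > 1 else C[system.i_vp]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(cvp > 0, amount / (np.where(cvp > 0, cvp, 1.0)
                                           * system.phys.BW), np.nan)


def vd_profile(result: SimulationResult, *, include_portal: bool = True) -> np.ndarray:
    """Distribution volume ``Vd(t)`` (L/kg): total amount over ``C_vp * BW``."""
    return _vd_from_states(result.system, result.C, include_portal)


@dataclass(frozen=True)
class PseudoSteadyState:
    t_pss: float
    Vdss: float
    lambda_terminal: float  # 1/h, positive decay constant (0 for closed system)


def detect_pseudo_steady_state(
    result: SimulationResult,
    *,
    slope_rtol: float = 1e-3,
    slope_atol: float = 1e-4,
    vd_drift_tol: float = 1e-4,
    include_portal: bool = True,
) -> PseudoSteadyState:
    """Find the pseudo-steady state: common terminal slope and a Vd plateau.

    Scans the output grid for the earliest time after which (a) the log-slopes
    of every tissue concentration agree with the venous-plasma slope within
    ``slope_rtol`` (relative) or ``slope_atol`` (absolute, 1/h — required for
    closed/steady systems whose slopes tend to zero), and (b) the relative
    drift of Vd stays below ``vd_drift_tol`` per hour.  ``Vdss`` is read at
    the end of the horizon.
    """
    t = result.t
    profiles = [result.C_vp] + [
        tissue_concentration(result, x) for x in result.system.phys.tissues
    ]
    P = np.vstack(profiles)
    vd = vd_profile(result, include_portal=include_portal)

    pos = (P > 0).all(axis=0) & np.isfinite(vd) & (t > 0)
    if pos.sum() < 5:
        raise ConvergenceError("trajectory support too short to assess a plateau")
    tt = t[pos]
    logP = np.log(P[:, pos])
    slopes = np.gradient(logP, tt, axis=1)          # 1/h
    lam_vp = slopes[0]
    slope_ok = (
        np.abs(slopes - lam_vp).max(axis=0)
        <= np.maximum(slope_rtol * np.abs(lam_vp), slope_atol)
    )
    vdd = vd[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = np.abs(np.gradient(vdd, tt)) / vdd
    vd_ok = drift <= vd_drift_tol

    ok = slope_ok & vd_ok
    # earliest index from which the condition holds for the rest of the grid
    holds_to_end = np.flip(np.logical_and.accumulate(np.flip(ok)))
    if not holds_to_end.any():
        raise ConvergenceError(
            "no pseudo-steady state within the horizon; extend t_end"
        )
    k = int(np.argmax(holds_to_end))
    return PseudoSteadyState(
        t_pss=float(tt[k]),
        Vdss=float(vdd[-1]),
        lambda_terminal=float(-lam_vp[-1]),
    )


# -------------------------------------------------------- closed-form Vdss

@dataclass(frozen=True)
class TerminalMode:
    """Shape of the terminal solution: ``C(t) ~ C_mode * exp(-lambda t)``."""

    lam: float          # decay constant (1/h); 0 for null/steady modes
    C_mode: np.ndarray  # terminal concentration direction (arbitrary scale)
    mode: str           # 'null' | 'eigen' | 'flipflop' | 'steady'
    flip_flop: bool = False


def terminal_mode(system: LinearSystem, regimen: DoseRegimen) -> TerminalMode:
    """Terminal-phase solution shape, computed without time stepping.

    * constant infusion: the stationary solve ``A C = -f`` (0 eigenvalue of
      the forced system);
    * single dose (IV bolus / PO with fast absorption): the dominant — least
      negative — eigenmode of ``A``; for a closed system this is the zero
      eigenvalue with the uniform eigenvector;
    * PO with absorption slower than the dominant decay (flip-flop): the
      particular solution ``C = -(A + Ka I)^{-1} g * exp(-Ka t)``.
    """
    A = system.A
    if regimen.route == "iv_infusion":
        if system.is_closed:
            raise ConvergenceError(
                "constant infusion into a closed system has no steady state"
            )
        _, forcing = apply_dose(system, regimen)
        C = -linalg.solve(A, forcing.g)
        return TerminalMode(lam=0.0, C_mode=C, mode="steady")

    w, V = np.linalg.eig(A)
    order = np.argsort(w.real)[::-1]
    w, V = w[order], V[:, order]
    lam_dom = -w[0].real
    if abs(w[0].imag) > 1e-9 * max(1.0, abs(w[0].real)):
        warnings.warn("dominant eigenvalue has a significant imaginary part")
    if len(w) > 1 and abs(w[0] - w[1]) < 1e-9 * max(1.0, abs(w[0])):
        warnings.warn("near-degenerate dominant eigenpair; Vdss may be "
                      "ill-conditioned")
    v = V[:, 0].real
    i_ref = int(np.argmax(np.abs(v)))
    v = v / v[i_ref]

    if regimen.route == "po" and regimen.ka < lam_dom:
        # absorption-limited terminal phase
        _, forcing = apply_dose(system, regimen)
        C = -linalg.solve(A + regimen.ka * np.eye(system.n), forcing.g)
        return TerminalMode(lam=regimen.ka, C_mode=C, mode="flipflop",
                            flip_flop=True)
    mode = "null" if abs(lam_dom) < 1e-12 else "eigen"
    return TerminalMode(lam=max(lam_dom, 0.0), C_mode=v, mode=mode)


def vdss_closed_form(
    system: LinearSystem, regimen: DoseRegimen, *, include_portal: bool = True
) -> float:
    """Vdss (L/kg) from the terminal mode — the time-stepping-free oracle."""
    tm = terminal_mode(system, regimen)
    return float(_vd_from_states(system, tm.C_mode, include_portal))


def kpss_closed_form(system: LinearSystem, regimen: DoseRegimen) -> dict[str, float]:
    """Pseudo-steady-state Kp per tissue from the terminal mode."""
    tm = terminal_mode(system, regimen)
    cvp = tm.C_mode[system.i_vp]
    out = {}
    for t in system.phys.tissues:
        idx = system.tissue_indices(t)
        V = system.volumes[idx]
        out[t] = float((V @ tm.C_mode[idx]) / V.sum() / cvp)
    return out


# ------------------------------------------------------------------ bundles

@dataclass
class DerivedMetrics:
    """Kp(t), Vd(t) and pseudo-steady-state summary of one simulation."""

    ctissue: pd.DataFrame   # time x tissue, mg/L
    kp: pd.DataFrame        # time x tissue
    vd: pd.Series           # time -> L/kg
    t_pss: float
    Vdss: float
    lambda_terminal: float


def derived_metrics(
    result: SimulationResult, *, include_portal: bool = True, **pss_kw
) -> DerivedMetrics:
    tissues = list(result.system.phys.tissues)
    ct = pd.DataFrame(
        {x: tissue_concentration(result, x) for x in tissues}, index=result.t
    )
    kp = pd.DataFrame({x: kp_profile(result, x) for x in tissues}, index=result.t)
    vd = pd.Series(vd_profile(result, include_portal=include_portal),
                   index=result.t, name="Vd_L_per_kg")
    pss = detect_pseudo_steady_state(result, include_portal=include_portal,
                                     **pss_kw)
    return DerivedMetrics(ctissue=ct, kp=kp, vd=vd, t_pss=pss.t_pss,
                          Vdss=pss.Vdss, lambda_terminal=pss.lambda_terminal)


def write_results(result: SimulationResult, outdir, *,
                  include_portal: bool = True) -> None:
    """Write long-format concentrations, Kp/Vd metrics, and a JSON summary."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = result.system.labels
    rows = []
    for i, (comp, sub) in enumerate(labels):
        rows.append(pd.DataFrame({
            "time_h": result.t, "compartment": comp, "subcompartment": sub,
            "conc_mg_per_L": result.C[i],
        }))
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "concentrations.csv", index=False)

    dm = derived_metrics(result, include_portal=include_portal)
    kp_long = dm.kp.reset_index(names="time_h").melt(
        id_vars="time_h", var_name="tissue", value_name="Kp")
    kp_long.to_csv(outdir / "kp.csv", index=False)
    dm.vd.rename_axis("time_h").reset_index().to_csv(
        outdir / "vd.csv", index=False)
    summary = {
        "Vdss_L_per_kg": dm.Vdss, "t_pss_h": dm.t_pss,
        "lambda_terminal_per_h": dm.lambda_terminal,
        "route": result.regimen.route,
        "diagnostics": result.diagnostics,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
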