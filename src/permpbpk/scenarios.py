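"""What-if scenario grids: permeability, metabolism site, transporters, route.

A scenario is a compound sketched entirely in fold-of-tissue-blood-flow
shorthand (``PS = 0.1 x Q``, ``CL_met = 1 x Q`` in the residual plasma of all
tissues, an efflux transporter at ``1 x Q``, ...) combined with one of four
reference regimens: constant IV infusion 100 mg/h, IV bolus 100 mg, or a
100 mg oral dose with fast (Ka = 1 1/h) or slow (Ka = 0.01 1/h) absorption.

``run_scenario`` assembles the compound, simulates to the (pseudo-)steady
state, and reports Vdss both from the trajectory and from the closed-form
terminal mode — the two must agree to a few tenths of a percent when the run
converged.  ``reproduce_table`` drives the four standard factorial grids:

* T1 — permeability ladder (PS/Q in 0.01..100) with intracellular metabolism
  ``CL = Q`` in all tissues;
* T2 — hepatic-only metabolism, one liver subcompartment at a time, CL/Q_liver
  in {0.1, 1, 10};
* T3 — metabolism in one subcompartment of *all* tissues, CL/Q in
  {0.1, 0.5, 1};
* T4 — uptake/efflux transporters (CL = Q) at low (0.1 x Q) and high (1 x Q)
  permeability with intracellular metabolism ``CL = Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dosing import DoseRegimen
from .model import CompoundParameters, assemble_system
from .physiology import BodyPhysiology, load_physiology
from .simulate import (
    ConvergenceError,
    detect_pseudo_steady_state,
    kpss_closed_form,
    simulate,
    terminal_mode,
    vdss_closed_form,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "STANDARD_REGIMENS",
    "run_scenario",
    "reproduce_table",
    "TABLES",
]

#: The four reference dosing regimens of the what-if study.
STANDARD_REGIMENS: dict[str, DoseRegimen] = {
    "iv_infusion": DoseRegimen("iv_infusion", rate=100.0),
    "iv_bolus": DoseRegimen("iv_bolus", dose=100.0),
    "po_fast": DoseRegimen("po", dose=100.0, ka=1.0),
    "po_slow": DoseRegimen("po", dose=100.0, ka=0.01),
}

#: Default horizons (h) per regimen: single doses reach the pseudo-steady
#: state within tens of hours; infusion and slow absorption need far longer.
DEFAULT_HORIZONS = {
    "iv_infusion": 1000.0,
    "iv_bolus": 60.0,
    "po_fast": 60.0,
    "po_slow": 1000.0,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a what-if grid, in fold-of-Q shorthand.

    ``ps_fold`` scales the TP<->EW and EW<->IW membranes jointly (the
    TC<->TP membrane stays at the near-instant ``ps_tc_tp``).  Metabolism is
    placed in subcompartment ``met_site`` of ``met_tissues`` ("all",
    "liver", or an explicit tuple).  ``transporter`` is None, "uptake", or
    "efflux" at ``transporter_fold x Q`` in every tissue.
    """

    route: str = "iv_bolus"
    ps_fold: float = 1.0
    met_site: str | None = None
    met_tissues: str | tuple[str, ...] = "all"
    met_fold: float = 0.0
    transporter: str | None = None
    transporter_fold: float = 0.0
    ps_tc_tp: float = 1000.0

    def regimen(self) -> DoseRegimen:
        return STANDARD_REGIMENS[self.route]

    def compound(self, phys: BodyPhysiology) -> CompoundParameters:
        kw = dict(ps_fold=self.ps_fold, ps_tc_tp=self.ps_tc_tp)
        if self.met_site is not None and self.met_fold > 0:
            kw.update(cl_met_fold=self.met_fold, cl_met_site=self.met_site,
                      cl_met_tissues=self.met_tissues)
        if self.transporter == "uptake":
            kw["uptake_fold"] = self.transporter_fold
        elif self.transporter == "efflux":
            kw["efflux_fold"] = self.transporter_fold
        elif self.transporter is not None:
            raise ValueError(f"unknown transporter mode {self.transporter!r}")
        return CompoundParameters.from_folds(phys, **kw)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    Vdss: float               # from the simulated trajectory
    Vdss_oracle: float        # from the closed-form terminal mode
    kpss: dict[str, float]
    t_pss: float
    lambda_terminal: float
    converged: bool
    flip_flop: bool

    @property
    def oracle_gap(self) -> float:
        """Relative disagreement between trajectory and closed-form Vdss."""
        return abs(self.Vdss - self.Vdss_oracle) / abs(self.Vdss_oracle)


def run_scenario(
    spec: ScenarioSpec,
    phys: BodyPhysiology | None = None,
    *,
    t_end: float | None = None,
    include_portal: bool = True,
) -> ScenarioResult:
    """Assemble, simulate, and summarize one what-if scenario.

    The horizon defaults to the route's standard value; for single doses it
    is stretched automatically when the spectral gap between the two slowest
    modes implies a late pseudo-steady-state onset.
    """
    phys = load_physiology() if phys is None else phys
    system = assemble_system(phys, spec.compound(phys))
    regimen = spec.regimen()
    tm = terminal_mode(system, regimen)
    atol = 1e-12
    if t_end is None:
        t_end = DEFAULT_HORIZONS[spec.route]
        if spec.route in ("iv_bolus", "po_fast") and not system.is_closed:
            gap = _spectral_gap(system.A)
            if gap > 0:
                t_end = float(np.clip(14.0 / gap, 30.0, 600.0))
    # keep the absolute floor well below the terminal concentration scale so
    # late-time slopes are not corrupted by solver floor noise
    c_scale = 100.0 / system.volumes[system.i_vp]
    decay = tm.lam * t_end
    if decay > 0:
        atol = float(np.clip(c_scale * np.exp(-decay) * 1e-8, 1e-250, 1e-12))
    result = simulate(system, regimen, t_end, atol=atol)
    try:
        pss = detect_pseudo_steady_state(result, include_portal=include_portal)
        vdss, t_pss, lam = pss.Vdss, pss.t_pss, pss.lambda_terminal
        converged = True
    except ConvergenceError:
        from .simulate import vd_profile

        vdss = float(vd_profile(result, include_portal=include_portal)[-1])
        t_pss, lam, converged = float("nan"), float("nan"), False
    return ScenarioResult(
        spec=spec,
        Vdss=vdss,
        Vdss_oracle=vdss_closed_form(system, regimen,
                                     include_portal=include_portal),
        kpss=kpss_closed_form(system, regimen),
        t_pss=t_pss,
        lambda_terminal=lam,
        converged=converged,
        flip_flop=tm.flip_flop,
    )


def _spectral_gap(A: np.ndarray) -> float:
    """Gap (1/h) between the dominant and next-slowest decay rates."""
    w = np.sort(np.linalg.eigvals(A).real)[::-1]
    return float(w[0] - w[1])


# ------------------------------------------------------------------- tables

_ROUTE_ORDER = ("iv_infusion", "iv_bolus", "po_fast", "po_slow")
_SITES = ("iw", "ew", "tp", "tc")
_SITE_LABEL = {"iw": "IW", "ew": "EW", "tp": "Residual Plasma",
               "tc": "Residual Blood Cells"}

TABLES = ("T1", "T2", "T3", "T4")


def _table_specs(table_id: str) -> list[ScenarioSpec]:
    if table_id == "T1":
        return [
            ScenarioSpec(route=r, ps_fold=f, met_site="iw", met_fold=1.0)
            for r in _ROUTE_ORDER for f in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
    if table_id == "T2":
        return [
            ScenarioSpec(route=r, ps_fold=1.0, met_site=s,
                         met_tissues="liver", met_fold=f)
            for r in _ROUTE_ORDER for s in _SITES for f in (0.1, 1.0, 10.0)
        ]
    if table_id == "T3":
        return [
            ScenarioSpec(route=r, ps_fold=1.0, met_site=s, met_fold=f)
            for r in _ROUTE_ORDER for s in _SITES for f in (0.1, 0.5, 1.0)
        ]
    if table_id == "T4":
        return [
            ScenarioSpec(route=r, ps_fold=p, met_site="iw", met_fold=1.0,
                         transporter=tr, transporter_fold=1.0 if tr else 0.0)
            for r in _ROUTE_ORDER for p in (0.1, 1.0)
            for tr in ("uptake", None, "efflux")
        ]
    raise ValueError(f"unknown table id {table_id!r}; expected one of {TABLES}")


def _describe(spec: ScenarioSpec) -> dict:
    row: dict = {"route": spec.route, "ps_fold": spec.ps_fold}
    if spec.met_site:
        row["met_site"] = _SITE_LABEL[spec.met_site]
        row["met_tissues"] = (spec.met_tissues if isinstance(spec.met_tissues, str)
                              else "+".join(spec.met_tissues))
        row["met_fold"] = spec.met_fold
    if spec.transporter or spec.transporter is None:
        row["transporter"] = spec.transporter or "none"
    return row


def reproduce_table(
    table_id: str,
    phys: BodyPhysiology | None = None,
    *,
    method: str = "simulate",
) -> pd.DataFrame:
    """Run the full factorial behind one of the four standard grids.

    Returns a tidy DataFrame with one row per cell, carrying the simulated
    Vdss, the closed-form oracle Vdss, their relative gap, and convergence
    flags.  ``method="closed_form"`` skips time stepping and reports only the
    oracle column (fast preview).
    """
    phys = load_physiology() if phys is None else phys
    rows = []
    for spec in _table_specs(table_id):
        row = _describe(spec)
        if method == "closed_form":
            system = assemble_system(phys, spec.compound(phys))
            regimen = spec.regimen()
            tm = terminal_mode(system, regimen)
            row.update(Vdss=float("nan"),
                       Vdss_oracle=vdss_closed_form(system, regimen),
                       flip_flop=tm.flip_flop)
        elif method == "simulate":
            res = run_scenario(spec, phys)
            row.update(Vdss=res.Vdss, Vdss_oracle=res.Vdss_oracle,
                       oracle_gap=res.oracle_gap, t_pss_h=res.t_pss,
                       converged=res.converged, flip_flop=res.flip_flop)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "table", table_id)
    return df
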