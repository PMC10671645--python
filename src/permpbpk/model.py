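"""Flux laws and assembly of the whole-body model as a linear ODE system.

Each tissue contributes four concentration states (IW, EW, TP, TC), each blood
pool two (plasma, cells); the reference human body therefore has
``12*4 + 3*2 = 54`` states.  Drug moves by

* passive permeation between adjacent subcompartments (TC<->TP, TP<->EW,
  EW<->IW, and cells<->plasma in the circulating pools), driven by the free
  (unbound *and* unionized) concentration difference,
* unidirectional active transport across the cell membrane (EW->IW uptake,
  IW->EW efflux), driven by the unbound source concentration,
* convective blood flow along the circulation network, and
* first-order metabolism, available in every subcompartment, driven by the
  unbound concentration.

Note the deliberate asymmetry, implemented exactly as the flux laws state it:
the unionized fraction ``fi`` enters *passive* permeation only; transporter
and metabolic fluxes see the unbound fraction ``fu`` alone.

With concentrations as state variables the dynamics are ``dC/dt = A C + f(t)``
with a constant rate matrix ``A`` (1/h).  Mass conservation takes the
algebraic form: for every column ``j``, ``sum_i V_i A[i, j] = -CLmet_j fu_j``,
i.e. mass leaves the body only through metabolism; a compound with no
metabolism anywhere defines a closed system in which ``A`` has the uniform
vector in its null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .physiology import BodyPhysiology

__all__ = [
    "SUBCOMPARTMENTS",
    "BLOOD_STATES",
    "TissueCompound",
    "CompoundParameters",
    "LinearSystem",
    "ParameterError",
    "passive_flux",
    "active_transport_flux",
    "metabolic_flux",
    "assemble_system",
    "reference_perfusion_model",
]

#: Canonical tissue subcompartment order.
SUBCOMPARTMENTS = ("iw", "ew", "tp", "tc")

#: Canonical blood-pool state order (pool, subcompartment).
BLOOD_STATES = (
    ("arterial", "plasma"), ("arterial", "cells"),
    ("venous", "plasma"), ("venous", "cells"),
    ("portal", "plasma"), ("portal", "cells"),
)

#: Short keys of the six blood states, for metabolic clearances and fractions.
BLOOD_KEYS = ("ap", "ac", "vp", "vc", "pvp", "pvc")

#: Default cells<->plasma PS (L/h): effectively instant equilibration.
PS_CELLS_PLASMA_DEFAULT = 1000.0


class ParameterError(ValueError):
    """Invalid compound or model parameter."""


# --------------------------------------------------------------------- fluxes

def passive_flux(PS, C_a, fu_a, fi_a, C_b, fu_b, fi_b):
    """Bidirectional passive mass flux a->b (mg/h), ``PS (Ca fua fia − Cb fub fib)``.

    Only free — unbound and unionized — drug permeates (pH-partition
    hypothesis), so fully bound or fully ionized drug gives zero flux.
    Antisymmetric under swapping the two sides.
    """
    if np.any(np.asarray(PS) < 0):
        raise ParameterError("PS must be >= 0")
    return PS * (C_a * fu_a * fi_a - C_b * fu_b * fi_b)


def active_transport_flux(CL, C_source, fu_source):
    """Unidirectional transporter mass flux (mg/h), ``CL * C_source * fu_source``.

    Uptake uses EW as the source, efflux uses IW; the flux never reverses.
    """
    if np.any(np.asarray(CL) < 0):
        raise ParameterError("transporter CL must be >= 0")
    return CL * C_source * fu_source


def metabolic_flux(CL_met, C, fu):
    """First-order metabolic mass flux (mg/h), ``CL_met * C * fu``."""
    if np.any(np.asarray(CL_met) < 0):
        raise ParameterError("CL_met must be >= 0")
    return CL_met * C * fu


# ------------------------------------------------------------------ compound

def _ones() -> dict[str, float]:
    return {s: 1.0 for s in SUBCOMPARTMENTS}


def _zeros() -> dict[str, float]:
    return {s: 0.0 for s in SUBCOMPARTMENTS}


@dataclass
class TissueCompound:
    """Compound parameters in one tissue (all clearances/PS in L/h)."""

    ps_tp_ew: float = 0.0
    ps_ew_iw: float = 0.0
    ps_tc_tp: float = PS_CELLS_PLASMA_DEFAULT
    cl_uptake: float = 0.0   # EW -> IW
    cl_efflux: float = 0.0   # IW -> EW
    cl_met: dict[str, float] = field(default_factory=_zeros)
    fu: dict[str, float] = field(default_factory=_ones)
    fi: dict[str, float] = field(default_factory=_ones)

    def validate(self, name: str) -> None:
        for f in ("ps_tp_ew", "ps_ew_iw", "ps_tc_tp", "cl_uptake", "cl_efflux"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{name}: negative {f}")
        for s in SUBCOMPARTMENTS:
            if self.cl_met.get(s, 0.0) < 0:
                raise ParameterError(f"{name}: negative cl_met[{s}]")
            for d, lab in ((self.fu, "fu"), (self.fi, "fi")):
                v = d.get(s, 1.0)
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"{name}: {lab}[{s}]={v} outside [0, 1]")


@dataclass
class CompoundParameters:
    """Whole-body compound parameter set.

    ``tissues`` maps tissue name to :class:`TissueCompound`; the blood-pool
    dictionaries are keyed by the short state keys ``ap, ac, vp, vc, pvp,
    pvc``.  Metabolism in circulating blood defaults to zero; a compound with
    every metabolic clearance zero defines a closed system.
    """

    tissues: Mapping[str, TissueCompound]
    cl_met_blood: dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in BLOOD_KEYS})
    fu_blood: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in BLOOD_KEYS})
    fi_blood: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in BLOOD_KEYS})
    ps_blood: float = PS_CELLS_PLASMA_DEFAULT  # cells<->plasma in each pool

    def validate(self) -> None:
        for name, tc in self.tissues.items():
            tc.validate(name)
        if self.ps_blood < 0:
            raise ParameterError("negative ps_blood")
        for k in BLOOD_KEYS:
            if self.cl_met_blood.get(k, 0.0) < 0:
                raise ParameterError(f"negative cl_met_blood[{k}]")
            for d, lab in ((self.fu_blood, "fu"), (self.fi_blood, "fi")):
                v = d.get(k, 1.0)
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"blood {lab}[{k}]={v} outside [0, 1]")

    @property
    def is_closed(self) -> bool:
        """True when no metabolic clearance exists anywhere (closed system)."""
        return (
            all(all(v == 0 for v in t.cl_met.values()) for t in self.tissues.values())
            and all(v == 0 for v in self.cl_met_blood.values())
        )

    @classmethod
    def from_folds(
        cls,
        phys: BodyPhysiology,
        *,
        ps_fold: float = 1.0,
        ps_fold_tp_ew: float | None = None,
        ps_fold_ew_iw: float | None = None,
        cl_met_fold: float = 0.0,
        cl_met_site: str = "iw",
        cl_met_tissues: str | Iterable[str] = "all",
        uptake_fold: float = 0.0,
        efflux_fold: float = 0.0,
        ps_tc_tp: float = PS_CELLS_PLASMA_DEFAULT,
    ) -> "CompoundParameters":
        """Build a parameter set from fold-of-tissue-blood-flow shorthands.

        Every fold is resolved per tissue against its total blood flow
        ``Q = Q_tp + Q_tc`` (for the liver: hepatic artery + portal vein).
        ``ps_fold`` scales the TP<->EW and EW<->IW membranes jointly unless
        overridden individually; the TC<->TP membrane keeps the near-instant
        default unless ``ps_tc_tp`` is given.
        """
        if cl_met_site not in SUBCOMPARTMENTS:
            raise ParameterError(f"unknown metabolic site {cl_met_site!r}")
        if isinstance(cl_met_tissues, str):
            met_set = (
                set(phys.tissues) if cl_met_tissues == "all" else {cl_met_tissues}
            )
        else:
            met_set = set(cl_met_tissues)
        unknown = met_set - set(phys.tissues)
        if unknown:
            raise ParameterError(f"unknown metabolic tissues {sorted(unknown)}")
        f_tp_ew = ps_fold if ps_fold_tp_ew is None else ps_fold_tp_ew
        f_ew_iw = ps_fold if ps_fold_ew_iw is None else ps_fold_ew_iw
        tissues = {}
        for name, t in phys.tissues.items():
            cl_met = _zeros()
            if name in met_set:
                cl_met[cl_met_site] = cl_met_fold * t.Q
            tissues[name] = TissueCompound(
                ps_tp_ew=f_tp_ew * t.Q,
                ps_ew_iw=f_ew_iw * t.Q,
                ps_tc_tp=ps_tc_tp,
                cl_uptake=uptake_fold * t.Q,
                cl_efflux=efflux_fold * t.Q,
                cl_met=cl_met,
            )
        out = cls(tissues=tissues)
        out.validate()
        return out


# -------------------------------------------------------------------- system

@dataclass
class LinearSystem:
    """The assembled concentration-space system ``dC/dt = A C + f(t)``.

    ``state_index`` maps ``(compartment, subcompartment)`` — e.g.
    ``("liver", "iw")`` or ``("venous", "plasma")`` — to a state position.
    Tissues come first in alphabetical order with subcompartments
    ``iw, ew, tp, tc``, followed by the arterial, venous, and portal pools
    (plasma then cells).  ``volumes`` is the per-state volume vector (L) and
    ``cl_met_eff`` the per-state effective elimination ``CL_met * fu`` (L/h).
    """

    state_index: dict[tuple[str, str], int]
    A: np.ndarray
    volumes: np.ndarray
    cl_met_eff: np.ndarray
    phys: BodyPhysiology
    compound: CompoundParameters

    @property
    def n(self) -> int:
        return len(self.volumes)

    @property
    def labels(self) -> list[tuple[str, str]]:
        out = [None] * self.n
        for k, i in self.state_index.items():
            out[i] = k
        return out

    def idx(self, compartment: str, sub: str) -> int:
        return self.state_index[(compartment, sub)]

    @property
    def i_vp(self) -> int:
        return self.state_index[("venous", "plasma")]

    @property
    def i_gut_iw(self) -> int:
        return self.state_index[("gut", "iw")]

    def tissue_indices(self, tissue: str) -> list[int]:
        if tissue not in self.phys.tissues:
            raise KeyError(f"unknown tissue {tissue!r}")
        return [self.state_index[(tissue, s)] for s in SUBCOMPARTMENTS]

    @property
    def is_closed(self) -> bool:
        return self.compound.is_closed

    def mass(self, C: np.ndarray) -> np.ndarray:
        """Total drug amount (mg) for a state vector or state x time matrix."""
        C = np.asarray(C)
        return self.volumes @ C if C.ndim > 1 else float(self.volumes @ C)


def assemble_system(
    phys: BodyPhysiology, compound: CompoundParameters
) -> LinearSystem:
    """Assemble the whole-body rate matrix from physiology and compound data.

    Reproduces the subcompartment balance of every compartment term by term:
    arterially perfused tissues, the lung fed by venous blood, the liver fed
    by hepatic artery plus portal vein, the portal vein collecting pancreas,
    spleen, and gut, and the venous/arterial pools closing the loop.
    """
    compound.validate()
    if set(compound.tissues) != set(phys.tissues):
        raise ParameterError(
            "compound tissue set does not match physiology: "
            f"{sorted(set(compound.tissues) ^ set(phys.tissues))}"
        )

    names = sorted(phys.tissues)
    state_index: dict[tuple[str, str], int] = {}
    vols = []
    for t in names:
        tp = phys.tissues[t]
        for s, v in zip(SUBCOMPARTMENTS, (tp.V_iw, tp.V_ew, tp.V_tp, tp.V_tc)):
            state_index[(t, s)] = len(vols)
            vols.append(v)
    for pool, sub in BLOOD_STATES:
        state_index[(pool, sub)] = len(vols)
        vols.append({
            ("arterial", "plasma"): phys.V_ap, ("arterial", "cells"): phys.V_ac,
            ("venous", "plasma"): phys.V_vp, ("venous", "cells"): phys.V_vc,
            ("portal", "plasma"): phys.V_pvp, ("portal", "cells"): phys.V_pvc,
        }[(pool, sub)])
    V = np.asarray(vols, dtype=float)
    if np.any(V <= 0):
        bad = [lab for lab, i in state_index.items() if V[i] <= 0]
        raise ParameterError(f"non-positive subcompartment volumes: {bad}")
    n = len(V)
    A = np.zeros((n, n))
    cl_eff = np.zeros(n)

    def add_passive(i, j, PS, k_i, k_j):
        # d(V_i C_i)/dt += -PS (k_i C_i - k_j C_j); opposite sign on j
        A[i, i] -= PS * k_i / V[i]
        A[i, j] += PS * k_j / V[i]
        A[j, j] -= PS * k_j / V[j]
        A[j, i] += PS * k_i / V[j]

    def add_transport(src, dst, CL, fu_src):
        A[src, src] -= CL * fu_src / V[src]
        A[dst, src] += CL * fu_src / V[dst]

    def add_met(i, CL, fu):
        A[i, i] -= CL * fu / V[i]
        cl_eff[i] += CL * fu

    def add_flow(dst, src, Q):
        A[dst, src] += Q / V[dst]

    def add_outflow(i, Q):
        A[i, i] -= Q / V[i]

    ix = state_index
    for t in names:
        tp = phys.tissues[t]
        cp = compound.tissues[t]
        iw, ew, tpp, tc = (ix[(t, s)] for s in SUBCOMPARTMENTS)
        k = {s: cp.fu.get(s, 1.0) * cp.fi.get(s, 1.0) for s in SUBCOMPARTMENTS}
        add_passive(ew, iw, cp.ps_ew_iw, k["ew"], k["iw"])
        add_passive(tpp, ew, cp.ps_tp_ew, k["tp"], k["ew"])
        add_passive(tc, tpp, cp.ps_tc_tp, k["tc"], k["tp"])
        add_transport(ew, iw, cp.cl_uptake, cp.fu.get("ew", 1.0))
        add_transport(iw, ew, cp.cl_efflux, cp.fu.get("iw", 1.0))
        for s in SUBCOMPARTMENTS:
            add_met(ix[(t, s)], cp.cl_met.get(s, 0.0), cp.fu.get(s, 1.0))
        # perfusion
        if t == "lung":
            add_flow(tpp, ix[("venous", "plasma")], tp.Q_tp)
            add_flow(tc, ix[("venous", "cells")], tp.Q_tc)
        elif t == "liver":
            add_flow(tpp, ix[("arterial", "plasma")], phys.Q_ha_p)
            add_flow(tpp, ix[("portal", "plasma")], phys.Q_pv_p)
            add_flow(tc, ix[("arterial", "cells")], phys.Q_ha_c)
            add_flow(tc, ix[("portal", "cells")], phys.Q_pv_c)
        else:
            add_flow(tpp, ix[("arterial", "plasma")], tp.Q_tp)
            add_flow(tc, ix[("arterial", "cells")], tp.Q_tc)
        add_outflow(tpp, tp.Q_tp)
        add_outflow(tc, tp.Q_tc)

    # blood pools: passive cells<->plasma, metabolism
    kb = {b: compound.fu_blood.get(b, 1.0) * compound.fi_blood.get(b, 1.0)
          for b in BLOOD_KEYS}
    for (plasma, cells, kp, kc) in (
        (("arterial", "plasma"), ("arterial", "cells"), "ap", "ac"),
        (("venous", "plasma"), ("venous", "cells"), "vp", "vc"),
        (("portal", "plasma"), ("portal", "cells"), "pvp", "pvc"),
    ):
        add_passive(ix[cells], ix[plasma], compound.ps_blood, kb[kc], kb[kp])
        add_met(ix[plasma], compound.cl_met_blood.get(kp, 0.0),
                compound.fu_blood.get(kp, 1.0))
        add_met(ix[cells], compound.cl_met_blood.get(kc, 0.0),
                compound.fu_blood.get(kc, 1.0))

    # circulation between pools and tissues
    for t in names:
        tp = phys.tissues[t]
        if t in ("lung", "liver"):
            continue
        dst = "portal" if tp.drains_to == "portal" else "venous"
        add_flow(ix[(dst, "plasma")], ix[(t, "tp")], tp.Q_tp)
        add_flow(ix[(dst, "cells")], ix[(t, "tc")], tp.Q_tc)
    # liver -> venous
    add_flow(ix[("venous", "plasma")], ix[("liver", "tp")], phys.tissues["liver"].Q_tp)
    add_flow(ix[("venous", "cells")], ix[("liver", "tc")], phys.tissues["liver"].Q_tc)
    # venous -> lung (outflow side of the venous pool)
    add_outflow(ix[("venous", "plasma")], phys.Q_vp)
    add_outflow(ix[("venous", "cells")], phys.Q_vc)
    # lung -> arterial
    add_flow(ix[("arterial", "plasma")], ix[("lung", "tp")], phys.tissues["lung"].Q_tp)
    add_flow(ix[("arterial", "cells")], ix[("lung", "tc")], phys.tissues["lung"].Q_tc)
    # arterial outflow: all arterially perfused tissues + hepatic artery
    q_art_p = phys.Q_ha_p + sum(
        phys.tissues[t].Q_tp for t in names if t not in ("lung", "liver"))
    q_art_c = phys.Q_ha_c + sum(
        phys.tissues[t].Q_tc for t in names if t not in ("lung", "liver"))
    add_outflow(ix[("arterial", "plasma")], q_art_p)
    add_outflow(ix[("arterial", "cells")], q_art_c)
    # portal outflow -> liver
    add_outflow(ix[("portal", "plasma")], phys.Q_pv_p)
    add_outflow(ix[("portal", "cells")], phys.Q_pv_c)

    return LinearSystem(
        state_index=state_index, A=A, volumes=V, cl_met_eff=cl_eff,
        phys=phys, compound=compound,
    )


# ---------------------------------------------------- traditional comparator

def reference_perfusion_model(
    Kp_tissue: Mapping[str, float],
    Q: Mapping[str, float],
    CL_int: Mapping[str, float],
    volumes: Mapping[str, float],
    V_plasma: float,
    BW: float,
) -> tuple[dict[str, float], float]:
    """Traditional perfusion-limited steady-state comparator.

    For each tissue, ``Kpss = Kp * (1 - ER)`` with extraction ratio
    ``ER = CL_int / (Q + CL_int)``; the reference distribution volume is
    ``(V_plasma + sum V_t Kp_t (1 - ER_t)) / BW`` (L/kg).  Used only to
    contrast the dynamic permeability-limited results with classical
    steady-state theory.
    """
    kpss = {}
    vd = V_plasma
    for t, kp in Kp_tissue.items():
        q = Q[t]
        if q <= 0:
            raise ParameterError(f"{t}: tissue blood flow must be > 0")
        cl = CL_int.get(t, 0.0)
        if cl < 0:
            raise ParameterError(f"{t}: negative CL_int")
        er = cl / (q + cl)
        kpss[t] = kp * (1.0 - er)
        vd += volumes[t] * kpss[t]
    return kpss, vd / BW
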