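"""Body physiology: tissue volumes, subcompartment splits, and the blood-flow network.

The whole-body model is a set of tissue compartments connected by the blood
circulation.  Each tissue is split into four well-stirred subcompartments —
intracellular water (IW), extracellular water (EW), residual tissue plasma
(TP), and residual tissue blood cells (TC) — while the three blood pools
(arterial, venous, portal vein) carry only plasma and blood-cell
subcompartments.  Pancreas, spleen, and gut drain into the portal vein, which
together with the hepatic artery perfuses the liver; all remaining tissues and
the liver drain into venous blood, which perfuses the lung, which feeds the
arterial pool.

Flow balances maintained at every node of this network::

    Q_liver_p = Q_ha_p + Q_pv_p                 (liver, plasma; cells analog)
    Q_pvp     = Q_pancreas_p + Q_spleen_p + Q_gut_p
    Q_vp      = sum of Q_tp over venous-draining tissues (incl. liver)
    Q_vp + Q_vc = cardiac output

A density of 1 kg/L is assumed for all tissues and blood, so the total of all
subcompartment volumes equals the body weight in kg.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TissuePhysiology",
    "BodyPhysiology",
    "PhysiologyError",
    "load_physiology",
    "validate_flow_balance",
    "TISSUES",
    "PORTAL_TISSUES",
    "DEFAULT_TABLE",
]

#: The 12 tissues of the reference whole-body model.
TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "pancreas", "skin", "spleen",
)

#: Tissues whose venous outflow drains into the portal vein.
PORTAL_TISSUES = ("pancreas", "spleen", "gut")

#: Fraction of residual blood that is blood cells (hematocrit split 45/55).
RESIDUAL_CELL_FRACTION = 0.45

_VOL_TOL = 1e-9
_BAL_TOL = 1e-9


class PhysiologyError(ValueError):
    """Invalid or unbalanced physiology specification."""


@dataclass(frozen=True)
class TissuePhysiology:
    """Volumes (L) and blood flows (L/h) of a single tissue.

    ``Q_tp``/``Q_tc`` are the plasma and blood-cell flow to the tissue; for
    the liver they are the *total* (hepatic artery + portal vein) flows, for
    the lung they equal the total venous plasma/cell flows.
    """

    name: str
    V_iw: float
    V_ew: float
    V_tp: float
    V_tc: float
    Q_tp: float
    Q_tc: float
    #: "venous" or "portal" — where the tissue's outflow goes.
    drains_to: str = "venous"

    @property
    def V_total(self) -> float:
        return self.V_iw + self.V_ew + self.V_tp + self.V_tc

    @property
    def V_residual(self) -> float:
        return self.V_tp + self.V_tc

    @property
    def Q(self) -> float:
        """Total tissue blood flow (plasma + cells), L/h."""
        return self.Q_tp + self.Q_tc

    def validate(self, hct: float) -> None:
        for f in ("V_iw", "V_ew", "V_tp", "V_tc", "Q_tp", "Q_tc"):
            if getattr(self, f) < 0:
                raise PhysiologyError(f"{self.name}: negative {f}")
        if self.drains_to not in ("venous", "portal"):
            raise PhysiologyError(f"{self.name}: bad drains_to {self.drains_to!r}")
        if self.Q > 0 and abs(self.Q_tc / self.Q - hct) > _BAL_TOL:
            raise PhysiologyError(
                f"{self.name}: blood-cell flow fraction {self.Q_tc / self.Q:.6g} "
                f"!= hematocrit {hct}"
            )


@dataclass(frozen=True)
class BodyPhysiology:
    """A validated whole-body physiology.

    Blood-pool volumes are per subcompartment (``V_ap``/``V_ac`` arterial
    plasma/cells, ``V_vp``/``V_vc`` venous, ``V_pvp``/``V_pvc`` portal vein).
    Hepatic arterial flows ``Q_ha_p``/``Q_ha_c`` complement the portal inflow
    so that the liver row's total flows balance.
    """

    tissues: Mapping[str, TissuePhysiology]
    V_ap: float
    V_ac: float
    V_vp: float
    V_vc: float
    V_pvp: float
    V_pvc: float
    BW: float
    CO: float
    Hct: float
    Q_ha_p: float
    Q_ha_c: float
    density: float = 1.0  # kg/L, all tissues and blood

    # ------------------------------------------------------------------ flows
    @property
    def portal_tissues(self) -> tuple[str, ...]:
        return tuple(t for t, tp in self.tissues.items() if tp.drains_to == "portal")

    @property
    def venous_tissues(self) -> tuple[str, ...]:
        """Tissues draining directly to venous blood (everything but lung and
        the portal-draining tissues)."""
        return tuple(
            t for t, tp in self.tissues.items()
            if tp.drains_to == "venous" and t != "lung"
        )

    @property
    def Q_pv_p(self) -> float:
        return sum(self.tissues[t].Q_tp for t in self.portal_tissues)

    @property
    def Q_pv_c(self) -> float:
        return sum(self.tissues[t].Q_tc for t in self.portal_tissues)

    @property
    def Q_vp(self) -> float:
        return sum(self.tissues[t].Q_tp for t in self.venous_tissues)

    @property
    def Q_vc(self) -> float:
        return sum(self.tissues[t].Q_tc for t in self.venous_tissues)

    @property
    def total_volume(self) -> float:
        return (
            sum(t.V_total for t in self.tissues.values())
            + self.V_ap + self.V_ac + self.V_vp + self.V_vc
            + self.V_pvp + self.V_pvc
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if "liver" not in self.tissues or "lung" not in self.tissues:
            raise PhysiologyError("physiology requires at least liver and lung")
        for t in self.tissues.values():
            t.validate(self.Hct)
        for f in ("V_ap", "V_ac", "V_vp", "V_vc", "V_pvp", "V_pvc"):
            if getattr(self, f) < 0:
                raise PhysiologyError(f"negative blood volume {f}")
        residuals = validate_flow_balance(self)
        for eq, r in residuals.items():
            if abs(r) > _BAL_TOL:
                raise PhysiologyError(f"flow balance violated: {eq} residual {r:.3e} L/h")
        dv = self.total_volume - self.BW / self.density
        if abs(dv) > 1e-6:
            raise PhysiologyError(
                f"total volume {self.total_volume:.6f} L != BW/density "
                f"{self.BW / self.density:.6f} L (residual {dv:.3e} L)"
            )

    def with_volumes_scaled(self, k: float) -> "BodyPhysiology":
        """All volumes multiplied by ``k`` (and BW with them); flows unchanged."""
        tissues = {
            name: replace(t, V_iw=t.V_iw * k, V_ew=t.V_ew * k,
                          V_tp=t.V_tp * k, V_tc=t.V_tc * k)
            for name, t in self.tissues.items()
        }
        return replace(
            self, tissues=tissues, BW=self.BW * k,
            V_ap=self.V_ap * k, V_ac=self.V_ac * k,
            V_vp=self.V_vp * k, V_vc=self.V_vc * k,
            V_pvp=self.V_pvp * k, V_pvc=self.V_pvc * k,
        )


def validate_flow_balance(phys: BodyPhysiology) -> dict[str, float]:
    """Residual (L/h) of each flow-balance equation of the circulation network.

    All residuals are zero (within 1e-9) for a valid physiology.  The report
    is informational; :func:`load_physiology` and
    :meth:`BodyPhysiology.validate` raise on violations.
    """
    t = phys.tissues
    res: dict[str, float] = {}
    res["liver_plasma (Q_liver_p = Q_ha_p + Q_pv_p)"] = (
        t["liver"].Q_tp - (phys.Q_ha_p + phys.Q_pv_p)
    )
    res["liver_cells (Q_liver_c = Q_ha_c + Q_pv_c)"] = (
        t["liver"].Q_tc - (phys.Q_ha_c + phys.Q_pv_c)
    )
    res["portal_plasma (Q_pvp = sum portal Q_tp)"] = phys.Q_pv_p - sum(
        t[x].Q_tp for x in phys.portal_tissues
    )
    res["portal_cells (Q_pvc = sum portal Q_tc)"] = phys.Q_pv_c - sum(
        t[x].Q_tc for x in phys.portal_tissues
    )
    res["venous_plasma (Q_vp = sum venous Q_tp)"] = phys.Q_vp - sum(
        t[x].Q_tp for x in phys.venous_tissues
    )
    res["cardiac_output (Q_vp + Q_vc = CO)"] = phys.Q_vp + phys.Q_vc - phys.CO
    res["lung_plasma (Q_lung_p = Q_vp)"] = t["lung"].Q_tp - phys.Q_vp
    res["lung_cells (Q_lung_c = Q_vc)"] = t["lung"].Q_tc - phys.Q_vc
    # arterial node: outflow to arterially perfused tissues + hepatic artery
    q_art_p = sum(
        t[x].Q_tp for x in phys.venous_tissues + phys.portal_tissues if x != "liver"
    ) + phys.Q_ha_p
    res["arterial_plasma (outflow = Q_vp)"] = q_art_p - phys.Q_vp
    return res


_BLOOD_ROWS = ("arterial_blood", "venous_blood", "portal_vein")


def default_table_path() -> str:
    """Path of the packaged reference 70 kg / 300 L/h physiology CSV."""
    return str(importlib.resources.files("permpbpk").joinpath("data/human_70kg.csv"))


DEFAULT_TABLE = default_table_path


def load_physiology(
    table: str | pd.DataFrame | None = None,
    *,
    BW: float = 70.0,
    CO: float = 300.0,
    Hct: float = 0.45,
    slack_tissue: str = "muscle",
) -> BodyPhysiology:
    """Load and validate a physiology table.

    Parameters
    ----------
    table
        CSV path or DataFrame with columns ``tissue, V_total_L,
        V_residual_blood_L, V_ew_L, V_iw_L, Q_blood_L_per_h`` containing the
        12 tissue rows plus ``arterial_blood``/``venous_blood``/``portal_vein``
        volume rows.  ``None`` loads the packaged 70 kg reference table.
    BW, CO, Hct
        Body weight (kg), cardiac output (L/h) and hematocrit the table is
        checked against.  Residual blood is split 45/55 into blood cells and
        plasma; blood *flows* are split by the hematocrit (flowing blood is
        treated as homogeneous).
    slack_tissue
        If print rounding leaves the volume total within 0.5% of ``BW``, the
        intracellular water of this tissue is rescaled to restore exact
        balance (the adjustment is recorded on the returned object via the
        tissue's volumes).
    """
    if table is None:
        table = default_table_path()
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, comment="#")
    df = df.set_index("tissue")

    missing = [t for t in TISSUES if t not in df.index]
    missing += [b for b in _BLOOD_ROWS if b not in df.index]
    if missing:
        raise PhysiologyError(f"physiology table missing rows: {missing}")

    fc = RESIDUAL_CELL_FRACTION
    tissues: dict[str, TissuePhysiology] = {}
    for name in TISSUES:
        r = df.loc[name]
        v_tot, v_res = float(r["V_total_L"]), float(r["V_residual_blood_L"])
        v_ew, v_iw = float(r["V_ew_L"]), float(r["V_iw_L"])
        q = float(r["Q_blood_L_per_h"])
        if min(v_tot, v_res, v_ew, v_iw, q) < 0:
            raise PhysiologyError(f"{name}: negative table entry")
        if abs(v_res + v_ew + v_iw - v_tot) > 1e-6:
            raise PhysiologyError(
                f"{name}: V_residual + V_ew + V_iw = {v_res + v_ew + v_iw:.6g} "
                f"!= V_total {v_tot:.6g}"
            )
        if name == "liver":
            q = q + sum(
                float(df.loc[t, "Q_blood_L_per_h"]) for t in PORTAL_TISSUES
            )
        tissues[name] = TissuePhysiology(
            name=name,
            V_iw=v_iw,
            V_ew=v_ew,
            V_tp=v_res * (1 - fc),
            V_tc=v_res * fc,
            Q_tp=q * (1 - Hct),
            Q_tc=q * Hct,
            drains_to="portal" if name in PORTAL_TISSUES else "venous",
        )
    # repair sub-1e-6 rounding inside each tissue so the 1e-9 invariant holds
    for name, t in tissues.items():
        v_tot = float(df.loc[name, "V_total_L"])
        tissues[name] = replace(t, V_iw=v_tot - t.V_ew - t.V_tp - t.V_tc)

    v_art = float(df.loc["arterial_blood", "V_total_L"])
    v_ven = float(df.loc["venous_blood", "V_total_L"])
    v_pv = float(df.loc["portal_vein", "V_total_L"])
    q_ha = float(df.loc["liver", "Q_blood_L_per_h"])  # hepatic artery blood flow

    phys = BodyPhysiology(
        tissues=tissues,
        V_ap=v_art * (1 - fc), V_ac=v_art * fc,
        V_vp=v_ven * (1 - fc), V_vc=v_ven * fc,
        V_pvp=v_pv * (1 - fc), V_pvc=v_pv * fc,
        BW=BW, CO=CO, Hct=Hct,
        Q_ha_p=q_ha * (1 - Hct), Q_ha_c=q_ha * Hct,
    )

    # rounding repair: rescale the slack tissue's IW if the printed table
    # sums to BW only approximately
    dv = phys.BW / phys.density - phys.total_volume
    if abs(dv) > 1e-6:
        if abs(dv) > 0.005 * phys.BW:
            raise PhysiologyError(
                f"table volumes sum to {phys.total_volume:.4f} L, beyond the "
                f"0.5% rounding-repair band around BW = {phys.BW} kg"
            )
        t = tissues[slack_tissue]
        tissues[slack_tissue] = replace(t, V_iw=t.V_iw + dv)
        phys = replace(phys, tissues=tissues)

    phys.validate()
    return phys
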