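"""Randomized miniature physiologies for fast, exhaustive testing.

A toy body keeps the full circulation topology — gut draining into the
portal vein, portal vein plus hepatic artery perfusing the liver, everything
returning through venous blood and the lung — but with only
``liver + lung + gut + n`` generic tissues, so the liver/portal equations
are always exercised while the state space stays small.  Volumes and flows
are drawn at random and then closed algebraically, so every flow-balance and
density invariant of the full body holds exactly for any seed.
"""

from __future__ import annotations

import numpy as np

from .physiology import BodyPhysiology, TissuePhysiology

__all__ = ["make_toy_body", "toy_body_csv"]


def make_toy_body(
    n_generic_tissues: int = 1,
    seed: int = 0,
    *,
    Hct: float = 0.45,
) -> BodyPhysiology:
    """A balanced random miniature physiology; deterministic given ``seed``.

    Generic tissues are named ``generic_1 ...``; body weight and cardiac
    output come out of the draw (density stays 1 kg/L by construction).
    """
    if n_generic_tissues < 1:
        raise ValueError("need at least one generic tissue")
    rng = np.random.default_rng(seed)

    def split_volume(v_total):
        # residual 2-20%, EW 10-35%, rest IW
        f_res = rng.uniform(0.02, 0.20)
        f_ew = rng.uniform(0.10, 0.35)
        return v_total * f_res, v_total * f_ew, v_total * (1 - f_res - f_ew)

    def tissue(name, v_total, q_blood, drains_to="venous"):
        v_res, v_ew, v_iw = split_volume(v_total)
        return TissuePhysiology(
            name=name, V_iw=v_iw, V_ew=v_ew,
            V_tp=v_res * 0.55, V_tc=v_res * 0.45,
            Q_tp=q_blood * (1 - Hct), Q_tc=q_blood * Hct,
            drains_to=drains_to,
        )

    tissues: dict[str, TissuePhysiology] = {}
    q_gut = rng.uniform(5, 40)
    q_ha = rng.uniform(2, 20)
    tissues["gut"] = tissue("gut", rng.uniform(0.3, 2.0), q_gut, "portal")
    tissues["liver"] = tissue("liver", rng.uniform(0.8, 3.0), q_ha + q_gut)
    q_generic = rng.uniform(5, 60, n_generic_tissues)
    for i, q in enumerate(q_generic, 1):
        tissues[f"generic_{i}"] = tissue(
            f"generic_{i}", rng.uniform(0.5, 20.0), q)
    co = q_ha + q_gut + q_generic.sum()
    tissues["lung"] = tissue("lung", rng.uniform(0.2, 1.0), co)

    v_art, v_ven, v_pv = rng.uniform(0.3, 2.5, 3)
    bw = sum(t.V_total for t in tissues.values()) + v_art + v_ven + v_pv
    body = BodyPhysiology(
        tissues=tissues,
        V_ap=v_art * 0.55, V_ac=v_art * 0.45,
        V_vp=v_ven * 0.55, V_vc=v_ven * 0.45,
        V_pvp=v_pv * 0.55, V_pvc=v_pv * 0.45,
        BW=bw, CO=co, Hct=Hct,
        Q_ha_p=q_ha * (1 - Hct), Q_ha_c=q_ha * Hct,
    )
    body.validate()
    return body


def toy_body_csv(body: BodyPhysiology, path) -> None:
    """Write a toy body in the same CSV dialect as the physiology loader.

    Round-trips through :func:`permpbpk.physiology.load_physiology` only for
    bodies with the full 12-tissue set; for smaller bodies the file is for
    inspection.
    """
    import pandas as pd

    rows = []
    for name, t in body.tissues.items():
        q = t.Q
        if name == "liver":
            q = body.Q_ha_p + body.Q_ha_c
        rows.append({
            "tissue": name, "V_total_L": t.V_total,
            "V_residual_blood_L": t.V_residual, "V_ew_L": t.V_ew,
            "V_iw_L": t.V_iw, "Q_blood_L_per_h": q,
        })
    for name, v in (
        ("arterial_blood", body.V_ap + body.V_ac),
        ("venous_blood", body.V_vp + body.V_vc),
        ("portal_vein", body.V_pvp + body.V_pvc),
    ):
        rows.append({"tissue": name, "V_total_L": v, "V_residual_blood_L": v,
                     "V_ew_L": 0.0, "V_iw_L": 0.0, "Q_blood_L_per_h": 0.0})
    pd.DataFrame(rows).to_csv(path, index=False)
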