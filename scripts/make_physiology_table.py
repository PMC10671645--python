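#!/usr/bin/env python
"""Regenerate the packaged reference physiology CSV (70 kg / 300 L/h).

Volumes are reference-male organ volumes (V_total includes the tissue's
residual blood); residual-blood and extracellular-water fractions come from
the standard compilations; flows are fractions of cardiac output, rescaled
proportionally so the venous return balances 300 L/h exactly; muscle volume
closes the 70 kg total; circulating blood (5.6 L minus residual) is split
venous:arterial 2:1 plus a 0.25 L portal vein.
"""

from pathlib import Path

CO, HCT, BW, BLOOD = 300.0, 0.45, 70.0, 5.6

# tissue: (V_total_L, f_residual, f_ew, Q_frac_of_CO [liver: hepatic artery])
ROWS = {
    "adipose":  (14.5,  0.010,  0.135, 0.050),
    "bone":     (10.5,  0.041,  0.100, 0.050),
    "brain":    (1.45,  0.037,  0.162, 0.120),
    "gut":      (1.17,  0.024,  0.282, 0.150),
    "heart":    (0.33,  0.061,  0.320, 0.040),
    "kidney":   (0.31,  0.105,  0.273, 0.190),
    "liver":    (1.80,  0.115,  0.161, 0.065),
    "lung":     (0.50,  0.2625, 0.336, 1.000),
    "muscle":   (None,  0.026,  0.079, 0.170),   # slack tissue closes 70 L
    "pancreas": (0.14,  0.180,  0.120, 0.010),
    "skin":     (3.30,  0.019,  0.382, 0.050),
    "spleen":   (0.15,  0.282,  0.207, 0.030),
}
PORTAL = ("pancreas", "spleen", "gut")
OUT = Path(__file__).resolve().parents[1] / "src/permpbpk/data/human_70kg.csv"


def main() -> None:
    v_known = sum(v for v, *_ in ROWS.values() if v is not None)
    f_r_musc = ROWS["muscle"][1]
    resid_known = sum(v * fr for v, fr, *_ in ROWS.values() if v is not None)
    # solve muscle volume: tissues + (BLOOD - residual) pools = BW
    v_m = (BW - BLOOD - v_known + resid_known) / (1 - f_r_musc)
    ROWS["muscle"] = (v_m,) + ROWS["muscle"][1:]
    pools = BLOOD - (resid_known + f_r_musc * v_m)
    v_pv = 0.25
    v_art = (pools - v_pv) / 3.0
    v_ven = 2.0 * v_art

    q = {t: r[3] * CO for t, r in ROWS.items() if t != "lung"}
    venous = (sum(qv for t, qv in q.items() if t not in PORTAL and t != "liver")
              + q["liver"] + sum(q[t] for t in PORTAL))
    scale = CO / venous
    q = {t: v * scale for t, v in q.items()}
    q["lung"] = CO

    lines = [
        "# Reference adult human physiology: 70 kg body weight, 300 L/h cardiac output,",
        "# hematocrit 0.45, density 1 kg/L for all tissues and blood.",
        "# V_total_L includes the tissue's residual blood. For the liver the flow column",
        "# is the hepatic ARTERIAL blood flow; portal inflow (pancreas+spleen+gut) is",
        "# added by the loader. Lung flow is the cardiac output. Blood-pool rows carry",
        "# only a total volume (split 45/55 cells/plasma by the loader).",
        "tissue,V_total_L,V_residual_blood_L,V_ew_L,V_iw_L,Q_blood_L_per_h",
    ]
    total = 0.0
    for t in sorted(ROWS):
        v, fr, few, _ = ROWS[t]
        vr, vew = v * fr, v * few
        total += v
        lines.append(f"{t},{v:.17g},{vr:.17g},{vew:.17g},{v - vr - vew:.17g},{q[t]:.17g}")
    for name, v in (("arterial_blood", v_art), ("venous_blood", v_ven),
                    ("portal_vein", v_pv)):
        total += v
        lines.append(f"{name},{v:.17g},{v:.17g},0,0,0")
    assert abs(total - BW) < 1e-9, total
    OUT.write_text("\n".join(lines) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
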