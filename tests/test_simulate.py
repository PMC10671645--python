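"""Integrator vs closed forms, derived metrics, pseudo-steady-state logic."""

import numpy as np
import pytest

from permpbpk import (
    CompoundParameters,
    DoseRegimen,
    assemble_system,
    detect_pseudo_steady_state,
    kp_profile,
    kpss_closed_form,
    simulate,
    solution_expm,
    tissue_concentration,
    vd_profile,
    vdss_closed_form,
)
from permpbpk.simulate import ConvergenceError, terminal_mode


@pytest.fixture(scope="module")
def closed_system(phys):
    return assemble_system(phys, CompoundParameters.from_folds(phys, ps_fold=10.0))


@pytest.fixture(scope="module")
def hepatic_system(phys):
    """Open system: hepatic IW clearance equal to hepatic blood flow."""
    cp = CompoundParameters.from_folds(
        phys, ps_fold=1.0, cl_met_fold=1.0, cl_met_site="iw",
        cl_met_tissues="liver")
    return assemble_system(phys, cp)


BOLUS = DoseRegimen("iv_bolus", dose=100.0)


def test_closed_system_equilibrates_uniformly(closed_system):
    res = simulate(closed_system, BOLUS, t_end=1000.0)
    final = res.C[:, -1]
    assert final == pytest.approx(np.full(54, 100.0 / 70.0), rel=1e-6)
    assert res.diagnostics["mass_drift_rel"] < 1e-6


@pytest.mark.parametrize("regimen", [
    BOLUS,
    DoseRegimen("iv_infusion", rate=100.0),
    DoseRegimen("po", dose=100.0, ka=1.0),
], ids=["bolus", "infusion", "po"])
def test_integrator_matches_matrix_exponential(hepatic_system, regimen):
    times = np.geomspace(0.01, 30.0, 20)
    res = simulate(hepatic_system, regimen, t_end=30.0,
                   grid=np.concatenate([[0.0], times]))
    oracle = solution_expm(hepatic_system, regimen, times)
    sim = res.C[:, np.isin(res.t, times)]
    scale = np.abs(oracle).max(axis=0)  # per-time scale
    assert np.abs(sim - oracle).max(axis=0) / scale == pytest.approx(
        np.zeros(times.size), abs=1e-6)


def test_zero_dose_gives_zero_trajectory(closed_system):
    res = simulate(closed_system, DoseRegimen("iv_bolus", dose=0.0), t_end=5.0)
    assert np.all(res.C == 0.0)


def test_nonpositive_horizon_rejected(closed_system):
    with pytest.raises(ValueError):
        simulate(closed_system, BOLUS, t_end=0.0)


def test_tissue_concentration_is_volume_weighted_mean(closed_system):
    res = simulate(closed_system, BOLUS, t_end=1.0)
    idx = closed_system.tissue_indices("kidney")
    V = closed_system.volumes[idx]
    manual = (V @ res.C[idx]) / V.sum()
    assert tissue_concentration(res, "kidney") == pytest.approx(manual)
    # uniform late concentrations -> tissue concentration equals C_vp
    res_long = simulate(closed_system, BOLUS, t_end=500.0)
    assert tissue_concentration(res_long, "adipose")[-1] == pytest.approx(
        res_long.C_vp[-1], rel=1e-6)
    with pytest.raises(KeyError):
        tissue_concentration(res, "thymus")


def test_initial_bolus_vd_is_venous_plasma_volume(closed_system):
    res = simulate(closed_system, BOLUS, t_end=1.0)
    vd = vd_profile(res)
    v_vp = closed_system.volumes[closed_system.i_vp]
    assert vd[0] == pytest.approx(v_vp / 70.0, rel=1e-9)


def test_closed_system_kp_and_vd_reach_unity(closed_system):
    res = simulate(closed_system, BOLUS, t_end=20.0)
    for tissue in ("lung", "kidney", "adipose", "muscle"):
        assert kp_profile(res, tissue)[-1] == pytest.approx(1.0, abs=1e-3)
    pss = detect_pseudo_steady_state(res)
    assert pss.Vdss == pytest.approx(1.0, rel=1e-3)
    assert vdss_closed_form(closed_system, BOLUS) == pytest.approx(1.0, rel=1e-9)
    # without the portal-vein pool the null case misses 1 by ~ V_pv / BW
    lit = vdss_closed_form(closed_system, BOLUS, include_portal=False)
    assert lit == pytest.approx(1.0 - 0.25 / 70.0, abs=1e-4)


def test_open_system_kp_pattern_with_hepatic_metabolism(hepatic_system):
    kpss = kpss_closed_form(hepatic_system, BOLUS)
    assert kpss["liver"] < 1.0
    for tissue, v in kpss.items():
        if tissue != "liver":
            assert v > 1.0, tissue
    vdss = vdss_closed_form(hepatic_system, BOLUS)
    assert vdss > 1.0


def test_simulated_pss_matches_eigenmode_oracle(hepatic_system):
    res = simulate(hepatic_system, BOLUS, t_end=80.0, atol=1e-16)
    pss = detect_pseudo_steady_state(res)
    oracle = vdss_closed_form(hepatic_system, BOLUS)
    assert pss.Vdss == pytest.approx(oracle, rel=5e-3)
    tm = terminal_mode(hepatic_system, BOLUS)
    assert pss.lambda_terminal == pytest.approx(tm.lam, rel=1e-2)


def test_infusion_elimination_balances_rate_at_steady_state(hepatic_system):
    reg = DoseRegimen("iv_infusion", rate=100.0)
    res = simulate(hepatic_system, reg, t_end=1000.0)
    C_end = res.C[:, -1]
    elimination = float(hepatic_system.cl_met_eff @ C_end)
    assert elimination == pytest.approx(100.0, rel=1e-3)
    pss = detect_pseudo_steady_state(res)
    assert pss.Vdss == pytest.approx(vdss_closed_form(hepatic_system, reg),
                                     rel=1e-4)


def test_dose_invariance_of_kp_and_vd(hepatic_system):
    lo = simulate(hepatic_system, DoseRegimen("iv_bolus", dose=1.0), t_end=30.0)
    hi = simulate(hepatic_system, DoseRegimen("iv_bolus", dose=100.0), t_end=30.0)
    assert vd_profile(lo)[1:] == pytest.approx(vd_profile(hi)[1:], rel=1e-6)
    assert kp_profile(lo, "muscle")[1:] == pytest.approx(
        kp_profile(hi, "muscle")[1:], rel=1e-6)
    assert hi.C == pytest.approx(100.0 * lo.C, rel=1e-6)


def test_missing_plateau_raises(hepatic_system):
    res = simulate(hepatic_system, BOLUS, t_end=0.5)
    with pytest.raises(ConvergenceError):
        detect_pseudo_steady_state(res)


def test_infusion_into_closed_system_has_no_steady_state(closed_system):
    with pytest.raises(ConvergenceError):
        vdss_closed_form(closed_system, DoseRegimen("iv_infusion", rate=10.0))


def test_write_results_roundtrip(tmp_path, hepatic_system):
    import json

    from permpbpk.simulate import write_results

    res = simulate(hepatic_system, BOLUS, t_end=60.0, atol=1e-16)
    write_results(res, tmp_path)
    summary = json.loads((tmp_path / "summary.json").read_text())
    assert summary["Vdss_L_per_kg"] == pytest.approx(
        vdss_closed_form(hepatic_system, BOLUS), rel=5e-3)
    import pandas as pd

    conc = pd.read_csv(tmp_path / "concentrations.csv")
    assert set(conc.columns) == {"time_h", "compartment", "subcompartment",
                                 "conc_mg_per_L"}
    assert conc["compartment"].nunique() == 15  # 12 tissues + 3 pools
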