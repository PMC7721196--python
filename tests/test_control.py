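import math

import numpy as np
import pytest

from dualloop.control import (
    ControlInput,
    MPCConfig,
    ShiftProtocol,
    canonical_inputs,
    canonical_protocol,
    mpc_solve_horizon,
    phase_step,
    run_mpc,
    settling_time,
    wrap_phase,
)


def test_wrap_phase_range_and_fixed_points():
    grid = np.linspace(-10, 10, 201)
    w = wrap_phase(grid)
    assert np.all(w > -np.pi - 1e-12) and np.all(w <= np.pi + 1e-12)
    assert wrap_phase(0.3) == pytest.approx(0.3)
    assert wrap_phase(2 * np.pi + 0.3) == pytest.approx(0.3)
    assert wrap_phase(-0.3) == pytest.approx(-0.3)


def test_control_input_validation_and_modulation(params):
    with pytest.raises(ValueError):
        ControlInput("bad", (("v_deg_P", 2),))
    with pytest.raises(ValueError):
        ControlInput("bad", (("v_deg_P", -1),), u_max=0.0)
    kl = ControlInput("KL001", (("v_deg_C1N", -1), ("v_deg_C2N", -1)), 0.5)
    mod = kl.modulated(params, 0.4)
    assert mod["v_deg_C1N"] == pytest.approx(0.6 * params["v_deg_C1N"])
    assert mod["v_deg_C2N"] == pytest.approx(0.6 * params["v_deg_C2N"])
    assert mod["v_deg_P"] == params["v_deg_P"]
    with pytest.raises(ValueError):
        kl.modulated(params, 0.6)


def test_canonical_input_library_layout():
    lib = canonical_inputs()
    assert dict(lib["KL001"].targets) == {"v_deg_C1N": -1, "v_deg_C2N": -1}
    assert dict(lib["Longdaysin"].targets) == {"v_deg_P": -1}
    assert dict(lib["FBXW7a"].targets) == {"v_deg_REV": +1}
    assert dict(lib["GSK3b-inhibitor"].targets) == {"v_deg_C2": +1,
                                                    "v_deg_REV": -1}
    assert set(dict(lib["KK-S6"].targets)) == {"K_txn_REV"}
    assert canonical_inputs(kk_s6_sign=-1)["KK-S6"].targets[0][1] == -1
    assert all(inp.u_max == 0.5 for inp in lib.values())


def test_phase_step_free_running_is_exact():
    omega = 2 * np.pi / 24.0
    phi = phase_step(1.0, [0.0], [lambda p: 1.23], omega, 2.0)
    assert phi == pytest.approx((1.0 + omega * 2.0) % (2 * np.pi), abs=1e-12)


def test_phase_step_constant_gain_closed_form():
    omega, c, u, dt = 0.25, 0.1, 0.4, 2.0
    phi = phase_step(0.5, [u], [lambda p: c], omega, dt)
    assert phi == pytest.approx(0.5 + dt * (omega + c * u), abs=1e-9)


def test_protocol_offsets_and_validation():
    prot = canonical_protocol()
    assert prot.offset(0.0) == 0.0
    assert prot.offset(12.0) == 5.0
    assert prot.offset(50.0) == 5.0
    assert prot.offset(84.0) == -6.0
    assert prot.segment_onsets() == [12.0, 84.0]
    with pytest.raises(ValueError):
        ShiftProtocol(schedule=((10.0, 1.0), (5.0, 2.0)), duration=50)


def test_horizon_zero_error_yields_zero_input():
    omega = 2 * np.pi / 24
    cfg = MPCConfig(input_weight=1e-3)
    ref = lambda t: omega * t
    u = mpc_solve_horizon(0.0, 0.0, ref, [lambda p: 0.3], [0.5], cfg, omega)
    assert u.shape == (3, 1)
    assert np.all(u <= 1e-6)


def test_one_step_horizon_matches_brute_force():
    """Single input, one step, constant gain: compare to a dense scan."""
    omega = 2 * np.pi / 24
    cfg = MPCConfig(horizon=1, input_weight=1e-3)
    gain = 0.2
    phi0, err0 = 1.0, -0.6                      # model behind the reference
    ref = lambda t: phi0 + omega * t - err0

    def brute(u):
        phi = phi0 + cfg.timestep * (omega + gain * u)
        e = float(wrap_phase(phi - ref(cfg.timestep)))
        return e * e + cfg.input_weight * u

    grid = np.linspace(0, 0.5, 20001)
    u_star = grid[np.argmin([brute(u) for u in grid])]
    u = mpc_solve_horizon(phi0, 0.0, ref, [lambda p: gain], [0.5], cfg,
                          omega)
    assert u[0, 0] == pytest.approx(u_star, abs=1e-3)


def test_settling_time_edge_cases():
    t = np.arange(0.0, 10.0, 1.0)
    assert settling_time(t, np.zeros(10), 0.1) == 0.0
    assert math.isinf(settling_time(t, np.full(10, 1.0), 0.1))
    # linear decay crossing the band between samples
    err = np.maximum(1.0 - 0.2 * t, 0.0)
    assert settling_time(t, err, 0.1) == pytest.approx(4.5, abs=1e-9)
    assert settling_time(t, err, 0.1, origin=1.0) == pytest.approx(3.5)


def test_zero_offset_protocol_tracks_with_negligible_input(params, analysis):
    prot = ShiftProtocol(schedule=((0.0, 0.0),), duration=24.0)
    lib = canonical_inputs()
    res = run_mpc(params, [lib["KL001"]], prot, analysis=analysis)
    assert np.all(np.abs(res.error()) < analysis.lc.omega * 0.5)
    assert res.inputs.max() < 0.05
    # bounds respected
    assert res.inputs.min() >= 0.0 and res.inputs.max() <= 0.5 + 1e-9


def test_linear_validation_zero_perturbation(params, analysis):
    from dualloop.control import validate_linear_approximation

    res = validate_linear_approximation(params, target_params=["v_deg_P"],
                                        n_phases=4, rel_change=0.0,
                                        analysis=analysis)
    assert np.allclose(res["predicted"], 0.0, atol=1e-9)
    assert np.allclose(res["observed"], 0.0, atol=2e-3)
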