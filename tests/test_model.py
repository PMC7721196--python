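import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualloop import derivatives
from dualloop.model import SPECIES, ebox_rate, rore_rate

conc = st.floats(min_value=0.0, max_value=50.0,
                 allow_nan=False, allow_infinity=False)


def test_ebox_rate_reduces_to_v_over_K_at_zero_repressors():
    assert ebox_rate(1.0, 1.0, 0.5, 0.0, 0.0, 0.0) == pytest.approx(1.0)


def test_ebox_rate_is_linear_in_v():
    args = dict(K=1.0, K_b=0.5, B=1.0, C1N=1.0, C2N=0.5)
    assert ebox_rate(v=2.0, **args) == pytest.approx(2 * ebox_rate(v=1.0, **args))


def test_ebox_rate_matches_direct_arithmetic():
    # Per-row constants; oracle is the expression evaluated independently
    v, K, K_b, B, C1N, C2N = 0.26726, 0.33468, 0.00117, 1.0, 0.5, 0.5
    expected = 0.26726 / (0.33468 + 0.00117 * 1.0 + 0.5 + 0.5)
    assert ebox_rate(v, K, K_b, B, C1N, C2N) == pytest.approx(expected,
                                                             rel=1e-15)


def test_ebox_rate_rejects_nonpositive_K_and_negative_args():
    with pytest.raises(ValueError):
        ebox_rate(1.0, 0.0, 0.5, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        ebox_rate(1.0, 1.0, 0.5, -1.0, 0.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(B=conc, C1N=conc, C2N=conc, delta=conc)
def test_ebox_rate_nonincreasing_in_each_repressor(B, C1N, C2N, delta):
    base = ebox_rate(1.0, 0.3, 0.01, B, C1N, C2N)
    assert ebox_rate(1.0, 0.3, 0.01, B + delta, C1N, C2N) <= base + 1e-12
    assert ebox_rate(1.0, 0.3, 0.01, B, C1N + delta, C2N) <= base + 1e-12
    assert ebox_rate(1.0, 0.3, 0.01, B, C1N, C2N + delta) <= base + 1e-12


def test_rore_rate_basal_and_repression_limit():
    assert rore_rate(0.0, 0.0, 5.0, 2.0, 1.0, 1.0) == pytest.approx(2.0)
    assert rore_rate(0.0, 1e9, 5.0, 2.0, 1.0, 1.0) == pytest.approx(0.0,
                                                                    abs=1e-7)


def test_rore_rate_matches_direct_arithmetic():
    v1, v2, K1, K2 = 1.81951, 2.01031, 1.72406, 1.07518
    expected = (v1 * 1.0 + v2) / (1.0 + K1 * 1.0 + K2 * 1.0)
    assert rore_rate(1.0, 1.0, v1, v2, K1, K2) == pytest.approx(expected,
                                                                rel=1e-15)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(ROR=conc, REV=conc, delta=conc)
def test_rore_rate_nonincreasing_in_REV(ROR, REV, delta):
    v1, v2, K1, K2 = 1.81951, 2.01031, 1.72406, 1.07518
    assert (rore_rate(ROR, REV + delta, v1, v2, K1, K2)
            <= rore_rate(ROR, REV, v1, v2, K1, K2) + 1e-12)


def _oracle_derivatives(x, p):
    """Independent term-by-term transcription of the rate equations."""
    s = dict(zip(SPECIES, x))
    ebox_den = p["K_b"] * s["B"] + s["C1N"] + s["C2N"]

    def mm(v, K, conc):
        return v * conc / (K + conc)

    d = {}
    d["p"] = p["v_txn_p"] / (p["K_txn_p"] + ebox_den) \
        - mm(p["v_deg_p"], p["K_deg_p"], s["p"])
    d["c1"] = p["v_txn_c1"] / (p["K_txn_c"] + ebox_den) \
        - mm(p["v_deg_c1"], p["K_deg_c"], s["c1"])
    d["c2"] = p["v_txn_c2"] / (p["K_txn_c"] + ebox_den) \
        - mm(p["v_deg_c2"], p["K_deg_c"], s["c2"])
    d["ror"] = p["v_txn_ror"] / (p["K_txn_ror"] + ebox_den) \
        - mm(p["v_deg_ror"], p["K_deg_ror"], s["ror"])
    d["rev"] = p["v_txn_rev"] / (p["K_txn_rev"] + ebox_den) \
        - mm(p["v_deg_rev"], p["K_deg_rev"], s["rev"])
    bind1 = p["v_a_CP"] * s["P"] * s["C1"] - p["v_d_CP"] * s["C1N"]
    bind2 = p["v_a_CP"] * s["P"] * s["C2"] - p["v_d_CP"] * s["C2N"]
    d["P"] = p["K_tln_p"] * s["p"] - mm(p["v_deg_P"], p["K_deg_P"], s["P"]) \
        - bind1 - bind2
    d["C1"] = p["K_tln_c1"] * s["c1"] \
        - mm(p["v_deg_C1"], p["K_deg_C"], s["C1"]) - bind1
    d["C2"] = p["K_tln_c2"] * s["c2"] \
        - mm(p["v_deg_C2"], p["K_deg_C"], s["C2"]) - bind2
    d["ROR"] = p["K_tln_ror"] * s["ror"] \
        - mm(p["v_deg_ROR"], p["K_deg_ROR"], s["ROR"])
    d["REV"] = p["K_tln_rev"] * s["rev"] \
        - mm(p["v_deg_REV"], p["K_deg_REV"], s["REV"])
    d["b"] = (p["v_txn_ROR"] * s["ROR"] + p["v_txn_REV"]) \
        / (1 + p["K_txn_REV"] * s["REV"] + p["K_txn_ROR"] * s["ROR"]) \
        - mm(p["v_deg_b"], p["K_deg_b"], s["b"])
    d["B"] = p["K_tln_b"] * s["b"] - mm(p["v_deg_B"], p["K_deg_B"], s["B"])
    nuc_den = p["K_deg_CP"] + s["C1N"] + s["C2N"]
    d["C1N"] = -p["v_deg_C1N"] * s["C1N"] / nuc_den + bind1
    d["C2N"] = -p["v_deg_C2N"] * s["C2N"] / nuc_den + bind2
    return np.array([d[name] for name in SPECIES])


def test_derivatives_at_origin(params):
    dx = derivatives(np.zeros(14), params)
    assert dx[0] == pytest.approx(params["v_txn_p"] / params["K_txn_p"])
    assert dx[12] == 0.0 and dx[13] == 0.0      # nuclear complexes
    assert dx[11] == 0.0                         # BMAL1: no mRNA, no decay


def test_derivatives_rejects_negative_state(params):
    x = np.zeros(14)
    x[3] = -1e-3
    with pytest.raises(ValueError):
        derivatives(x, params)


def test_derivatives_agree_with_term_by_term_oracle(params, rng):
    for _ in range(100):
        x = rng.uniform(0.0, 5.0, size=14)
        got = derivatives(x, params)
        want = _oracle_derivatives(x, params)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)


def test_symbolic_rhs_matches_hand_coded(params, rng):
    """The sympy-generated RHS (used for Jacobians) equals the model RHS."""
    from dualloop._symbolic import jacobian_functions

    f_fn, _, _ = jacobian_functions()
    for _ in range(20):
        x = rng.uniform(0.0, 5.0, size=14)
        np.testing.assert_allclose(f_fn(x, params.as_array()),
                                   derivatives(x, params), rtol=1e-12)
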