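import numpy as np
import pytest

from dualloop import find_limit_cycle
from dualloop.params import CANONICAL_PARAM_NAMES, rescale_time
from dualloop.sensitivity import (
    NEGATIVE_LOOP_PARAMS,
    POSITIVE_LOOP_PARAMS,
    CycleSensitivity,
    finite_difference_period_sensitivity,
    loop_of,
)

# subset spanning both loops and three orders of sensitivity magnitude;
# the full 45-parameter oracle comparison runs in the acceptance suite
FD_SUBSET = ["K_tln_p", "K_tln_b", "v_deg_C1N", "v_txn_p",
             "v_deg_REV", "K_txn_rev"]


def test_loop_partition_covers_all_published_parameters():
    assert len(NEGATIVE_LOOP_PARAMS) + len(POSITIVE_LOOP_PARAMS) == 45
    assert set(NEGATIVE_LOOP_PARAMS) | set(POSITIVE_LOOP_PARAMS) \
        == set(CANONICAL_PARAM_NAMES)
    assert loop_of("v_deg_C1N") == "negative"
    assert loop_of("K_tln_b") == "positive"
    with pytest.raises(KeyError):
        loop_of("nope")


def test_period_sensitivity_signs(analysis):
    # increased BMAL1 lengthens, increased PER shortens the period
    assert analysis.period_sensitivity("K_tln_b") > 0
    assert analysis.period_sensitivity("K_tln_p") < 0
    # Cry mRNA degradation: faster Cry1 turnover shortens, Cry2 lengthens
    assert analysis.period_sensitivity("v_deg_c1") < 0
    assert analysis.period_sensitivity("v_deg_c2") > 0


@pytest.mark.parametrize("param", FD_SUBSET)
def test_period_sensitivity_matches_finite_difference(params, lc, analysis,
                                                      param):
    var = analysis.period_sensitivity(param)
    fd = finite_difference_period_sensitivity(
        params, param, rel_step=1e-3, x0=lc.anchor, burn_in=300.0)
    assert var == pytest.approx(fd, rel=0.05)


@pytest.mark.parametrize("param,species",
                         [("v_txn_p", "p"), ("K_tln_b", "B"),
                          ("v_deg_C1N", "c1"), ("v_deg_rev", "REV")])
def test_amplitude_sensitivity_matches_finite_difference(params, lc,
                                                         analysis, param,
                                                         species):
    var = analysis.amplitude_sensitivity(param, species)
    h = 1e-3 * params[param]
    lo = find_limit_cycle(params.replace(**{param: params[param] - h}),
                          x0=lc.anchor, burn_in=300.0)
    hi = find_limit_cycle(params.replace(**{param: params[param] + h}),
                          x0=lc.anchor, burn_in=300.0)
    fd = (hi.species(species).max() - lo.species(species).max()) / (2 * h)
    assert var == pytest.approx(fd, rel=0.05, abs=1e-4)


def test_mrna_and_protein_amplitude_sensitivities_correlate(analysis):
    """Amplitude responses of an mRNA and its protein track each other."""
    for mrna, prot in [("p", "P"), ("b", "B"), ("ror", "ROR")]:
        a = np.array([analysis.amplitude_sensitivity(q, mrna)
                      for q in CANONICAL_PARAM_NAMES])
        b = np.array([analysis.amplitude_sensitivity(q, prot)
                      for q in CANONICAL_PARAM_NAMES])
        assert np.corrcoef(a, b)[0, 1] > 0.5


@pytest.mark.parametrize("param", FD_SUBSET)
def test_prc_period_integral_identity(analysis, param):
    """∫₀ᵀ PRC(φ(t)) dt = −(2π/T)·dT/dp, adjoint vs boundary-value route."""
    lc = analysis.lc
    curve = analysis.parametric_prc(param, n_phases=512)
    integral = np.trapezoid(np.append(curve.values, curve.values[:1]),
                            np.append(curve.phases, 2 * np.pi)) / lc.omega
    expected = -(2 * np.pi / lc.period) * analysis.period_sensitivity(param)
    assert integral == pytest.approx(expected, rel=0.05, abs=1e-6)


def test_prc_grid_refinement_consistency(analysis):
    c1 = analysis.parametric_prc("v_deg_C1N", n_phases=128)
    c2 = analysis.parametric_prc("v_deg_C1N", n_phases=256)
    scale = np.abs(c2.values).max()
    assert np.abs(c2(c1.phases) - c1.values).max() < 0.01 * scale


def test_prc_lobe_areas_have_opposite_signs(analysis):
    pos, neg = analysis.parametric_prc("v_deg_C1N").lobe_areas()
    assert pos >= 0 and neg <= 0


def test_period_sensitivity_time_rescaling(params, analysis):
    """Scaling all rate parameters by k: dT/d(rate) shrinks by k²,
    dT/d(Michaelis constant) by k."""
    k = 2.0
    fast = CycleSensitivity(rescale_time(params, k))
    assert fast.period_sensitivity("K_tln_p") == pytest.approx(
        analysis.period_sensitivity("K_tln_p") / k ** 2, rel=0.01)
    assert fast.period_sensitivity("K_txn_p") == pytest.approx(
        analysis.period_sensitivity("K_txn_p") / k, rel=0.01)


def test_nonoscillatory_set_is_rejected(params):
    from dualloop import apply_knockout

    with pytest.raises(ValueError):
        CycleSensitivity(apply_knockout(params, ["Cry1", "Cry2"]))
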