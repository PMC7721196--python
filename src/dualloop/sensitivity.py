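"""Local sensitivity analysis of the clock limit cycle.

Three infinitesimal quantities are computed about a parameter set:

* **period sensitivity** dT/dp_i — how the free-running period responds to
  a parameter change;
* **amplitude sensitivity** dA_x/dp_i — how the peak value of species *x*
  responds, evaluated at that species' peak (where the timing contribution
  vanishes to first order);
* **infinitesimal parametric phase response curve** PRC_{p_i}(φ) =
  ∂²φ/∂t∂p_i — the phase-velocity response to a parameter change as a
  function of the phase at which it is applied.

Implementation: the one-period variational (monodromy) problem is solved
with a piecewise-exponential (Magnus) propagator on a fine phase grid,
using symbolically generated Jacobians.  Period and amplitude
sensitivities come from the periodicity boundary-value problem on the
Poincaré section; the ipPRC comes from the adjoint (left Floquet)
eigenfunction Q(t) of the monodromy matrix, normalised so Q·f = ω, via
PRC_{p_i}(φ(t)) = Q(t)·∂f/∂p_i(x(t)).  The two routes satisfy the
integral identity ∫₀ᵀ PRC_{p_i}(φ(t)) dt = −(2π/T)·dT/dp_i, which is used
as an internal consistency check in the test suite, with plain
finite-difference re-simulation as the external oracle.

The per-loop partition of the published parameters (negative Per/Cry loop
vs positive Ror/Rev-erbα/Bmal1 loop) supports the loop-comparison summary:
period sensitivities correlate with the signed areas of the ipPRC lobes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
from scipy.linalg import expm

from ._symbolic import jacobian_functions
from .model import SPECIES_INDEX
from .params import CANONICAL_PARAM_NAMES, PARAM_NAMES, ParameterSet
from .simulate import LimitCycle, find_limit_cycle

_PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Parameters of the negative (Per/Cry/PER:CRY) feedback loop.  K_b is
#: counted here: it is an Ebox-promoter constant of the repressor-gene
#: transcription equations, alongside the other K_txn constants.
NEGATIVE_LOOP_PARAMS: tuple[str, ...] = (
    "v_txn_p", "K_txn_p", "K_b", "v_deg_p", "K_deg_p",
    "v_txn_c1", "v_txn_c2", "K_txn_c", "v_deg_c1", "v_deg_c2", "K_deg_c",
    "K_tln_p", "v_deg_P", "K_deg_P", "v_a_CP", "v_d_CP",
    "v_deg_C1", "K_deg_C", "v_deg_C2",
    "v_deg_C1N", "K_deg_CP", "v_deg_C2N",
)

#: Parameters of the positive (Ror/Rev-erbα/Bmal1) feedback loop.
POSITIVE_LOOP_PARAMS: tuple[str, ...] = tuple(
    name for name in CANONICAL_PARAM_NAMES
    if name not in NEGATIVE_LOOP_PARAMS
)


def loop_of(param: str) -> str:
    """Loop membership ('negative' or 'positive') of a published parameter."""
    if param in NEGATIVE_LOOP_PARAMS or param in ("K_tln_c1", "K_tln_c2"):
        return "negative"
    if param in POSITIVE_LOOP_PARAMS:
        return "positive"
    raise KeyError(f"unknown parameter {param!r}")


@dataclass(frozen=True)
class PRCCurve:
    """An ipPRC on a uniform phase grid over [0, 2π)."""

    param: str
    phases: np.ndarray             # uniform, length n, in [0, 2π)
    values: np.ndarray             # rad / (h · parameter unit)

    def __post_init__(self):
        if len(self.phases) < 100:
            raise ValueError("PRC grid needs at least 100 points")

    def __call__(self, phi):
        """Periodic linear interpolation of the curve at phase(s) ``phi``."""
        phi = np.mod(phi, 2 * np.pi)
        ext_p = np.append(self.phases, 2 * np.pi)
        ext_v = np.append(self.values, self.values[:1])
        return np.interp(phi, ext_p, ext_v)

    def lobe_areas(self) -> tuple[float, float]:
        """Signed areas (positive lobe, negative lobe) in phase: ∫PRC± dφ."""
        dphi = 2 * np.pi / len(self.phases)
        pos = float(np.sum(np.clip(self.values, 0.0, None)) * dphi)
        neg = float(np.sum(np.clip(self.values, None, 0.0)) * dphi)
        return pos, neg


class CycleSensitivity:
    """All local sensitivities of one limit cycle, computed jointly.

    One variational sweep over the cycle yields the monodromy matrix, the
    parameter-inhomogeneous solutions for every parameter, and the adjoint
    eigenfunction; individual sensitivities are then cheap lookups.

    Parameters
    ----------
    params:
        Parameter set (must be oscillatory).
    lc:
        Optionally a precomputed limit cycle for ``params``.
    n_steps:
        Grid resolution of the exponential propagator (default 8192).
    """

    def __init__(self, params: ParameterSet, lc: Optional[LimitCycle] = None,
                 n_steps: int = 8192):
        if lc is None:
            lc = find_limit_cycle(params)
        if lc is None:
            raise ValueError("parameter set is non-oscillatory")
        self.params = params
        self.lc = lc
        self.n_steps = int(n_steps)
        self._computed = False

    # -- the variational sweep -------------------------------------------
    def _compute(self) -> None:
        if self._computed:
            return
        f_fn, jx_fn, jp_fn = jacobian_functions()
        lc, N = self.lc, self.n_steps
        T = lc.period
        h = T / N
        pvec = self.params.as_array()
        npar = len(PARAM_NAMES)

        t_grid = np.linspace(0.0, T, N + 1)
        x_grid = lc.state_at(t_grid)            # (N+1, 14)
        x_mid = lc.state_at(t_grid[:-1] + h / 2)

        # step propagators E_k = expm(h J(x_mid_k)) and step inhomogeneous
        # contributions via the block-augmented exponential
        E = np.empty((N, 14, 14))
        M_hist = np.empty((N + 1, 14, 14))
        Z_hist = np.empty((N + 1, 14, npar))
        M = np.eye(14)
        Z = np.zeros((14, npar))
        M_hist[0] = M
        Z_hist[0] = Z
        aug = np.zeros((14 + npar, 14 + npar))
        for k in range(N):
            J = jx_fn(x_mid[k], pvec)
            G = jp_fn(x_mid[k], pvec)
            aug[:14, :14] = J * h
            aug[:14, 14:] = G * h
            Eaug = expm(aug)
            Ek = Eaug[:14, :14]
            Sk = Eaug[:14, 14:]        # = h·φ1(hJ)·G
            E[k] = Ek
            M = Ek @ M
            Z = Ek @ Z + Sk
            M_hist[k + 1] = M
            Z_hist[k + 1] = Z

        self._t_grid = t_grid
        self._x_grid = x_grid
        self._M_hist = M_hist
        self._Z_hist = Z_hist
        monodromy = M_hist[-1]

        # periodicity boundary-value problem on the section through the
        # anchor with normal along the flow
        v = f_fn(lc.anchor, pvec)
        A = np.zeros((15, 15))
        A[:14, :14] = monodromy - np.eye(14)
        A[:14, 14] = v
        A[14, :14] = v / np.linalg.norm(v)
        rhs = np.zeros((15, npar))
        rhs[:14, :] = -Z_hist[-1]
        sol = np.linalg.solve(A, rhs)
        self._w = sol[:14, :]                  # dx*/dp on the section
        self._dT = sol[14, :]                  # dT/dp, hours per unit

        # adjoint eigenfunction: left eigenvector of the monodromy at
        # multiplier 1, swept backwards with the stored step propagators
        evals, evecs = np.linalg.eig(monodromy.T)
        i1 = int(np.argmin(np.abs(evals - 1.0)))
        q0 = np.real(evecs[:, i1])
        q0 *= lc.omega / float(q0 @ v)
        Q = np.empty((N + 1, 14))
        Q[0] = q0
        Q[N] = q0
        for k in range(N - 1, 0, -1):
            Q[k] = E[k].T @ Q[k + 1]
        self._Q = Q
        # ipPRC values for every parameter on the sweep grid
        self._prc_grid = np.empty((N + 1, npar))
        for k in range(N + 1):
            self._prc_grid[k] = Q[k] @ jp_fn(x_grid[k], pvec)
        self._computed = True

    # -- public queries ----------------------------------------------------
    def period_sensitivity(self, param: str) -> float:
        """dT/dp (hours per parameter unit) from the variational BVP."""
        self._compute()
        return float(self._dT[_PIDX[param]])

    def all_period_sensitivities(self,
                                 params: Iterable[str] = CANONICAL_PARAM_NAMES
                                 ) -> dict[str, float]:
        self._compute()
        return {name: float(self._dT[_PIDX[name]]) for name in params}

    def cycle_state_sensitivity(self, param: str, t: float) -> np.ndarray:
        """d x(t)/dp along the perturbed periodic orbit, at orbit time t."""
        self._compute()
        k = int(round(t / self.lc.period * self.n_steps))
        k = min(max(k, 0), self.n_steps)
        j = _PIDX[param]
        return self._M_hist[k] @ self._w[:, j] + self._Z_hist[k][:, j]

    def amplitude_sensitivity(self, param: str, species: str) -> float:
        """dA_x/dp: response of the species' peak value to the parameter."""
        self._compute()
        y = self.lc.species(species)
        k_peak = int(np.argmax(y))
        t_peak = self.lc.orbit_t[k_peak]
        sens = self.cycle_state_sensitivity(param, t_peak)
        return float(sens[SPECIES_INDEX[species]])

    def parametric_prc(self, param: str,
                       n_phases: int = 256) -> PRCCurve:
        """The ipPRC of ``param`` on a uniform phase grid."""
        if n_phases < 100:
            raise ValueError("n_phases must be at least 100")
        self._compute()
        vals = self._prc_grid[:, _PIDX[param]]
        phases_full = self.lc.omega * self._t_grid
        grid = np.linspace(0.0, 2 * np.pi, n_phases, endpoint=False)
        return PRCCurve(param=param, phases=grid,
                        values=np.interp(grid, phases_full, vals))

    def loop_comparison(self,
                        params: Iterable[str] = CANONICAL_PARAM_NAMES
                        ) -> dict:
        """Per-loop |dT/dp| summary and correlation with ipPRC lobe areas."""
        self._compute()
        params = list(params)
        dT = np.array([self.period_sensitivity(p) for p in params])
        pos_areas, neg_areas = [], []
        for p in params:
            pos, neg = self.parametric_prc(p).lobe_areas()
            pos_areas.append(pos)
            neg_areas.append(neg)
        pos_areas = np.array(pos_areas)
        neg_areas = np.array(neg_areas)
        loops = np.array([loop_of(p) for p in params])
        neg_mask = loops == "negative"

        def pearson(a, b):
            return float(np.corrcoef(a, b)[0, 1])

        return {
            "params": params,
            "dT_dp": dT,
            "positive_lobe_area": pos_areas,
            "negative_lobe_area": neg_areas,
            "loop": loops,
            "max_abs_dT_negative_loop": float(np.abs(dT[neg_mask]).max()),
            "max_abs_dT_positive_loop": float(np.abs(dT[~neg_mask]).max()),
            "corr_dT_positive_lobe": pearson(dT, pos_areas),
            "corr_dT_negative_lobe": pearson(dT, neg_areas),
        }


@lru_cache(maxsize=4)
def _cached_analysis(params: ParameterSet) -> CycleSensitivity:
    return CycleSensitivity(params)


def period_sensitivity(params: ParameterSet, param: str) -> float:
    """dT/dp_i at ``params`` (convenience wrapper, cached per set)."""
    return _cached_analysis(params).period_sensitivity(param)


def amplitude_sensitivity(params: ParameterSet, param: str,
                          species: str) -> float:
    """dA_x/dp_i at the peak of ``species`` (cached per set)."""
    return _cached_analysis(params).amplitude_sensitivity(param, species)


def parametric_prc(params: ParameterSet, param: str,
                   n_phases: int = 256) -> PRCCurve:
    """ipPRC of ``param`` at ``params`` (cached per set)."""
    return _cached_analysis(params).parametric_prc(param, n_phases)


def loop_comparison(params: ParameterSet) -> dict:
    """Loop-resolved sensitivity summary (cached per set)."""
    return _cached_analysis(params).loop_comparison()


def finite_difference_period_sensitivity(params: ParameterSet, param: str,
                                         rel_step: float = 1e-3,
                                         **lc_kw) -> float:
    """Central-difference dT/dp by re-simulating the limit cycle.

    This is the plain re-simulation route kept deliberately separate from
    the variational implementation; the test suite compares the two.
    """
    p0 = params[param]
    h = rel_step * p0 if p0 > 0 else rel_step
    lo = find_limit_cycle(params.replace(**{param: p0 - h}), **lc_kw)
    hi = find_limit_cycle(params.replace(**{param: p0 + h}), **lc_kw)
    if lo is None or hi is None:
        raise ValueError("parameter set became non-oscillatory in the stencil")
    return (hi.period - lo.period) / (2 * h)


__all__ = [
    "NEGATIVE_LOOP_PARAMS",
    "POSITIVE_LOOP_PARAMS",
    "loop_of",
    "PRCCurve",
    "CycleSensitivity",
    "period_sensitivity",
    "amplitude_sensitivity",
    "parametric_prc",
    "loop_comparison",
    "finite_difference_period_sensitivity",
]
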