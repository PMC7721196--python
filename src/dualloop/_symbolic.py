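"""Symbolically generated Jacobians of the model right-hand side.

The state Jacobian ∂f/∂x and parameter Jacobian ∂f/∂p are derived once
with sympy from a symbolic transcription of the rate equations and
lambdified to fast numeric callables.  Used by the sensitivity machinery
(variational propagation and adjoint phase-response computation).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .model import SPECIES
from .params import PARAM_NAMES


def _symbolic_rhs():
    x = sp.symbols(" ".join(SPECIES), nonnegative=True)
    par = sp.symbols(" ".join(PARAM_NAMES), nonnegative=True)
    d = dict(zip(PARAM_NAMES, par))
    p, c1, c2, ror, rev, P, C1, C2, ROR, REV, b, B, C1N, C2N = x
    ebox = d["K_b"] * B + C1N + C2N
    nuc = d["K_deg_CP"] + C1N + C2N
    assoc1 = d["v_a_CP"] * P * C1
    assoc2 = d["v_a_CP"] * P * C2
    f = sp.Matrix([
        d["v_txn_p"] / (d["K_txn_p"] + ebox)
        - d["v_deg_p"] * p / (d["K_deg_p"] + p),
        d["v_txn_c1"] / (d["K_txn_c"] + ebox)
        - d["v_deg_c1"] * c1 / (d["K_deg_c"] + c1),
        d["v_txn_c2"] / (d["K_txn_c"] + ebox)
        - d["v_deg_c2"] * c2 / (d["K_deg_c"] + c2),
        d["v_txn_ror"] / (d["K_txn_ror"] + ebox)
        - d["v_deg_ror"] * ror / (d["K_deg_ror"] + ror),
        d["v_txn_rev"] / (d["K_txn_rev"] + ebox)
        - d["v_deg_rev"] * rev / (d["K_deg_rev"] + rev),
        d["K_tln_p"] * p - d["v_deg_P"] * P / (d["K_deg_P"] + P)
        - assoc1 + d["v_d_CP"] * C1N - assoc2 + d["v_d_CP"] * C2N,
        d["K_tln_c1"] * c1 - d["v_deg_C1"] * C1 / (d["K_deg_C"] + C1)
        - assoc1 + d["v_d_CP"] * C1N,
        d["K_tln_c2"] * c2 - d["v_deg_C2"] * C2 / (d["K_deg_C"] + C2)
        - assoc2 + d["v_d_CP"] * C2N,
        d["K_tln_ror"] * ror - d["v_deg_ROR"] * ROR / (d["K_deg_ROR"] + ROR),
        d["K_tln_rev"] * rev - d["v_deg_REV"] * REV / (d["K_deg_REV"] + REV),
        (d["v_txn_ROR"] * ROR + d["v_txn_REV"])
        / (1 + d["K_txn_REV"] * REV + d["K_txn_ROR"] * ROR)
        - d["v_deg_b"] * b / (d["K_deg_b"] + b),
        d["K_tln_b"] * b - d["v_deg_B"] * B / (d["K_deg_B"] + B),
        -d["v_deg_C1N"] * C1N / nuc + assoc1 - d["v_d_CP"] * C1N,
        -d["v_deg_C2N"] * C2N / nuc + assoc2 - d["v_d_CP"] * C2N,
    ])
    return x, par, f


@lru_cache(maxsize=1)
def jacobian_functions():
    """Return ``(f, J_x, J_p)`` numeric callables of ``(x_vec, p_vec)``.

    ``f`` → shape (14,), ``J_x`` → (14, 14), ``J_p`` → (14, n_params).
    """
    x, par, f = _symbolic_rhs()
    Jx = f.jacobian(x)
    Jp = f.jacobian(par)
    f_fn = sp.lambdify((x, par), f, modules="numpy", cse=True)
    jx_fn = sp.lambdify((x, par), Jx, modules="numpy", cse=True)
    jp_fn = sp.lambdify((x, par), Jp, modules="numpy", cse=True)

    def wrap(fn, shape):
        def call(x_vec, p_vec):
            out = np.asarray(fn(tuple(x_vec), tuple(p_vec)), dtype=float)
            return out.reshape(shape)
        return call

    n = len(PARAM_NAMES)
    return (wrap(f_fn, (14,)), wrap(jx_fn, (14, 14)), wrap(jp_fn, (14, n)))
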