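"""Right-hand side of the 14-state dual-loop clock ODE system.

Species (state order is the public contract):

====== =================================== ============================
index  symbol                              species
====== =================================== ============================
0      p      *Per* mRNA
1      c1     *Cry1* mRNA
2      c2     *Cry2* mRNA
3      ror    *Ror* mRNA
4      rev    *Rev-erbα* mRNA
5      P      PER protein
6      C1     CRY1 protein
7      C2     CRY2 protein
8      ROR    ROR protein
9      REV    REV-ERBα protein
10     b      *Bmal1* mRNA
11     B      BMAL1 protein
12     C1N    nuclear PER:CRY1 heterodimer
13     C2N    nuclear PER:CRY2 heterodimer
====== =================================== ============================

Kinetics: Ebox-driven transcription for p, c1, c2, ror, rev (repressed by
the nuclear heterodimers, with a BMAL1 term weighted by ``K_b``);
competitive ROR-activation / REV-ERBα-repression of *Bmal1* transcription
at the RORE site; mass-action translation; Michaelis–Menten degradation of
every species; mass-action PER:CRY association/dissociation; and a shared
competitive Michaelis denominator for nuclear heterodimer degradation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .params import ParameterSet

#: State order of the system (index matches the table in the module docs).
SPECIES: tuple[str, ...] = (
    "p", "c1", "c2", "ror", "rev",
    "P", "C1", "C2", "ROR", "REV",
    "b", "B", "C1N", "C2N",
)

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

N_SPECIES = len(SPECIES)


def ebox_rate(v: float, K: float, K_b: float,
              B: float, C1N: float, C2N: float) -> float:
    """Transcription rate of an Ebox-controlled gene.

    ``r = v / (K + K_b*B + C1N + C2N)`` — the promoter-equilibrium rate,
    non-increasing in each of the BMAL1 and nuclear-heterodimer
    concentrations.  ``K`` must be strictly positive so the rate is defined
    at the naive state ``B = C1N = C2N = 0``.
    """
    if K <= 0:
        raise ValueError("K must be strictly positive")
    if min(v, K_b, B, C1N, C2N) < 0:
        raise ValueError("ebox_rate arguments must be nonnegative")
    return v / (K + K_b * B + C1N + C2N)


def rore_rate(ROR: float, REV: float, v1: float, v2: float,
              K1: float, K2: float) -> float:
    """Transcription rate of *Bmal1* at the RORE promoter site.

    ``r_b = (v1*ROR + v2) / (1 + K1*REV + K2*ROR)`` — ROR activates, REV
    represses; the denominator is bounded below by 1, so no argument
    combination is singular.
    """
    if min(ROR, REV, v1, v2, K1, K2) < 0:
        raise ValueError("rore_rate arguments must be nonnegative")
    return (v1 * ROR + v2) / (1.0 + K1 * REV + K2 * ROR)


def make_rhs(params: ParameterSet) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a fast ``f(t, x)`` closure for the ODE integrators.

    Parameter values are captured as scalars; no validation is performed
    per call (the integrators evaluate the RHS many thousands of times).
    """
    (v_txn_p, K_txn_p, K_b, v_deg_p, K_deg_p,
     v_txn_c1, v_txn_c2, K_txn_c, v_deg_c1, v_deg_c2, K_deg_c,
     v_txn_ror, K_txn_ror, v_deg_ror, K_deg_ror,
     v_txn_rev, K_txn_rev, v_deg_rev, K_deg_rev,
     K_tln_p, v_deg_P, K_deg_P, v_a_CP, v_d_CP,
     v_deg_C1, K_deg_C, v_deg_C2,
     K_tln_ror, v_deg_ROR, K_deg_ROR,
     K_tln_rev, v_deg_REV, K_deg_REV,
     v_txn_ROR, v_txn_REV, K_txn_REV, K_txn_ROR,
     v_deg_b, K_deg_b, K_tln_b, v_deg_B, K_deg_B,
     v_deg_C1N, K_deg_CP, v_deg_C2N,
     K_tln_c1, K_tln_c2) = params.as_array()

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        p, c1, c2, ror, rev, P, C1, C2, ROR, REV, b, B, C1N, C2N = x
        ebox = K_b * B + C1N + C2N
        assoc1 = v_a_CP * P * C1
        assoc2 = v_a_CP * P * C2
        dissoc1 = v_d_CP * C1N
        dissoc2 = v_d_CP * C2N
        nuc = K_deg_CP + C1N + C2N
        return np.array([
            v_txn_p / (K_txn_p + ebox) - v_deg_p * p / (K_deg_p + p),
            v_txn_c1 / (K_txn_c + ebox) - v_deg_c1 * c1 / (K_deg_c + c1),
            v_txn_c2 / (K_txn_c + ebox) - v_deg_c2 * c2 / (K_deg_c + c2),
            v_txn_ror / (K_txn_ror + ebox) - v_deg_ror * ror / (K_deg_ror + ror),
            v_txn_rev / (K_txn_rev + ebox) - v_deg_rev * rev / (K_deg_rev + rev),
            K_tln_p * p - v_deg_P * P / (K_deg_P + P)
            - assoc1 + dissoc1 - assoc2 + dissoc2,
            K_tln_c1 * c1 - v_deg_C1 * C1 / (K_deg_C + C1) - assoc1 + dissoc1,
            K_tln_c2 * c2 - v_deg_C2 * C2 / (K_deg_C + C2) - assoc2 + dissoc2,
            K_tln_ror * ror - v_deg_ROR * ROR / (K_deg_ROR + ROR),
            K_tln_rev * rev - v_deg_REV * REV / (K_deg_REV + REV),
            (v_txn_ROR * ROR + v_txn_REV)
            / (1.0 + K_txn_REV * REV + K_txn_ROR * ROR)
            - v_deg_b * b / (K_deg_b + b),
            K_tln_b * b - v_deg_B * B / (K_deg_B + B),
            -v_deg_C1N * C1N / nuc + assoc1 - dissoc1,
            -v_deg_C2N * C2N / nuc + assoc2 - dissoc2,
        ])

    return rhs


def derivatives(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Time derivative dx/dt of the 14-state system at state ``x``.

    Validating wrapper around the integrator closure; rejects states with
    negative components.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have length {N_SPECIES}")
    if np.any(x < 0):
        raise ValueError("state components must be nonnegative")
    return make_rhs(params)(0.0, x)
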