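"""Parameter space of the dual-loop clock model.

The model has 47 kinetic constants: the 45 published rate/affinity
constants of the fitted optimum plus the two Cry translation rates
(``K_tln_c1``, ``K_tln_c2``).  The published parameter table omits the Cry
translation rates even though the protein balance equations require them;
the values shipped here were identified once against the published model
outputs (period, Cry-knockout period ratios, peak-to-trough ratios,
relative abundances and phase differences) and are treated as part of the
canonical set ever after.

Names are ASCII-normalised (``v_txn_p``, ``K_deg_CP`` ...).  Rates
(``v_*`` and the translation/association constants) carry units of
concentration per hour; ``K_*`` Michaelis/affinity constants carry
concentration units (``K_b``, ``K_txn_REV``, ``K_txn_ROR`` are inverse
concentrations from the promoter-equilibrium derivation).  One model time
unit is treated as one hour throughout the package.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np

#: The 45 published parameter names, in the published table order.
CANONICAL_PARAM_NAMES: tuple[str, ...] = (
    "v_txn_p", "K_txn_p", "K_b", "v_deg_p", "K_deg_p",
    "v_txn_c1", "v_txn_c2", "K_txn_c", "v_deg_c1", "v_deg_c2", "K_deg_c",
    "v_txn_ror", "K_txn_ror", "v_deg_ror", "K_deg_ror",
    "v_txn_rev", "K_txn_rev", "v_deg_rev", "K_deg_rev",
    "K_tln_p", "v_deg_P", "K_deg_P", "v_a_CP", "v_d_CP",
    "v_deg_C1", "K_deg_C", "v_deg_C2",
    "K_tln_ror", "v_deg_ROR", "K_deg_ROR",
    "K_tln_rev", "v_deg_REV", "K_deg_REV",
    "v_txn_ROR", "v_txn_REV", "K_txn_REV", "K_txn_ROR",
    "v_deg_b", "K_deg_b", "K_tln_b", "v_deg_B", "K_deg_B",
    "v_deg_C1N", "K_deg_CP", "v_deg_C2N",
)

#: Full parameter vector: published names followed by the two identified
#: Cry translation rates.  This order is the serialization contract.
PARAM_NAMES: tuple[str, ...] = CANONICAL_PARAM_NAMES + ("K_tln_c1", "K_tln_c2")

_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Genes that can be knocked out by zeroing transcription-rate parameters.
#: Bmal1 transcription has no single basal rate constant, so its knockout
#: zeroes both numerator rates of the RORE promoter function.
KNOCKOUT_GENES: dict[str, tuple[str, ...]] = {
    "Per": ("v_txn_p",),
    "Cry1": ("v_txn_c1",),
    "Cry2": ("v_txn_c2",),
    "Ror": ("v_txn_ror",),
    "Rev-erba": ("v_txn_rev",),
    "Bmal1": ("v_txn_ROR", "v_txn_REV"),
}

# Spelling variants accepted for knockout gene names.
_GENE_ALIASES = {
    "per": "Per", "cry1": "Cry1", "cry2": "Cry2", "ror": "Ror",
    "rev-erba": "Rev-erba", "rev-erbα": "Rev-erba", "rev": "Rev-erba",
    "reverba": "Rev-erba", "bmal1": "Bmal1", "bmal": "Bmal1",
}


def _normalize_gene(name: str) -> str:
    key = name.strip().lower()
    if key not in _GENE_ALIASES:
        raise KeyError(
            f"unknown knockout gene {name!r}; expected one of "
            f"{sorted(set(_GENE_ALIASES.values()))}"
        )
    return _GENE_ALIASES[key]


class ParameterSet(Mapping[str, float]):
    """Immutable named vector of the model's kinetic constants.

    Behaves as a mapping from parameter name to value; ``as_array()``
    exposes the underlying vector in :data:`PARAM_NAMES` order.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        vec = np.array([float(values[name]) for name in PARAM_NAMES])
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameters must be finite")
        if np.any(vec < 0):
            bad = [PARAM_NAMES[i] for i in np.where(vec < 0)[0]]
            raise ValueError(f"parameters must be nonnegative: {bad}")
        vec.setflags(write=False)
        self._values = vec

    @classmethod
    def from_array(cls, vec: Iterable[float]) -> "ParameterSet":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} values, got {vec.shape}"
            )
        return cls(dict(zip(PARAM_NAMES, vec)))

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return float(self._values[_INDEX[name]])
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    # -- conversions -------------------------------------------------------
    def as_array(self) -> np.ndarray:
        """Parameter vector in :data:`PARAM_NAMES` order (read-only view)."""
        return self._values

    def to_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(PARAM_NAMES, self._values)}

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        d = self.to_dict()
        for name, value in updates.items():
            if name not in d:
                raise KeyError(f"unknown parameter {name!r}")
            d[name] = value
        return ParameterSet(d)

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        """Return a copy with ``name`` multiplied by ``factor``."""
        return self.replace(**{name: self[name] * factor})

    # -- io ------------------------------------------------------------------
    def save(self, path) -> None:
        """Write as flat JSON, loss-free to full double precision."""
        with open(path, "w") as fh:
            json.dump({k: repr(v) for k, v in self.to_dict().items()},
                      fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: float(v) for k, v in raw.items()})

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ParameterSet({self.to_dict()!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return bool(np.array_equal(self._values, other._values))

    def __hash__(self) -> int:
        return hash(self._values.tobytes())


def canonical_parameters() -> ParameterSet:
    """The fitted lowest-cost parameter set shipped with the package."""
    raw = json.loads(
        resources.files("dualloop")
        .joinpath("data/canonical_params.json")
        .read_text()
    )
    return ParameterSet({k: float(v) for k, v in raw.items()})


def apply_knockout(params: ParameterSet,
                   genes: Iterable[str]) -> ParameterSet:
    """Simulate gene knockouts by zeroing transcription-rate parameters.

    ``genes`` is any subset of :data:`KNOCKOUT_GENES`; an empty iterable
    returns the parameter set unchanged (wild type).
    """
    zeros: dict[str, float] = {}
    for gene in genes:
        for pname in KNOCKOUT_GENES[_normalize_gene(gene)]:
            zeros[pname] = 0.0
    return params.replace(**zeros) if zeros else params


#: Parameters carrying a per-time dimension: multiplying all of them by k
#: rescales time by 1/k (period divides by k, ratio features unchanged).
RATE_PARAM_NAMES: tuple[str, ...] = tuple(
    name for name in PARAM_NAMES
    if name.startswith("v_") or name.startswith("K_tln_")
)


def rescale_time(params: ParameterSet, factor: float) -> ParameterSet:
    """Multiply every per-time-dimension parameter by ``factor``."""
    return params.replace(
        **{name: params[name] * factor for name in RATE_PARAM_NAMES}
    )
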