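"""Waveform features of the clock limit cycle.

The model was fitted to experimentally observed peak-to-trough ratios,
relative abundances of species, phase differences between species peaks
(in percent of the period), and the period responses to Cry1/Cry2
knockout.  This module computes those features from a limit cycle and
ships the canonical feature specification (desired values, inequality
bounds and fitting weights) as package data.

Conventions (fixed once, used everywhere):

* relative abundance — ratio of one-cycle means of the summed species;
* phase difference ``a → b`` — time from the peak of ``a`` forward to the
  next peak of ``b``, divided by the period, × 100;
* peaks are localised by quadratic interpolation around the discrete
  maximum of the densely sampled orbit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .params import ParameterSet, apply_knockout
from .simulate import LimitCycle, find_limit_cycle


@dataclass(frozen=True)
class FeatureSpec:
    """One target feature: a desired value or bound, and a fitting weight."""

    id: str
    kind: str                      # "numeric" | "inequality"
    weight: float
    desired: float
    direction: Optional[str] = None   # for inequalities: "lt" | "gt"
    compute: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("numeric", "inequality"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "inequality" and self.direction not in ("lt", "gt"):
            raise ValueError("inequality features need direction 'lt' or 'gt'")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")

    def satisfied(self, value: float) -> bool:
        """For inequality features: does ``value`` meet the bound?"""
        if self.kind != "inequality":
            raise ValueError("satisfied() applies to inequality features")
        return value < self.desired if self.direction == "lt" \
            else value > self.desired


@dataclass(frozen=True)
class FeatureReport:
    """Computed feature values; empty when the model is arrhythmic."""

    oscillatory: bool
    values: dict[str, float]
    period: Optional[float] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"oscillatory": self.oscillatory,
                       "period_h": self.period,
                       "features": self.values}, fh, indent=1)
            fh.write("\n")


def canonical_feature_specs() -> list[FeatureSpec]:
    """The shipped feature specification (all fitted rows with weights)."""
    raw = json.loads(
        resources.files("dualloop")
        .joinpath("data/feature_spec.json")
        .read_text()
    )
    return [FeatureSpec(**row) for row in raw]


def _peak_time(lc: LimitCycle, species: str) -> float:
    """Peak time of a species on the orbit, quadratically refined."""
    y = lc.species(species)
    n = len(y)
    i = int(np.argmax(y))
    a, b, c = y[(i - 1) % n], y[i], y[(i + 1) % n]
    denom = a - 2 * b + c
    shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    dt = lc.period / n
    return float(np.mod(lc.orbit_t[i] + shift * dt, lc.period))


def peak_trough_ratio(lc: LimitCycle, species: str) -> float:
    """Orbit maximum over orbit minimum; ``inf`` if the trough reaches 0."""
    y = lc.species(species)
    lo, hi = float(y.min()), float(y.max())
    if lo <= 0.0:
        return math.inf
    return hi / lo


def relative_abundance(lc: LimitCycle,
                       numerator: Sequence[str] | str,
                       denominator: Sequence[str] | str) -> float:
    """Ratio of cycle-averaged total concentrations of two species sets."""
    if isinstance(numerator, str):
        numerator = [numerator]
    if isinstance(denominator, str):
        denominator = [denominator]
    num = sum(lc.species(s).mean() for s in numerator)
    den = sum(lc.species(s).mean() for s in denominator)
    if den == 0:
        raise ZeroDivisionError("denominator species average to zero")
    return float(num / den)


def phase_difference(lc: LimitCycle, a: str, b: str) -> float:
    """Percent of period from the peak of ``a`` to the next peak of ``b``."""
    ta, tb = _peak_time(lc, a), _peak_time(lc, b)
    return float(np.mod(tb - ta, lc.period) / lc.period * 100.0)


def _ko_relative_period(params: ParameterSet, gene: str,
                        wild_period: float, **lc_kw) -> float:
    lc = find_limit_cycle(apply_knockout(params, [gene]), **lc_kw)
    return math.nan if lc is None else lc.period / wild_period


def _ko_period_sensitivity(params: ParameterSet, gene: str,
                           rel_step: float = 1e-2, **lc_kw) -> float:
    """Central-difference period sensitivity to the mRNA degradation rate
    of the given Cry isoform (negative for Cry1, positive for Cry2 in the
    fitted model)."""
    pname = {"Cry1": "v_deg_c1", "Cry2": "v_deg_c2"}[gene]
    p0 = params[pname]
    h = rel_step * p0
    hi = find_limit_cycle(params.replace(**{pname: p0 + h}), **lc_kw)
    lo = find_limit_cycle(params.replace(**{pname: p0 - h}), **lc_kw)
    if hi is None or lo is None:
        return math.nan
    return (hi.period - lo.period) / (2 * h)


def extract_features(params: ParameterSet,
                     specs: Optional[Iterable[FeatureSpec]] = None,
                     lc: Optional[LimitCycle] = None,
                     **lc_kw) -> FeatureReport:
    """Compute every requested feature from the wild-type limit cycle.

    Returns a report with ``oscillatory=False`` and no values when the
    parameter set does not sustain oscillations.  Knockout-block features
    trigger additional limit-cycle computations.
    """
    if specs is None:
        specs = canonical_feature_specs()
    if lc is None:
        lc = find_limit_cycle(params, **lc_kw)
    if lc is None:
        return FeatureReport(oscillatory=False, values={})

    values: dict[str, float] = {}
    for spec in specs:
        kind = spec.compute.get("type")
        if kind == "ptr":
            v = peak_trough_ratio(lc, spec.compute["species"])
        elif kind == "ra":
            v = relative_abundance(lc, spec.compute["num"],
                                   spec.compute["den"])
        elif kind == "pd":
            v = phase_difference(lc, spec.compute["a"], spec.compute["b"])
        elif kind == "ko_period":
            v = _ko_relative_period(params, spec.compute["gene"],
                                    lc.period, **lc_kw)
        elif kind == "ko_sensitivity":
            v = _ko_period_sensitivity(params, spec.compute["gene"], **lc_kw)
        else:
            raise ValueError(f"unknown feature computation {kind!r}")
        values[spec.id] = v
    return FeatureReport(oscillatory=True, values=values, period=lc.period)


__all__ = [
    "FeatureSpec",
    "FeatureReport",
    "canonical_feature_specs",
    "peak_trough_ratio",
    "relative_abundance",
    "phase_difference",
    "extract_features",
]
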