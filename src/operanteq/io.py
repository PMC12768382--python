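"""Model configuration loading and tabular export.

The iterate table mirrors the supporting-information layout of the worked
examples: a uniform x column followed by columns ``Gamma0 … GammaN``
evaluating each Picard iterate.  Rational values in JSON configs are
strings ``"num/den"`` so exactness survives the round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .exact import PicardTrace
from .model import (
    DiscreteModel,
    IntegralModel,
    WeightFunction,
    make_affine_operator,
    preset_model,
)

__all__ = ["IterateTable", "load_model_config", "write_iterates_csv", "iterate_table"]

# 12 significant digits: lossless enough for replication, still compact
_FLOAT_FMT = "%.12g"


@dataclass
class IterateTable:
    """x grid plus one column per iterate, as a DataFrame with the exact
    supporting-table header ``x, Gamma0, Gamma1, …``."""

    frame: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _parse_rational(value) -> Fraction:
    if isinstance(value, bool):
        raise ValueError(f"not a rational: {value!r}")
    if isinstance(value, (int, str)):
        try:
            return Fraction(value)
        except (ValueError, ZeroDivisionError) as exc:
            raise ValueError(f"cannot parse rational {value!r}: {exc}") from None
    raise ValueError(f"rational values must be int or 'num/den' strings, got {value!r}")


def _parse_weight(spec) -> WeightFunction:
    # {"coeffs": {"i,j": "num/den", ...}} with i = x power, j = t power
    coeffs = {}
    for key, val in spec["coeffs"].items():
        i, j = (int(part) for part in str(key).split(","))
        coeffs[(i, j)] = _parse_rational(val)
    return WeightFunction(coeffs=coeffs, label=spec.get("label", ""))


def load_model_config(path) -> IntegralModel | DiscreteModel:
    """Load and validate a JSON model config.

    Schema::

        {"preset": "example1", "params": {...}}                  # preset form
        {"type": "integral",
         "weights": "pigeon" | "four_outcome" | [{"coeffs": {"0,1": "1"}}, ...],
         "operators": [{"slope": "1/4", "intercept": "1/4"}, ...],
         "p": "1/2"}                                             # explicit form
        {"type": "discrete",
         "operators": [{"slope": ..., "intercept": ...}, {...}]}

    Errors name the offending field; rational strings are parsed exactly.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)

    if cfg.get("preset"):
        return preset_model(cfg["preset"], cfg.get("params", {}))

    kind = cfg.get("type")
    if kind not in ("integral", "discrete"):
        raise ValueError(f"config field 'type' must be 'integral' or 'discrete', got {kind!r}")

    try:
        ops = [
            make_affine_operator(_parse_rational(o["slope"]), _parse_rational(o["intercept"]))
            for o in cfg["operators"]
        ]
    except KeyError as exc:
        raise ValueError(f"operator entry missing field {exc}") from None

    if kind == "discrete":
        if len(ops) != 2:
            raise ValueError("discrete config needs exactly two operators (g1, g2)")
        return DiscreteModel(g1=ops[0], g2=ops[1], name=path.stem)

    weights_spec = cfg.get("weights", "pigeon")
    if weights_spec == "pigeon":
        weights = [
            WeightFunction.from_poly_t({1: 1}, label="t"),
            WeightFunction.from_poly_t({0: 1, 1: -1}, label="1-t"),
        ]
    elif weights_spec == "four_outcome":
        p = _parse_rational(cfg.get("p", "1/2"))
        from .model import _four_outcome_weights

        weights = list(_four_outcome_weights(p))
    else:
        weights = [_parse_weight(w) for w in weights_spec]
    if len(weights) != len(ops):
        raise ValueError(
            f"config has {len(weights)} weights but {len(ops)} operators"
        )
    model = IntegralModel(terms=tuple(zip(weights, ops)), name=path.stem)
    from .model import validate_integral_model

    report = validate_integral_model(model)
    if not report.valid:
        raise ValueError(f"config model failed validation: {report.violations}")
    return model


def iterate_table(trace: PicardTrace, n_grid: int = 101) -> IterateTable:
    """Evaluate every iterate of a trace on a uniform grid."""
    if not trace.iterates:
        raise ValueError("empty trace")
    x = np.linspace(0.0, 1.0, n_grid)
    data = {"x": x}
    for i, poly in enumerate(trace.iterates):
        data[f"Gamma{i}"] = poly.eval_float(x)
    return IterateTable(pd.DataFrame(data))


def write_iterates_csv(trace: PicardTrace, n_grid: int, path) -> IterateTable:
    """Write the ``x, Gamma0, …, GammaN`` table to CSV (12 sig. digits)."""
    table = iterate_table(trace, n_grid=n_grid)
    table.write_csv(path)
    return table
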