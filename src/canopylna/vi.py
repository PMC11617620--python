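"""Declarative registry of vegetation-index formulas over the six bands.

Each index is an arithmetic expression over the band symbols B450, B530,
B570, B675, B730 and B850 (reflectances). The default set covers the
normalized, difference, ratio and multi-band indices commonly used for
nitrogen retrieval (NDRE, gNDVI, mSR, RD_730, RD_850, RERI_730,
CI_rededge, CI_green, PSSRa, OSAVI, EVI, AIVI). The registry is
overridable and round-trips through JSON, so a sensor-specific or
publication-specific formula table can be dropped in.

Provisional mappings: RD_850, RERI_730 and AIVI are mapped onto the
nearest available bands (the "green" band for green indices is 570 nm;
AIVI's two red-edge wavelengths are both taken at 730 nm). Treat these
as nearest-band adaptations rather than authoritative reproductions of
the original publications.
"""

from __future__ import annotations

import ast
import json
import math
import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import BAND_CENTERS, MultiBandReflectance

__all__ = [
    "VIDefinition",
    "VIRegistry",
    "default_registry",
    "compute_vi",
    "compute_vi_table",
]

BAND_SYMBOLS = {f"B{c}": c for c in BAND_CENTERS}

_BINOPS = {ast.Add: operator.add, ast.Sub: operator.sub,
           ast.Mult: operator.mul, ast.Div: operator.truediv}


class VIError(ValueError):
    """Invalid VI definition or evaluation failure."""


def _eval_node(node: ast.AST, env: dict[str, float]) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](_eval_node(node.left, env),
                                      _eval_node(node.right, env))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return -_eval_node(node.operand, env)
    if isinstance(node, ast.Call):
        if (isinstance(node.func, ast.Name) and node.func.id == "sqrt"
                and len(node.args) == 1):
            return math.sqrt(_eval_node(node.args[0], env))
        raise VIError("only sqrt(...) calls are allowed in VI expressions")
    if isinstance(node, ast.Name):
        if node.id in env:
            return env[node.id]
        raise VIError(f"unknown symbol {node.id!r} in VI expression")
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    raise VIError(f"unsupported expression element {ast.dump(node)}")


@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation index: expression over band symbols, optional range."""

    name: str
    expression: str
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        tree = ast.parse(self.expression, mode="eval")
        for node in ast.walk(tree):
            if isinstance(node, ast.Name) and node.id not in BAND_SYMBOLS \
                    and node.id != "sqrt":
                raise VIError(f"{self.name}: unknown band symbol {node.id!r}")
        object.__setattr__(self, "_tree", tree)

    def evaluate(self, bands: dict[int, float]) -> float:
        """Evaluate on a complete band map; NaN on division by zero."""
        env = {sym: bands[c] for sym, c in BAND_SYMBOLS.items()}
        try:
            value = _eval_node(self._tree, env)  # type: ignore[attr-defined]
        except (ZeroDivisionError, ValueError):
            return float("nan")
        return float(value)


_DEFAULTS = [
    ("NDRE", "(B850 - B730) / (B850 + B730)", (-1.0, 1.0)),
    ("gNDVI", "(B850 - B570) / (B850 + B570)", (-1.0, 1.0)),
    ("mSR", "(B850 / B730 - 1) / sqrt(B850 / B730 + 1)", None),
    ("RD_730", "B850 - B730", None),
    ("RD_850", "B850 - B675", None),
    ("RERI_730", "(B850 - B675) / B730", None),
    ("CI_rededge", "B850 / B730 - 1", None),
    ("CI_green", "B850 / B570 - 1", None),
    ("PSSRa", "B850 / B675", None),
    ("OSAVI", "1.16 * (B850 - B675) / (B850 + B675 + 0.16)", None),
    ("EVI", "2.5 * (B850 - B675) / (B850 + 6 * B675 - 7.5 * B450 + 1)", None),
    # three-band angular-insensitivity form, both red-edge terms at 730 nm
    ("AIVI",
     "(B450 * (B730 + B730) - B570 * (B730 - B730)) / (B730 * (B450 + B570))",
     None),
]


class VIRegistry:
    """Mapping of VI name -> :class:`VIDefinition`, JSON-serializable."""

    def __init__(self, definitions: list[VIDefinition] | None = None):
        self._defs: dict[str, VIDefinition] = {}
        for d in definitions or []:
            self.register(d)

    def register(self, definition: VIDefinition) -> None:
        self._defs[definition.name] = definition

    def __getitem__(self, name: str) -> VIDefinition:
        try:
            return self._defs[name]
        except KeyError:
            raise VIError(f"VI {name!r} is not registered") from None

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def names(self) -> list[str]:
        return sorted(self._defs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VIRegistry):
            return NotImplemented
        return {(d.name, d.expression, d.valid_range) for d in self} == \
               {(d.name, d.expression, d.valid_range) for d in other}

    def to_json(self) -> str:
        return json.dumps(
            [{"name": d.name, "expression": d.expression,
              "valid_range": list(d.valid_range) if d.valid_range else None}
             for d in sorted(self, key=lambda d: d.name)], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VIRegistry":
        items = json.loads(text)
        return cls([VIDefinition(
            name=i["name"], expression=i["expression"],
            valid_range=tuple(i["valid_range"]) if i.get("valid_range")
            else None) for i in items])


def default_registry() -> VIRegistry:
    """The built-in twelve-index registry."""
    return VIRegistry([VIDefinition(n, e, r) for n, e, r in _DEFAULTS])


def compute_vi(reflectance: MultiBandReflectance, name: str,
               registry: VIRegistry | None = None) -> float:
    """Evaluate one registered index on one reflectance record."""
    registry = registry if registry is not None else default_registry()
    return registry[name].evaluate(reflectance.bands)


def compute_vi_table(records: pd.DataFrame,
                     registry: VIRegistry | None = None) -> pd.DataFrame:
    """Long VI table from wide multiband records.

    ``records`` has columns plot_id, stage, vza and b450..b850. Output is
    one row per record x registered VI with columns plot_id, stage, vza,
    vi_name, value, in deterministic (record, name) order. Cells whose
    expression divides by zero are NaN.
    """
    registry = registry if registry is not None else default_registry()
    band_cols = {c: f"b{c}" for c in BAND_CENTERS}
    missing = [v for v in band_cols.values() if v not in records.columns]
    if missing:
        raise VIError(f"multiband records missing columns {missing}")
    rows = []
    for _, rec in records.iterrows():
        bands = {c: float(rec[col]) for c, col in band_cols.items()}
        for name in registry.names:
            rows.append({"plot_id": rec["plot_id"], "stage": rec["stage"],
                         "vza": rec["vza"], "vi_name": name,
                         "value": registry[name].evaluate(bands)})
    return pd.DataFrame(rows)
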