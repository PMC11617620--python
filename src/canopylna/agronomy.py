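"""Layer stratification and per-layer nitrogen accounting for wheat canopies.

The canopy is divided into equal-height layers (top-down: 1st = upper,
2nd = middle, 3rd = lower); the 4th and 5th "layers" are the upper+middle
and middle+lower aggregates, and ``canopy`` is the three-layer total.

Per-layer quantities:

* LNC - leaf nitrogen concentration, stored internally as a mass fraction
  (g N per g leaf dry matter); CSV I/O accepts and emits percent.
* LDW - leaf dry weight per ground area (g/m^2), scaled up from sampled
  tillers by the plot tiller density.
* LNA - leaf nitrogen accumulation per ground area (g/m^2) = LNC x LDW.

Aggregate LNC is the ratio of aggregate LNA to aggregate LDW, not the mean
of the constituent concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TillerSample",
    "LayerRecord",
    "CanopyProfile",
    "BASE_LAYERS",
    "AGGREGATE_LAYERS",
    "compute_ldw",
    "compute_lna",
    "aggregate_layers",
    "stratify_heights",
    "read_agronomy_csv",
    "profiles_to_frame",
]

#: biological layers, ordered top (1st) to bottom (3rd)
BASE_LAYERS = ("1st", "2nd", "3rd")
#: derived aggregates: 4th = 1st+2nd, 5th = 2nd+3rd, canopy = 1st+2nd+3rd
AGGREGATE_LAYERS = ("4th", "5th", "canopy")
ALL_LAYERS = BASE_LAYERS + AGGREGATE_LAYERS

_AGGREGATE_PARTS = {"4th": ("1st", "2nd"), "5th": ("2nd", "3rd"),
                    "canopy": ("1st", "2nd", "3rd")}

#: plausible LNC range for wheat leaves as a mass fraction (0-10 %)
LNC_PLAUSIBLE = (0.0, 0.10)


class AgronomyError(ValueError):
    """Domain error in the layered-accounting arithmetic."""


@dataclass(frozen=True)
class TillerSample:
    """Dry leaf mass of the tillers sampled from one layer of one plot.

    Parameters
    ----------
    dw_layer : float
        Total dry leaf mass of the sampled tillers in this layer (g).
    n_sampled : int
        Number of tillers sampled.
    tiller_density : float
        Plot tiller density N (tillers per m^2 of ground).
    """

    dw_layer: float
    n_sampled: int
    tiller_density: float

    def __post_init__(self) -> None:
        if self.dw_layer < 0:
            raise AgronomyError(f"dw_layer must be >= 0, got {self.dw_layer}")
        if self.n_sampled < 1:
            raise AgronomyError(f"n_sampled must be >= 1, got {self.n_sampled}")
        if self.tiller_density <= 0:
            raise AgronomyError(
                f"tiller_density must be > 0, got {self.tiller_density}")


@dataclass(frozen=True)
class LayerRecord:
    """LNC/LDW/LNA triple for one layer (or aggregate) of one plot."""

    layer_id: str
    lnc: float  # mass fraction g/g
    ldw: float  # g/m^2
    lna: float  # g/m^2

    def __post_init__(self) -> None:
        if self.layer_id not in ALL_LAYERS:
            raise AgronomyError(f"unknown layer_id {self.layer_id!r}")
        if self.ldw < 0:
            raise AgronomyError(f"ldw must be >= 0, got {self.ldw}")
        if not np.isclose(self.lna, self.lnc * self.ldw,
                          rtol=1e-9, atol=1e-12):
            raise AgronomyError(
                f"inconsistent record for layer {self.layer_id}: "
                f"lna={self.lna} != lnc*ldw={self.lnc * self.ldw}")


@dataclass(frozen=True)
class CanopyProfile:
    """Layered agronomy record for one plot at one growth stage."""

    plot_id: str
    stage: str
    n_treatment: str
    height: float  # mean canopy height H (m)
    layers: dict[str, LayerRecord] = field(default_factory=dict)
    n_base_layers: int = 3  # 2 at jointing (short plants), else 3

    def layer(self, layer_id: str) -> LayerRecord:
        return self.layers[layer_id]

    @property
    def is_complete(self) -> bool:
        wanted = BASE_LAYERS[: self.n_base_layers]
        if self.n_base_layers == 3:
            wanted = ALL_LAYERS
        else:
            wanted = wanted + ("canopy",)
        return all(k in self.layers for k in wanted)


def compute_ldw(sample: TillerSample) -> float:
    """Areal leaf dry weight (g/m^2) from a tiller sample.

    Scales the sampled dry mass to ground area via the tiller density:
    ``LDW = N * DW / n``.
    """
    return sample.tiller_density * sample.dw_layer / sample.n_sampled


def compute_lna(lnc: float, ldw: float) -> float:
    """Leaf nitrogen accumulation (g/m^2) = concentration x dry weight.

    ``lnc`` outside the plausible wheat range (0-10 % as a fraction) raises
    a warning but is not fatal - field data occasionally exceed it.
    """
    if ldw < 0:
        raise AgronomyError(f"ldw must be >= 0, got {ldw}")
    if not (LNC_PLAUSIBLE[0] <= lnc <= LNC_PLAUSIBLE[1]):
        warnings.warn(
            f"lnc={lnc} outside plausible mass-fraction range {LNC_PLAUSIBLE}",
            stacklevel=2)
    return lnc * ldw


def _merge(records: list[LayerRecord], layer_id: str) -> LayerRecord:
    lna = sum(r.lna for r in records)
    ldw = sum(r.ldw for r in records)
    if ldw == 0:
        if abs(lna) > 1e-12:
            raise AgronomyError(
                f"aggregate {layer_id}: zero LDW with nonzero LNA {lna}")
        lnc = 0.0
    else:
        lnc = lna / ldw
    return LayerRecord(layer_id=layer_id, lnc=lnc, ldw=ldw, lna=lna)


def aggregate_layers(profile: CanopyProfile) -> CanopyProfile:
    """Complete a profile with the 4th/5th aggregates and the canopy total.

    Aggregate LNA and LDW are sums over constituent layers; aggregate LNC is
    the quotient LNA/LDW. Idempotent: aggregates of an already complete
    profile are recomputed to identical values. Two-layer (jointing)
    profiles gain only the canopy total (1st + 2nd).
    """
    base = BASE_LAYERS[: profile.n_base_layers]
    missing = [b for b in base if b not in profile.layers]
    if missing:
        raise AgronomyError(f"profile {profile.plot_id} missing layers {missing}")

    layers = dict(profile.layers)
    if profile.n_base_layers == 3:
        for agg, parts in _AGGREGATE_PARTS.items():
            layers[agg] = _merge([layers[p] for p in parts], agg)
    else:
        layers["canopy"] = _merge([layers[b] for b in base], "canopy")
    return replace(profile, layers=layers)


def stratify_heights(height: float, n_layers: int = 3) -> list[float]:
    """Boundary heights (m, from the ground) of equal-thickness layers.

    Returns the internal boundaries ordered top-down, matching the top-down
    layer labels: for H=0.9 and 3 layers, ``[0.6, 0.3]`` (1st layer spans
    0.6-0.9 m). Only 2 (jointing-stage) or 3 layers are supported.
    """
    if height <= 0:
        raise AgronomyError(f"height must be > 0, got {height}")
    if n_layers not in (2, 3):
        raise AgronomyError(f"unsupported layer count {n_layers}; use 2 or 3")
    step = height / n_layers
    return [height - step * i for i in range(1, n_layers)]


# ---------------------------------------------------------------------------
# CSV interface: long format, one row per (plot, stage, base layer)

AGRONOMY_COLUMNS = ["plot_id", "stage", "n_treatment", "height_m", "layer_id",
                    "dw_g", "n_sampled", "tiller_density", "lnc_pct"]

_LAYER_FROM_INT = {1: "1st", 2: "2nd", 3: "3rd"}


def read_agronomy_csv(path, lnc_units: str = "percent") -> list[CanopyProfile]:
    """Read a long-format agronomy table and return completed profiles.

    Expected columns: plot_id, stage, n_treatment, height_m,
    layer_id (1..3), dw_g, n_sampled, tiller_density, lnc_pct.
    ``lnc_units`` declares the units of the LNC column: "percent"
    (default, divided by 100 on load) or "fraction".
    """
    df = pd.read_csv(path)
    missing = [c for c in AGRONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise AgronomyError(f"agronomy csv missing columns {missing}")
    if lnc_units not in ("percent", "fraction"):
        raise AgronomyError(f"unknown lnc_units {lnc_units!r}")
    scale = 0.01 if lnc_units == "percent" else 1.0

    profiles = []
    for (plot, stage, ntr), grp in df.groupby(
            ["plot_id", "stage", "n_treatment"], sort=True):
        layers: dict[str, LayerRecord] = {}
        for _, row in grp.iterrows():
            lid = _LAYER_FROM_INT.get(int(row["layer_id"]))
            if lid is None:
                raise AgronomyError(
                    f"layer_id must be 1..3, got {row['layer_id']}")
            sample = TillerSample(dw_layer=float(row["dw_g"]),
                                  n_sampled=int(row["n_sampled"]),
                                  tiller_density=float(row["tiller_density"]))
            ldw = compute_ldw(sample)
            lnc = float(row["lnc_pct"]) * scale
            layers[lid] = LayerRecord(lid, lnc=lnc, ldw=ldw,
                                      lna=compute_lna(lnc, ldw))
        profile = CanopyProfile(
            plot_id=str(plot), stage=str(stage), n_treatment=str(ntr),
            height=float(grp["height_m"].iloc[0]), layers=layers,
            n_base_layers=len(layers))
        profiles.append(aggregate_layers(profile))
    return profiles


def profiles_to_frame(profiles: list[CanopyProfile],
                      lnc_units: str = "percent") -> pd.DataFrame:
    """Flatten completed profiles into a long table (one row per layer)."""
    scale = 100.0 if lnc_units == "percent" else 1.0
    rows = []
    for p in profiles:
        for lid in ALL_LAYERS:
            if lid not in p.layers:
                continue
            r = p.layers[lid]
            rows.append({"plot_id": p.plot_id, "stage": p.stage,
                         "n_treatment": p.n_treatment, "height_m": p.height,
                         "layer_id": lid, "lnc": r.lnc * scale,
                         "ldw": r.ldw, "lna": r.lna,
                         "lnc_units": lnc_units})
    return pd.DataFrame(rows)
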