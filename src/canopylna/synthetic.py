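"""Synthetic layered wheat canopies with multiangular VI observations.

The generator emulates the statistical structure the stratified analysis
relies on, so the whole pipeline is testable without field data:

* a top-to-bottom declining leaf-nitrogen-concentration gradient
  (upper > middle > lower), fading over growth stages and stronger under
  high nitrogen supply;
* leaf dry weight (and hence leaf nitrogen accumulation) rising then
  falling across stages, peaking earlier under high nitrogen;
* view-zenith-angle-dependent layer visibility: the nadir view is
  dominated by the upper layer while oblique views weight the middle and
  lower layers;
* vegetation indices generated as noisy affine responses to the
  angularly weighted layer LNA, optionally through a mild exponential
  saturation (the well-documented flattening of VI response at high
  biomass); the planted coefficients are returned in a truth table so
  recovery can be asserted.

All randomness flows from one root seed through named substreams
(profiles / vi / split), so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agronomy import BASE_LAYERS, CanopyProfile, LayerRecord, \
    aggregate_layers, profiles_to_frame
from .spectra import HyperSpectrum, VZA_SET

__all__ = [
    "SynthConfig",
    "DEFAULT_VISIBILITY",
    "ONE_HOT_VISIBILITY",
    "generate_profiles",
    "generate_vi_observations",
    "generate_dataset",
    "make_hyperspectra",
]

#: default layer visibility per VZA: nadir sees mostly the upper layer,
#: oblique angles progressively weight the middle and lower layers
DEFAULT_VISIBILITY = {0: (0.70, 0.20, 0.10),
                     -30: (0.25, 0.50, 0.25),
                     -45: (0.15, 0.35, 0.50)}

#: idealized visibility in which each VZA sees exactly one layer; used by
#: recovery tests where the planted composite must be returned exactly
ONE_HOT_VISIBILITY = {0: (1.0, 0.0, 0.0),
                      -30: (0.0, 1.0, 0.0),
                      -45: (0.0, 0.0, 1.0)}

#: baseline VI response (alpha, beta): VI = alpha + beta * weighted LNA
VI_RESPONSE = {
    "NDRE": (0.10, 0.10), "gNDVI": (0.20, 0.12), "mSR": (0.10, 0.15),
    "RD_730": (0.05, 0.05), "RD_850": (0.10, 0.08),
    "RERI_730": (0.20, 0.25), "CI_rededge": (0.30, 0.60),
    "CI_green": (0.50, 0.80), "PSSRa": (2.00, 2.00),
    "OSAVI": (0.20, 0.12), "EVI": (0.20, 0.20), "AIVI": (0.60, 0.10),
}

DEFAULT_STAGES = ("jointing", "booting", "heading", "anthesis",
                  "forward_filling", "mid_filling")


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 36 plots x 6 stages x 2 nitrogen levels.

    ``noise_sd`` is the VI observation noise expressed in LNA-equivalent
    units (g/m^2): the noise added to a VI is noise_sd * beta of that VI.
    ``sat_scale`` (g/m^2) bends the VI response as
    s * (1 - exp(-x/s)); ``None`` keeps the response exactly affine.
    """

    n_plots: int = 36
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_levels: dict[str, float] = field(
        default_factory=lambda: {"low": 0.75, "high": 1.0})
    lnc_top: float = 0.045
    vertical_decay: tuple[float, float, float] = (1.0, 0.85, 0.65)
    stage_lnc_slope: float = 0.08
    ldw_peak_stage: dict[str, float] = field(
        default_factory=lambda: {"low": 3.0, "high": 2.0})
    ldw_canopy_max: float = 220.0
    ldw_shares: tuple[float, float, float] = (0.40, 0.35, 0.25)
    ldw_stage_width: float = 1.8
    plot_sigma_ldw: float = 0.25
    plot_sigma_lnc: float = 0.06
    visibility: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VISIBILITY))
    vi_names: tuple[str, ...] = tuple(sorted(VI_RESPONSE))
    noise_sd: float = 0.3
    sat_scale: float | None = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        for vza, w in self.visibility.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"visibility row for vza {vza} must be nonnegative and "
                    f"sum to 1, got {tuple(w)}")
        if any(not 0 < d <= 1 for d in self.vertical_decay):
            raise ValueError("vertical_decay factors must lie in (0, 1]")
        unknown = [v for v in self.vi_names if v not in VI_RESPONSE]
        if unknown:
            raise ValueError(f"no planted response for VI(s) {unknown}")

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG: 'profiles', 'vi' or 'split'."""
        order = {"profiles": 0, "vi": 1, "split": 2}
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order[name]])


def _saturate(x: np.ndarray, scale: float | None) -> np.ndarray:
    if scale is None:
        return x
    return scale * (1.0 - np.exp(-x / scale))


def generate_profiles(config: SynthConfig
                      ) -> tuple[list[CanopyProfile], dict]:
    """Layered agronomy profiles plus the hidden truth table.

    Per layer i (1=upper) at stage index s under treatment multiplier m:

        LNC_i = lnc_top * decay_i * (1 - stage_lnc_slope * s) * m
        LDW_i = ldw_max * share_i * m * exp(-((s - peak_m)/width)^2 / 2)
        LNA_i = LNC_i * LDW_i

    with per-plot lognormal heterogeneity on LNC and LDW (independent per
    layer, which is what makes the canopy sum unresolvable from any
    single viewing angle). Canopy rows are exact layer sums by
    construction; LNC is floored at 0.005 g/g.
    """
    rng = config.substream("profiles")
    treatments = sorted(config.n_levels)
    profiles: list[CanopyProfile] = []
    truth_rows = []
    for p in range(config.n_plots):
        treatment = treatments[p % len(treatments)]
        mult = config.n_levels[treatment]
        peak = config.ldw_peak_stage[treatment]
        plot_id = f"plot{p:03d}"
        for s, stage in enumerate(config.stages):
            height = 0.45 + 0.09 * s
            layers: dict[str, LayerRecord] = {}
            for i, lid in enumerate(BASE_LAYERS):
                lnc = (config.lnc_top * config.vertical_decay[i]
                       * max(1.0 - config.stage_lnc_slope * s, 0.0) * mult)
                lnc *= np.exp(rng.normal(0.0, config.plot_sigma_lnc))
                lnc = max(lnc, 0.005)
                ldw = (config.ldw_canopy_max * config.ldw_shares[i] * mult
                       * np.exp(-0.5 * ((s - peak)
                                        / config.ldw_stage_width) ** 2))
                ldw *= np.exp(rng.normal(0.0, config.plot_sigma_ldw))
                layers[lid] = LayerRecord(lid, lnc=lnc, ldw=ldw,
                                          lna=lnc * ldw)
            profile = aggregate_layers(CanopyProfile(
                plot_id=plot_id, stage=stage, n_treatment=treatment,
                height=height, layers=layers))
            profiles.append(profile)
            truth_rows.append({
                "plot_id": plot_id, "stage": stage,
                "n_treatment": treatment,
                **{f"lna_{lid}": profile.layer(lid).lna
                   for lid in ("1st", "2nd", "3rd", "4th", "5th", "canopy")},
            })
    truth = {"layer_lna": pd.DataFrame(truth_rows), "config": config}
    return profiles, truth


def generate_vi_observations(profiles: list[CanopyProfile], truth: dict,
                             config: SynthConfig) -> pd.DataFrame:
    """Long VI table (plot, stage, vza, vi_name, value) with planted truth.

    For each VI v and angle theta the observation is

        VI = alpha_v + beta_v * sat(sum_i w_i(theta) * LNA_i) + eps,
        eps ~ Normal(0, noise_sd * beta_v)

    The planted (alpha, beta) per VI, the visibility matrix and the
    saturation scale are stored in ``truth`` for recovery tests.
    """
    rng = config.substream("vi")
    lna = truth["layer_lna"].set_index(["plot_id", "stage"])
    rows = []
    for profile in profiles:
        key = (profile.plot_id, profile.stage)
        layer_lna = np.array([lna.loc[key, f"lna_{lid}"]
                              for lid in BASE_LAYERS])
        for vza in sorted(config.visibility, reverse=True):
            w = np.asarray(config.visibility[vza], dtype=float)
            exposure = float(_saturate(np.array([w @ layer_lna]),
                                       config.sat_scale)[0])
            for name in config.vi_names:
                alpha, beta = VI_RESPONSE[name]
                eps = rng.normal(0.0, config.noise_sd * beta) \
                    if config.noise_sd > 0 else 0.0
                rows.append({"plot_id": profile.plot_id,
                             "stage": profile.stage, "vza": vza,
                             "vi_name": name,
                             "value": alpha + beta * exposure + eps})
    truth["vi_response"] = {name: VI_RESPONSE[name]
                            for name in config.vi_names}
    truth["visibility"] = dict(config.visibility)
    truth["sat_scale"] = config.sat_scale
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Convenience: (long profile frame, VI table, truth) in one call."""
    profiles, truth = generate_profiles(config)
    vi_table = generate_vi_observations(profiles, truth, config)
    return profiles_to_frame(profiles, lnc_units="fraction"), vi_table, truth


# ---------------------------------------------------------------------------
# optional hyperspectral pathway

def _vegetation_spectrum(wl: np.ndarray, lnc_canopy: float,
                         ldw_canopy: float) -> np.ndarray:
    """Smooth vegetation-like curve driven by canopy nitrogen and biomass.

    Chlorophyll (tracking LNC) deepens the red trough and shrinks the
    green peak; biomass (tracking LDW) raises the NIR plateau. Purely
    phenomenological: green bump at 550 nm, logistic red edge at ~718 nm,
    gentle decline beyond 1350 nm.
    """
    lna = lnc_canopy * ldw_canopy
    r_red = 0.02 + 0.08 * np.exp(-lna / 3.0)
    r_nir = 0.25 + 0.25 * (1.0 - np.exp(-ldw_canopy / 80.0))
    green = (0.03 + 0.05 * np.exp(-lna / 4.0)) \
        * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    edge = 1.0 / (1.0 + np.exp(-(wl - 718.0) / 18.0))
    swir = 1.0 - 0.25 / (1.0 + np.exp(-(wl - 1400.0) / 100.0))
    return (r_red + (r_nir - r_red) * edge + green) * swir


def make_hyperspectra(profiles: list[CanopyProfile], config: SynthConfig,
                      flat_value: float | None = None,
                      ) -> list[tuple[CanopyProfile, HyperSpectrum]]:
    """One 350-2500 nm (1 nm) spectrum per profile, driven by canopy state.

    With ``flat_value`` set, every spectrum is constant at that value (a
    degenerate configuration for convolution contracts). Convolving these
    spectra with the default band SRFs and computing red-edge indices
    reproduces the qualitative VI-LNA relation the VI table plants (NDRE
    increases with canopy LNA); it does not reproduce the planted affine
    coefficients exactly.
    """
    wl = np.arange(350.0, 2501.0, 1.0)
    out = []
    for profile in profiles:
        if flat_value is not None:
            refl = np.full_like(wl, flat_value)
        else:
            canopy = profile.layer("canopy")
            refl = _vegetation_spectrum(wl, canopy.lnc, canopy.ldw)
        out.append((profile, HyperSpectrum(wl, refl)))
    return out
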