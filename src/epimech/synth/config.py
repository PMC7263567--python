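"""Configuration for the synthetic-microscopy generator.

The generator emulates live-imaging data from the basal surface of the
*Drosophila* follicular epithelium: mosaics of follicle cells carrying
integrin-null (*mys*) clones next to wild-type neighbours.  Every preset
bundles the effect sizes reported for one experimental condition —
stress-fiber count and intensity, cortical F-actin level, whip-like
protrusion counts at tricellular junctions, actomyosin oscillation
period/amplitude, laser-ablation recoil parameters, and stage-resolved
basal areas — so that each downstream analysis module can be validated
by parameter recovery against known ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

STAGES = ("S6", "S7", "S8", "S9", "S10")
#: Stages accepted in morphometry tables (includes late stage 10B).
ALL_STAGES = STAGES + ("S10B",)

_RECOIL_DT_S = 0.8  # vertex tracking frame interval (s)


def dlmax_for_v0(v0_um_per_s: float, tau_s: float, dt_s: float = _RECOIL_DT_S) -> float:
    """ΔL_max of an exponential recoil whose first-frame velocity is ``v0``.

    The recoil model is L(t) = L0 + ΔL_max (1 − e^(−t/τ)); the initial
    velocity estimated at the first post-cut frame t1 = dt is
    v0 = ΔL_max (1 − e^(−dt/τ)) / dt, inverted here for ΔL_max.
    """
    if tau_s <= 0:
        raise ValueError(f"recoil tau must be positive, got {tau_s}")
    return v0_um_per_s * dt_s / (1.0 - math.exp(-dt_s / tau_s))


@dataclass(frozen=True)
class Preset:
    """Parameter set for one experimental condition.

    Intensities are arbitrary fluorescence units (a.u.), lengths μm,
    times seconds, areas μm².
    """

    # --- scene rendering ---
    fiber_count_per_cell: int = 6
    fiber_intensity: float = 100.0          # F-actin channel, stress fibers
    myosin_intensity: float = 100.0         # myosin channel, stress fibers
    cortical_intensity: float = 100.0       # F-actin at cell-cell boundaries
    whip_count_leading_edge: float = 2.0    # mean whips per cell, leading edge
    noise_sd: float = 10.0                  # Gaussian read noise (a.u.)

    # --- oscillations ---
    oscillation_period_s: float = 480.0
    oscillation_amplitude: float = 100.0    # myosin a.u.; peak-to-peak is 2x
    period_jitter_frac: float = 0.05        # cycle-to-cycle period CV
    coupling_phase: float = 0.0             # myosin vs protrusion-area phase (rad)
    dv_ap_anisotropy: float = 5.0           # D-V / A-P fractional length change

    # --- laser ablation recoil ---
    recoil_L0_um: float = 5.0
    recoil_dLmax_um: float = dlmax_for_v0(0.58, 2.0)
    recoil_tau_s: float = 2.0
    recoil_noise_frac: float = 0.05         # noise sd as fraction of dLmax

    # --- morphometry ---
    basal_area_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {"S6": 30.0, "S7": 40.0, "S8": 50.0,
                                 "S9": 85.0, "S10": 153.0}
    )
    apical_area_um2: float = 20.0
    height_um: float = 35.0
    nuclear_area_um2: float = 25.0
    morpho_cv: float = 0.15                 # per-cell coefficient of variation

    def __post_init__(self) -> None:
        positive = {
            "fiber_intensity": self.fiber_intensity,
            "myosin_intensity": self.myosin_intensity,
            "cortical_intensity": self.cortical_intensity,
            "oscillation_period_s": self.oscillation_period_s,
            "oscillation_amplitude": self.oscillation_amplitude,
            "recoil_L0_um": self.recoil_L0_um,
            "recoil_tau_s": self.recoil_tau_s,
            "dv_ap_anisotropy": self.dv_ap_anisotropy,
            "apical_area_um2": self.apical_area_um2,
            "height_um": self.height_um,
            "nuclear_area_um2": self.nuclear_area_um2,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.noise_sd < 0 or self.recoil_noise_frac < 0 or self.morpho_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        for stage, area in self.basal_area_by_stage.items():
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if area <= 0:
                raise ValueError(f"basal area for {stage} must be positive")

    def replace(self, **kwargs) -> "Preset":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SynthConfig:
    """Global generator configuration: calibration plus named presets."""

    seed: int = 0
    pixel_size_um: float = 0.25
    frame_interval_s: float = 30.0
    presets: Mapping[str, Preset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    def preset(self, name: str) -> Preset:
        try:
            return self.presets[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(self.presets)}"
            ) from None

    def with_preset(self, name: str, preset: Preset) -> "SynthConfig":
        presets = dict(self.presets)
        presets[name] = preset
        return dataclasses.replace(self, presets=presets)


def default_config(seed: int = 0) -> SynthConfig:
    """Generator configuration reproducing the study's reported conditions.

    Presets:

    ``control``
        Wild-type follicle cells: six bright stress fibers per cell, two
        whip-like protrusions at leading-edge tricellular junctions,
        recoil v0 = 0.58 μm/s, basal surface growing 1.7x (S8→S9) and
        1.8x (S9→S10), D-V/A-P contraction anisotropy 5.
    ``mutant``
        Integrin-null (*mys*) cells: fiber F-actin at 40% of control
        (a 60% reduction), myosin at 60% (a 40% reduction), two-fold
        cortical F-actin, >5 whips per cell, shorter and noisier
        oscillations, recoil v0 = 1.26 μm/s, growth 1.5x and 1.3x,
        near-symmetric contraction (anisotropy 1.2).
    ``mixed``
        A control-mutant boundary (recoil v0 = 0.61 μm/s); other fields
        inherit control values and are not used for boundary simulation.
    ``mutant_rescue``
        Mutant cells with protrusion formation blocked: no whips and
        recoil v0 = 0.38 μm/s.
    """
    control = Preset()
    mutant = Preset(
        fiber_count_per_cell=3,
        fiber_intensity=40.0,           # 60% reduction vs control
        myosin_intensity=60.0,          # 40% reduction vs control
        cortical_intensity=200.0,       # two-fold cortical F-actin
        whip_count_leading_edge=5.5,    # "more than 5" per cell
        oscillation_period_s=300.0,
        oscillation_amplitude=60.0,
        period_jitter_frac=0.15,        # more stochastic cycling
        dv_ap_anisotropy=1.2,
        recoil_dLmax_um=dlmax_for_v0(1.26, 2.0),
        basal_area_by_stage={"S6": 30.0, "S7": 40.0, "S8": 45.0,
                             "S9": 67.5, "S10": 87.75},
    )
    mixed = control.replace(recoil_dLmax_um=dlmax_for_v0(0.61, 2.0))
    rescue = mutant.replace(
        whip_count_leading_edge=0.0,
        recoil_dLmax_um=dlmax_for_v0(0.38, 2.0),
    )
    return SynthConfig(
        seed=seed,
        presets={
            "control": control,
            "mutant": mutant,
            "mixed": mixed,
            "mutant_rescue": rescue,
        },
    )


# ---------------------------------------------------------------------------
# YAML round-trip

def config_to_yaml(config: SynthConfig, path) -> None:
    payload = {
        "seed": config.seed,
        "pixel_size_um": config.pixel_size_um,
        "frame_interval_s": config.frame_interval_s,
        "presets": {
            name: {**dataclasses.asdict(p),
                   "basal_area_by_stage": dict(p.basal_area_by_stage)}
            for name, p in config.presets.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> SynthConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    presets = {name: Preset(**p) for name, p in payload.pop("presets", {}).items()}
    return SynthConfig(presets=presets, **payload)
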