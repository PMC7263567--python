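"""Synthetic time series: coupled actomyosin oscillation traces and
laser-ablation vertex-distance traces.

Oscillation traces model basal myosin pulsing as a sinusoid with
optional cycle-to-cycle period jitter (integrin mutants cycle more
stochastically).  Protrusion area is phase-locked to myosin by the
preset coupling phase, basal area oscillates in anti-phase (myosin
accumulation drives contraction), and the D-V / A-P basal lengths
contract with the preset anisotropy ratio.  Recoil traces follow the
standard viscoelastic response L(t) = L0 + ΔL_max (1 − e^(−t/τ)) after
the cut, sampled every 0.8 s with a >10 s pre-cut baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ablation import AblationTrace
from ..oscillation import IntensityTrace
from .config import SynthConfig

RECOIL_DT_S = 0.8
RECOIL_N_PRE = 16      # pre-cut frames: 12.8 s of baseline (>= 10 s required)
RECOIL_N_POST = 20     # post-cut frames: 16 s of recoil

# fixed baselines of the auxiliary traces (see docs/methods.md)
PROTRUSION_BASE_PCT = 15.0
PROTRUSION_AMP_PCT = 8.0
BASAL_AREA_BASE_UM2 = 60.0
BASAL_AREA_AMP_FRAC = 0.10
DV_LENGTH_UM = 8.0
AP_LENGTH_UM = 8.0
AP_STRAIN = 0.05       # A-P per-cycle strain; D-V strain = anisotropy * this


@dataclass
class TraceBundle:
    """Aligned per-cell traces plus the generator's ground truth."""

    myosin: IntensityTrace
    protrusion_pct: IntensityTrace
    basal_area: IntensityTrace
    dv_length: IntensityTrace
    ap_length: IntensityTrace
    truth_period_s: float
    truth_amplitude: float
    truth_phase: float
    truth_anisotropy: float


def _phase(t: np.ndarray, period_s: float, jitter_frac: float,
           rng: np.random.Generator) -> np.ndarray:
    """Oscillation phase; piecewise-linear when cycle periods jitter."""
    if jitter_frac <= 0:
        return 2.0 * np.pi * t / period_s
    # draw successive cycle periods until they cover the trace
    nodes_t = [0.0]
    while nodes_t[-1] <= t[-1]:
        cycle = period_s * max(0.2, 1.0 + jitter_frac * rng.standard_normal())
        nodes_t.append(nodes_t[-1] + cycle)
    nodes_phase = 2.0 * np.pi * np.arange(len(nodes_t))
    return np.interp(t, nodes_t, nodes_phase)


def simulate_traces(config: SynthConfig, preset_name: str, duration_s: float,
                    seed: int, noise_frac: float = 0.05) -> TraceBundle:
    """Simulate one cell's coupled oscillation traces.

    ``noise_frac`` scales additive Gaussian noise per trace relative to
    that trace's oscillation amplitude; 0 gives exact closed forms.
    """
    preset = config.preset(preset_name)
    period = preset.oscillation_period_s
    if duration_s < 3.0 * period:
        raise ValueError(
            f"duration {duration_s} s too short: need >= 3 periods ({3 * period} s)")
    dt = config.frame_interval_s
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2.0, dt)
    phase = _phase(t, period, preset.period_jitter_frac, rng)

    amp = preset.oscillation_amplitude
    myosin = 2.0 * amp + amp * np.sin(phase)
    protrusion = PROTRUSION_BASE_PCT + PROTRUSION_AMP_PCT * np.sin(
        phase + preset.coupling_phase)
    area_amp = BASAL_AREA_AMP_FRAC * BASAL_AREA_BASE_UM2
    basal_area = BASAL_AREA_BASE_UM2 - area_amp * np.sin(phase)
    e_ap = AP_STRAIN
    e_dv = preset.dv_ap_anisotropy * e_ap
    dv = DV_LENGTH_UM * (1.0 - e_dv * np.sin(phase))
    ap = AP_LENGTH_UM * (1.0 - e_ap * np.sin(phase))

    if noise_frac > 0:
        def noisy(x, scale):
            return x + rng.normal(0.0, noise_frac * scale, size=x.shape)
        myosin = noisy(myosin, amp)
        protrusion = np.clip(noisy(protrusion, PROTRUSION_AMP_PCT), 0.0, 100.0)
        basal_area = noisy(basal_area, area_amp)
        dv = noisy(dv, DV_LENGTH_UM * e_dv)
        ap = noisy(ap, AP_LENGTH_UM * e_ap)

    def trace(values, label):
        return IntensityTrace(values=values, dt_s=dt, label=label)

    return TraceBundle(
        myosin=trace(myosin, "myosin"),
        protrusion_pct=trace(protrusion, "protrusion_pct"),
        basal_area=trace(basal_area, "basal_area"),
        dv_length=trace(dv, "dv_length"),
        ap_length=trace(ap, "ap_length"),
        truth_period_s=period,
        truth_amplitude=amp,
        truth_phase=preset.coupling_phase,
        truth_anisotropy=preset.dv_ap_anisotropy,
    )


def simulate_recoil(config: SynthConfig, preset_name: str, seed: int,
                    noise_frac: float | None = None) -> AblationTrace:
    """Simulate one laser-ablation vertex-distance trace.

    Samples every 0.8 s with 12.8 s of pre-cut baseline; the cut occurs at
    t = 0 and the first post-cut frame is t1 = 0.8 s.  ``noise_frac``
    (default: the preset's ``recoil_noise_frac``) scales Gaussian noise
    relative to ΔL_max.  The recorded ``truth_v0_um_per_s`` is the exact
    first-frame velocity ΔL_max (1 − e^(−0.8/τ)) / 0.8.
    """
    preset = config.preset(preset_name)
    tau = preset.recoil_tau_s
    if tau <= 0:
        raise ValueError(f"recoil tau must be positive, got {tau}")
    L0 = preset.recoil_L0_um
    dLmax = preset.recoil_dLmax_um
    if noise_frac is None:
        noise_frac = preset.recoil_noise_frac

    rng = np.random.default_rng(seed)
    n = RECOIL_N_PRE + 1 + RECOIL_N_POST
    times = (np.arange(n) - RECOIL_N_PRE) * RECOIL_DT_S
    cut_index = RECOIL_N_PRE                      # frame at t = 0
    distance = np.full(n, L0, dtype=float)
    post = times > 0
    distance[post] = L0 + dLmax * (1.0 - np.exp(-times[post] / tau))
    if noise_frac > 0:
        distance = distance + rng.normal(0.0, noise_frac * dLmax, size=n)

    v0 = dLmax * (1.0 - np.exp(-RECOIL_DT_S / tau)) / RECOIL_DT_S if dLmax else 0.0
    return AblationTrace(times_s=times, distance_um=distance,
                         cut_index=cut_index, truth_v0_um_per_s=float(v0))
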