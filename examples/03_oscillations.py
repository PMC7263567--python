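"""Analyse pulsatile basal myosin: period, amplitude and coupling.

Simulates one hour of coupled traces sampled every 30 s, then runs the
oscillation pipeline (background subtraction, σ = 3 Gaussian smoothing,
cycle detection) and reports the period from adjacent-peak intervals and
from the PSD of the autocorrelation, plus myosin/geometry correlations.
"""

from epimech.oscillation import analyze_trace, coupling_stats
from epimech.synth import default_config, simulate_traces

config = default_config()
for preset in ("control", "mutant"):
    bundle = simulate_traces(config, preset, duration_s=3600, seed=4,
                             noise_frac=0.05)
    res = analyze_trace(bundle.myosin)
    cpl = coupling_stats(bundle)
    print(f"{preset}: true period {bundle.truth_period_s:.0f} s | "
          f"intervals {res['period_intervals_mean_s']:.0f} s, "
          f"PSD {res['period_psd_s']:.0f} s, "
          f"amplitude {res['amplitude']:.0f} a.u. "
          f"(true peak-to-peak {2 * bundle.truth_amplitude:.0f})")
    print(f"  r(myosin, protrusion area) = {cpl.r_myosin_protrusion:+.2f}, "
          f"r(myosin, basal area) = {cpl.r_myosin_area:+.2f}")
print("\nMyosin accumulation tracks protrusion growth (r > 0) and basal "
      "contraction (r < 0); mutants cycle faster and more irregularly.")
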