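# epimech

Quantitative analysis of basal actomyosin networks in epithelial cell
mosaics, built around the phenotypes of integrin-null (*myospheroid*)
follicle-cell clones in the *Drosophila* follicular epithelium.

Follicle cells assemble two F-actin systems on their basal surface:
contractile stress fibers anchored at integrin adhesions, and a
cortical network at cell-cell junctions with whip-like protrusions at
tricellular vertices.  Removing integrins redistributes F-actin from
fibers into cortex and protrusions, raises junctional tension, and
stunts basal-surface growth.  `epimech` implements the measurements
used to establish those phenotypes:

- **Stress-fiber density** — intensity profiles sampled perpendicular to
  the fiber axis; peaks above the wild-type threshold
  (mean − 1 SD of control peak heights) counted per μm.
- **Junctional F-actin** — total intensity of a 2 μm bar across each
  cell-cell boundary, per boundary class, normalised to control-control.
- **Actomyosin oscillations** — background subtraction, Gaussian
  smoothing (σ = 3 samples), cycle detection; period from adjacent-peak
  intervals and from the PSD computed as the Fourier transform of the
  autocorrelation; amplitude as mean per-cycle max − min; coupling of
  myosin with protrusion area and basal area.
- **Laser-ablation recoil** — baseline L₀ as the 10 s pre-cut mean of
  the vertex distance; initial velocity v₀ = ΔL(t₁)/t₁ at the first
  post-cut frame (t₁ = 0.8 s); averaged displacement curves and Welch
  t-tests between boundary classes.
- **Morphometry** — label-image areas, stage-to-stage basal growth,
  protrusion-area percentage, whip counts at leading-edge tricellular
  junctions, D-V/A-P contraction anisotropy.

No imaging data accompanies the study, so the package ships a
synthetic-microscopy generator (`epimech.synth`) whose presets encode
the reported effect sizes; every analysis module is validated by
recovering those parameters from generated scenes, traces and tables.

## Worked example

```python
from epimech.ablation import summarize_group
from epimech.synth import default_config, simulate_recoil

config = default_config()
for label, preset in (("ctrl-ctrl", "control"), ("mut-mut", "mutant")):
    traces = [simulate_recoil(config, preset, seed=s) for s in range(1, 15)]
    s = summarize_group(traces, label)
    print(f"{label}: v0 = {s.mean:.2f} ± {s.se:.2f} um/s (n = 14)")
```

prints

```
ctrl-ctrl: v0 = 0.57 ± 0.03 um/s (n = 14)
mut-mut: v0 = 1.24 ± 0.06 um/s (n = 14)
```

The recoil velocity at the first post-cut frame is a relative proxy for
junctional tension (equal viscosity assumed): tension roughly doubles
between two integrin-null cells.  The `examples/` directory holds one
short script per capability — scene rendering and fiber density,
cortical bars, oscillations, ablation, morphometry — each printing the
numbers it computes and what they mean.  A thin CLI mirrors the same
operations for batch use (`epimech --help`).

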