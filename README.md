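# fluorspec

Vibrational spectroscopy of helical perfluoroalkyl-like chains:
linking infrared line broadening of C–F stretching bands to
accelerated helicity-reversal dynamics.

Perfluoroalkyl chains (PFAS and semifluorinated alkanes) adopt helical
backbones whose left- and right-handed conformers interconvert on the
picosecond scale. In a fluorous environment this helicity reversal
speeds up, and because the transition dipole moment μ_k of a C–F
stretching mode rotates upon reversal, the vibrational correlation
time shortens and the IR band broadens. `fluorspec` implements the
full analysis chain behind that mechanism, for people who compute IR
spectra from molecular-dynamics-style trajectories or quantify ATR-FTIR
band series:

* **Trajectory arm** — dipole power spectra via the Wiener–Khinchin
  theorem (S_vv(ω) = |ṽ(ω)|²/t_max, reported as one-sided densities in
  cm⁻¹), Green–Kubo susceptibility χ″(ω) ∝ ω S_MM(ω)/(3Vε₀k_BT),
  normal-mode analysis of supplied Hessians with Eckart projection,
  projection of motion onto modes q_k = η_k^(±)·√m(x_fit − x_ref^(±))
  with per-frame helicity assignment, dipole decomposition
  μ = μ^rb + Σ_k μ_k q_k + residual, helicity-frozen spectra
  |μ_k⁻|²S_q̇q̇, helicity lifetimes τ_hel from the indicator ACF, and
  event-aligned conditional correlation functions.
* **Experimental arm** — Kramers–Kronig separation of ATR spectra
  (90° global phase), continuous-wavelet peak detection
  (second-derivative-Lorentzian analyzing function, γ = 3–6 cm⁻¹),
  Lorentzian deconvolution with clamped centers, band normalization to
  ν_s(CF₂), and concentration / chain-length trend tables.
* **Synthetic generators** — helical mirror-pair geometries with
  spring-network Hessians, exact-discretization Langevin mode dynamics
  with telegraph helicity flips, and forward-modelled ATR spectra — so
  every stage is testable against analytic oracles. For a telegraph
  flip rate k and a 180° dipole rotation, the band FWHM exceeds the
  frozen width by exactly 4k/(2πc), with the integrated intensity
  unchanged; this identity anchors the test suite.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Emulate a concentration series in which only the helicity-reversal
kinetics change (flip rates 0.1, 0.4 and 1.0 ps⁻¹), then compare the
full vibrational band of the strongest C–F-band mode with its
helicity-frozen counterpart:

```python
from fluorspec.pipeline import run_trajectory_workflow

config = {
    "synth": {
        "n_steps": 2**16,
        "flip_rates": [0.1, 0.4, 1.0],
        "labels": ["a", "b", "c"],
        "seed": 2,
    },
}
report = run_trajectory_workflow(config, "run_out")
print(report["summary"])
```

prints (abridged):

```
label  flip_rate_per_ps  fwhm_full_cm  fwhm_frozen_cm  tau_hel_ps
a      0.1               5.38          3.46            9.37
b      0.4               11.45         3.47            2.31
c      1.0               20.40         3.15            0.81
```

Reading the numbers: the helicity-frozen width (≈3.2–3.5 cm⁻¹) is set
by the vibrational damping alone and stays flat, while the full band
broadens from 5.4 to 20.4 cm⁻¹ as the flip rate grows — the excess
tracks the analytic 4k/(2πc) = 2.1, 8.5 and 21.2 cm⁻¹. The helicity
lifetime falls from 9.4 to 0.8 ps, and the free-energy profile of the
backbone dihedral (written per label to `run_out/`) is identical
across the series: the broadening is kinetic, not thermodynamic.

The same mechanism appears in the experimental arm:

```python
from fluorspec.pipeline import run_ftir_workflow

out = run_ftir_workflow({"synth_ftir": {"snr": 200.0}}, "ftir_out")
print(out["trends"]["series"][["label", "assignment", "fwhm", "area_norm"]])
```

where the ν_s(CF₂)-normalized band areas stay constant while every
FWHM grows monotonically along the series.

A `fluorspec` command-line tool wraps the workflows
(`fluorspec run --config run.toml`, plus `synth`, `helicity`, `ftir`,
`spectra` subcommands).

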