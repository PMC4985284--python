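# photosv

Multi-component analysis of fluorescence-detected sedimentation velocity
(FDS-SV) data using photoswitchable fluorescent proteins (psFPs) as temporal
tags.

## The problem

Sedimentation velocity analytical ultracentrifugation with fluorescence
detection resolves protein complexes free in solution at picomolar to
nanomolar concentrations, but the detector has a single excitation wavelength
(488 nm), so co-sedimenting components cannot be distinguished spectrally.
Photoswitchable fluorescent proteins offer a way out: under the weak,
radially scanned excitation of the detector they switch between fluorescent
and dark states over hours — the time scale of sedimentation — and each psFP
class does so with a characteristic rate and amplitude. That temporal
signature substitutes for a second color ("monochromatic multi-component"
detection), so separate sedimentation coefficient distributions can be
computed for, say, an rsEGFP2-tagged protein and a photostable-dye-labeled
partner from a single data set. This enables simultaneous isotherms for
competing homo- and hetero-dimerization at sub-nanomolar affinity.

`photosv` is for biophysicists designing or analyzing such experiments. It
provides:

* **Lamm equation solvers** for sector cells (finite-volume,
  Scharfetter–Gummel fluxes, Crank–Nicolson), including a coupled
  fluorescent/dark two-state variant for localized ("FRAP-like") exposure,
* **the psFP signal model**: accumulated photon dose along a sedimentation
  trajectory, single-exponential switching with asymptotic fraction α and
  rate β, 405 nm "blinking" resets, Gaussian-beam illumination profiles,
* **multi-component decomposition**: scans a(r, t) are fitted as
  a(r,t) = Σₚ ∫ cₚ(s) E⁽ᵖ⁾(s,r,t) χ(s,r,t) ds by non-negative least squares
  with second-difference Tikhonov regularization, giving per-component cₚ(s),
  weighted-average s-values (s_w), and Monte-Carlo confidence intervals,
* **experimental design**: the analytical discrimination error
  δc = cond(𝔼)·√2·δa/√n from the temporal signature cross-product matrix
  𝔼ₚq = Σₜ E⁽ᵖ⁾(t) E⁽q⁾(t) w(s,t), used to pick the optimal switching rate
  and to compare constant-scanning versus blinking protocols,
* **binding isotherms**: mass-action equilibria for competitive
  homo-/hetero-dimerization (Kd,22, Kd,33, Kd,23) and weighted fits of
  per-component s_w isotherms with Monte-Carlo intervals,
* **synthetic data generation** emulating FDS-SV acquisition (6.0–7.2 cm
  column, 50,000 rpm, 20 µm radial steps, scans every 5 min for 12 h) for
  every protocol, with ground-truth sidecars.

## Worked example

Simulate a mixture of a photostable dye conjugate (DL488-like, 4.25 S) and an
off-switching fusion (rsEGFP2-like, α = 0.0274, β = 5.5×10⁻⁴/s, 2.5 S) with
0.5% acquisition noise, then decompose it:

```python
import numpy as np
from photosv import (CellGeometry, Photoswitcher, SedimentingSpecies,
                     fit_mcmc, generate_synthetic)
from photosv.decomposition import ComponentSpec, monte_carlo_errors
from photosv.synthetic import (SyntheticComponent, SyntheticRunConfig,
                               default_scan_times)

geometry = CellGeometry()  # 6.0-7.2 cm column, 50,000 rpm
dl488 = Photoswitcher(name="DL488", alpha=1.0, beta=0.0)            # photostable
rsegfp2 = Photoswitcher(name="rsEGFP2", alpha=0.0274, beta=5.5e-4)  # off-switcher

config = SyntheticRunConfig(
    components=[
        SyntheticComponent(SedimentingSpecies(s=4.25, loading_signal=0.5), dl488),
        SyntheticComponent(SedimentingSpecies(s=2.5, loading_signal=0.5), rsegfp2),
    ],
    geometry=geometry,
    scan_times=default_scan_times(600.0, 21600.0),  # every 10 min for 6 h
    dr=0.005, noise_sd=0.005, seed=7, dt_max=30.0,
)
scans, truth = generate_synthetic(config)

fit = fit_mcmc(
    scans,
    [ComponentSpec("DL488", dl488), ComponentSpec("rsEGFP2", rsegfp2)],
    s_grid=np.arange(0.5, 8.01, 0.25),
    geometry=geometry, dt_max=30.0,
)
mc = monte_carlo_errors(fit, n_iter=100, seed=1)
print(f"fit rmsd: {fit.rmsd:.4f} signal units")
for name in ("DL488", "rsEGFP2"):
    dist = fit.distributions[name]
    lo, hi = mc.sw_interval(name, 68)
    print(f"{name}: total signal {dist.total_signal():.3f}, "
          f"sw = {dist.sw():.3f} [{lo:.3f}-{hi:.3f}, 68% CI] S")
```

Output:

```
fit rmsd: 0.0050 signal units
DL488: total signal 0.501, sw = 4.252 [4.251-4.253, 68% CI] S
rsEGFP2: total signal 0.498, sw = 2.506 [2.493-2.523, 68% CI] S
```

The rmsd equals the injected noise (the model fits to within acquisition
noise); each component's integrated signal recovers its loading (0.5), and
the weighted-average sedimentation coefficients recover the true 4.25 S and
2.5 S species despite both being observed at the same wavelength — the
switching component is identified purely by its temporal signature, with the
Monte-Carlo interval wider for the decaying signal, whose information fades
at late times.

## Command line

The `photosv` entry point wraps the library for shell use:

```bash
photosv simulate run.yaml --out runs/sim      # synthetic scan sets + truth sidecar
photosv fit runs/sim/scans fit.yaml --out runs/fit   # c_p(s) distributions (CSV) + summary
photosv design --s-ref 2.8 --delta-a 0.01 --out runs/design   # delta_c(beta) curve
photosv isotherm sw_data.csv system.yaml --out runs/iso       # Kd fits + curves
```

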