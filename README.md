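# photospec

Spectral and time-resolved fluorescence analysis of plant photosystem I
(PSI), for photosynthesis researchers working with steady-state
spectrofluorometry, streak-camera lifetime imaging and PAM fluorometry.

PSI carries low-energy "red" chlorophylls in its LHCI antenna that absorb
and emit beyond 700 nm. Excitations on these red forms need thermal energy
to climb back to the bulk chlorophylls and reach the reaction centre, so
the far-red share of PSI emission grows on cooling and the trapping
kinetics slow down. Because PSI emits exactly where PAM fluorometers detect
(through a far-red long-pass such as the RG9), it contaminates the F₀ and
F_M levels used to estimate PSII quantum efficiency. This package provides
the complete analysis chain for quantifying these effects:

* **Preprocessing** (`photospec.preprocess`) — scattering correction
  (zero at 750 nm, mean-slope baseline over 750–800 nm), area and peak
  normalisation, Savitzky–Golay smoothing, sub-nanometre peak location, and
  the red-form temperature statistic (700–800 nm area relative to 293 K).
* **Global lifetime analysis** (`photospec.das`) — variable-projection
  fitting of streak images into decay-associated spectra (DAS),

      S(t, λ) = Σᵢ DASᵢ(λ) · [exp(−t/τᵢ) ⊗ IRF](t),

  with role assignment (transfer / bulk decay / red decay / contamination)
  and the average lifetime ⟨τ⟩ = (A₂τ₂ + A₃τ₃)/(A₂ + A₃).
* **Boltzmann temperature model** (`photospec.kinetics`) — a two-pool
  (bulk + red) kinetic model with detailed-balance uphill transfer
  k_up = k_down·(n_bulk/n_red)·exp(−ΔE/k_BT), steady-state spectra, decay
  eigenmodes and least-squares calibration of the energy gap ΔE.
* **PAM contribution** (`photospec.contribution`) — PSI share of
  filter-weighted fluorescence in F₀ and F_M and the resulting
  F_v/F_M = 1 − F₀/F_M, using lifetimes as yield proxies
  (69 ps PSI, 224 ps open PSII, 1.6 ns closed PSII).
* **Pigment unmixing** (`photospec.unmix`) — non-negative least-squares
  decomposition of acetone-extract absorption into pigment spectra and the
  Chl a/b ratio.
* **Statistics** (`photospec.stats`) — one-way ANOVA, Tukey HSD and a
  compact letter display for species comparisons.
* **Synthetic data** (`photospec.synthetic`) — seeded generators for all of
  the above, so the entire pipeline runs and is tested without downloads.

Fit-shaped operations follow the scikit-learn estimator protocol
(`GlobalDASFit`, `BoltzmannCalibrator`, `PigmentUnmixer`: constructor
parameters, `fit`, fitted `_`-suffixed attributes, `get_params`/`set_params`),
with plain functions (`global_fit`, `calibrate`, `unmix`) as thin wrappers.

## Worked example

```python
import numpy as np
from photospec import (KineticModel, emission_spectrum, find_lambda_max,
                       global_fit, make_psii_emission, make_streak,
                       normalize_peak, psi_contribution, rg9_filter, savgol)
from photospec.lineshapes import BandModel
from photospec.spectra import Spectrum

# 1. model PSI emission at 293 K and locate the red-form maximum
model = KineticModel.default()           # 69-ps mean lifetime at 293 K
psi_293 = emission_spectrum(model, 293.0)
peak = find_lambda_max(normalize_peak(savgol(psi_293), (700, 800)), (700, 800))
print(f"PSI red-form maximum at 293 K: {peak.lambda_max_nm:.1f} nm")

# 2. global lifetime analysis of a synthetic streak image
grid = np.arange(620.0, 800.0, 1.0)
bulk = Spectrum(grid, 1.8 * BandModel(687.0, 25.0)(grid))
red = Spectrum(grid, BandModel(727.0, 30.0)(grid))
img = make_streak([(35.0, bulk), (120.0, red)], counts_scale=1e4, seed=0)
result = global_fit(img, n_components=2, tau_init_ps=[20.0, 200.0],
                    roles={0: "bulk_decay", 1: "red_decay"})
taus = ", ".join(f"{c.lifetime_ps:.1f}" for c in result.components)
print(f"fitted lifetimes: {taus} ps;  <tau> = {result.average_lifetime_ps:.1f} ps")

# 3. PSI share of RG9-filtered fluorescence in F0 and FM
res = psi_contribution(psi_293, make_psii_emission(), rg9_filter())
print(f"PSI fraction of F0: {100 * res.f0_psi_fraction:.0f}%   "
      f"of FM: {100 * res.fm_psi_fraction:.0f}%   Fv/FM = {res.fv_over_fm:.2f}")
```

Output:

```
PSI red-form maximum at 293 K: 733.0 nm
fitted lifetimes: 34.9, 120.4 ps;  <tau> = 68.9 ps
PSI fraction of F0: 38%   of FM: 8%   Fv/FM = 0.79
```

The fitted lifetimes recover the 35/120 ps decay classes that generated the
image, and their area-weighted mean reproduces the ~69-ps PSI trapping
lifetime. Through a far-red long-pass, PSI supplies roughly two fifths of
the minimal-fluorescence signal but less than a tenth of F_M — the reason
uncorrected PAM readings understate PSII quantum efficiency.

A command-line interface mirrors the library
(`photospec preprocess|redform|simulate|dasfit|tempmodel|contribution|pigments|compare`);
each subcommand prints JSON or writes the standard two-column table formats.

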