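# Methods

This note documents the models, estimators and numerical choices behind
`photospec`, in the order the analysis pipeline runs them.

## Scope and data model

The package analyses the spectroscopy of plant photosystem I (PSI) and its
low-energy "red" chlorophylls: steady-state absorption and emission spectra
(two-column wavelength/intensity tables, nm and instrument units), streak-camera
time-resolved fluorescence images (counts on a time × wavelength grid), and the
derived quantities used to compare species and temperatures. All wavelength
integrals are trapezoidal on the recorded grid with window endpoints included
by linear interpolation; on a uniform 1-nm grid this equals a plain intensity
sum up to end corrections, while staying well defined on non-uniform grids.

## Preprocessing

* **Scattering correction** (absorption): the spectrum is zeroed at 750 nm and a
  line `m·(λ − 750) + A(750)` is subtracted, with `m` the mean finite-difference
  slope over 750–800 nm. The output is exactly zero at 750 nm and has zero mean
  slope over the window; a pure band spectrum that is already zero beyond
  745 nm passes through unchanged to 1e-9.
* **Normalisation**: by area over 650–750 nm (absorption) or by the maximum in a
  window (emission; 675–690 nm for the bulk peak, >700 nm for red-dominated
  spectra). Both are idempotent and scale invariant.
* **Smoothing**: Savitzky–Golay, 21 points, 2nd order, on uniform grids only
  (non-uniform input raises with instructions to resample). Edges use the
  polynomial fitted to the last full window. A symmetric window must be odd;
  21 is the nearest odd width to a nominal 20-point setting, and on 1-nm grids
  the difference is immaterial. Note that this filter flattens a σ = 10 nm
  Gaussian peak by about 1% of its height — smoothing before peak-height
  normalisation is deliberate and consistent across all spectra.
* **Peak location**: the reported λmax is the vertex of a parabola through the
  grid argmax and its two neighbours. Emission maxima are conventionally quoted
  to sub-nanometre precision on 1-nm data, which a raw argmax cannot support;
  parabolic refinement recovers off-grid Gaussian centres to <0.05 nm. At a
  window edge the raw argmax is returned flagged `edge`; >3 tied maxima return
  the plateau centre flagged `plateau`.
* **Red-form statistic**: per spectrum in a temperature series — subtract the
  minimum, normalise to the 675–690 nm bulk peak (this absorbs slow
  photodamage between temperature steps), integrate 700–800 nm; all values are
  divided by the 293 K value. If 293 K was not measured, the reference is
  linearly interpolated from the neighbouring temperatures. Whether the
  minimum is zeroed before or after peak normalisation is exposed as
  `zero_min_first` (default True); for well-behaved spectra the two orders
  differ only through the additive offset.

## Global lifetime analysis (decay-associated spectra)

The streak image model is

    S(t, λ) = Σᵢ DASᵢ(λ) · [exp(−t/τᵢ) ⊗ IRF](t),

with a Gaussian instrument response of fixed width (a calibrated instrument
property) and fitted time zero (which drifts between measurements; fixing it is
an option). The convolution kernel is the exponentially modified Gaussian

    k(t) = ½ exp(σ²/2τ² − x/τ) erfc((σ/τ − x/σ)/√2),  x = t − t₀,

evaluated through `erfcx` on the early-time branch and `erfc` on the late-time
branch so neither overflows; it matches adaptive-quadrature convolution to
1e-15 and tends to the causal exponential as σ → 0.

Fitting uses **variable projection**: for candidate lifetimes the amplitude
spectra are the exact linear least-squares solution against the kernel basis,
and only the (log) lifetimes and t₀ are iterated nonlinearly
(`scipy.optimize.least_squares`, bounds 0.5 ps – 5 ns in log space for
positivity and conditioning). At convergence this equals the full joint fit,
which is verified against a brute-force joint optimiser on small instances.
Images are averaged into 5-nm wavelength bins before fitting.

Component roles are auto-assigned by a heuristic mirroring how DAS are read by
eye — a component with substantial lobes of both signs is energy *transfer*
(bulk → red equilibration); the longest-lived component with a blue (<700 nm)
maximum is *contamination* (free Chl, LHCII, PSII); the remaining two are
*bulk decay* and *red decay* in lifetime order — and can always be overridden
by an explicit index→role mapping. The average PSI lifetime is the area-
weighted mean over the two decay components,
⟨τ⟩ = (A₂τ₂ + A₃τ₃)/(A₂ + A₃), computed before or after DAS normalisation
(it is invariant). DAS normalisation divides all amplitudes by Σ|areaᵢ|
(total absolute area 1); per-component unit-area normalisation is offered as a
flag since either reading of "normalised to the total area" is defensible.

Recovery performance at the study conditions (800-ps window, 2-ps sampling,
16-ps IRF, 5-nm bins, ~10⁴ peak Poisson counts, four components at
10/35/120/400 ps): lifetime bias is below 1% for every component; single-shot
scatter is ~2% (1σ) for the 10-ps transfer component — which sits *under* the
IRF width — and well below 1% for the slower components. The 6–20 ps class is
therefore reported with that caveat.

## Boltzmann temperature model

Two emitting pools — bulk (685 nm, containing the trap) and red (720–745 nm) —
with degeneracies n_bulk : n_red = 20 : 1 and an energy gap ΔE. Downhill
transfer k_down is fixed; the uphill rate follows detailed balance,

    k_up = k_down · (n_bulk/n_red) · exp(−ΔE / k_B T),

so with losses switched off the stationary distribution is exactly Boltzmann.
Trapping (k_trap) acts on the bulk pool, radiative and non-radiative losses
(k_rad, k_nr) on both; lineshapes are temperature-independent Gaussians —
the temperature dependence of the spectrum is carried entirely by the pool
populations, which is the hypothesis the model exists to express. Two pools
plus a trap is the smallest structure that reproduces the observed
phenomenology (transfer component, bulk and red decay classes, monotone
red-fraction decrease with temperature); the pool list is extensible if finer
compartmentation is ever needed.

Defaults: ΔE = 0.08 eV; k_down = 0.2 ps⁻¹ (5-ps downhill transfer, fast
relative to all losses so the pools sit near thermal equilibrium);
k_rad = (15 ns)⁻¹ and k_nr = (2 ns)⁻¹ (textbook chlorophyll-a values); k_trap
is solved at construction (Brent root-find on the analytic mean trapping time
1ᵀ(−M)⁻¹p₀) so that the 293 K mean excitation lifetime is 69 ps, the measured
plant PSI-LHCI value. In the near-equilibrium regime the 286 K/293 K far-red
area ratio is ≈ exp(ΔE/k_B·(1/286 − 1/293)) ≈ 1.08, i.e. the ~10% rise
observed on cooling follows from the gap alone. Steady-state emission is
F(λ) = k_rad Σ_pool p·lineshape(λ); decay components come from the 2×2 rate
matrix eigendecomposition (a near-defective matrix triggers a perturbation
fallback with a warning), and the amplitude-weighted mean of the decay
lifetimes equals the analytic mean trapping time identically.

Calibration fits ΔE (optionally also k_down, though steady-state series barely
constrain it) to a measured red-form series by least squares on the relative
areas, computed through the *same* statistic pipeline applied to measured
data. A flat series raises (non-identifiable). Recovery of a known 0.08-eV gap
from model-generated series is within 5%.

## PSI contribution to PAM fluorescence

PSI and PSII emission spectra are normalised to unit total area over their
full recorded range (distinct from the 650–750 nm absorption window — the
point is a yield-neutral shape comparison), multiplied by the detection-filter
transmission and integrated to transmitted signals s_PSI, s_PSII. With
fluorescence lifetimes as yield proxies — 69 ps (PSI), 224 ps (open PSII),
1.6 ns (closed PSII) — and excitation ratio r (default 1, equal excitation):

    F₀ = s_PSI·τ_PSI·r + s_PSII·τ_open,   F_M = s_PSI·τ_PSI·r + s_PSII·τ_closed,
    PSI fraction = PSI term / total,       F_v/F_M = 1 − F₀/F_M.

The result is invariant to rescaling either input spectrum; with
τ_open = τ_closed, F_v/F_M is exactly 0; F_v/F_M decreases monotonically in r,
which quantifies the leverage of the equal-excitation assumption. The
transmitted-signal integral can optionally be restricted to ≥700 nm; with a
long-pass filter the difference is confined to the cut-on transition
overlapping the PSII tail (≲2 percentage points on the F₀ fraction here, less
with a sharper glass). The packaged filter curve `data/rg9_synthetic.tsv` is a
constructed stand-in for an RG9-class far-red long-pass (sigmoidal cut-on near
705 nm, 88% plateau), evaluated by linear interpolation and fully blocking
outside its tabulated range; analyses of real instruments should substitute
the manufacturer's tabulated curve via the `--filter` option.

## Pigment unmixing

Acetone-extract absorption is fitted over 350–750 nm as a non-negative linear
combination of pigment basis spectra (active-set NNLS; concentrations cannot
be negative). KKT optimality is verified on every fit (zero gradient on the
active set, non-negative on the zero set); a basis with condition number
>1e8 or an all-zero extract raises. The Chl a/b ratio is the ratio of the
scaled chlorophyll weights and is invariant to global rescaling of the
extract. The packaged basis is a Gaussian stand-in (Soret + Qy bands per
pigment), synthetic by construction; quantitative work requires measured
extinction spectra as user files. At 1% peak-level Gaussian noise the weight
bias is below 1% over 100 realisations.

## Replicate statistics

Technical replicates are averaged before any testing; biological replicates
enter a one-way ANOVA followed by all-pairs Tukey HSD (studentized-range
p-values from statsmodels). The compact letter display uses insert-and-absorb:
two groups share a letter iff their adjusted p ≥ α (a tie at exactly α counts
as not significant, matching a strict p < α criterion). The resulting letter
columns equal the maximal cliques of the non-significance graph, verified
against exhaustive subset enumeration for up to five groups. Reported "±"
values are standard errors over biological replicates (sd/√n, ddof = 1).

## Synthetic data

The generators produce data with the statistical structure the estimators
assume, at the study conditions: PSI emission whose bulk/red balance follows
the kinetic model's populations (hence the monotone temperature behaviour),
a temperature-independent PSII shape (685/695 nm bands, weak vibronic tail),
streak images from the analytic kernel with Poisson counting noise (800-ps
window, 2-ps sampling, 16-ps IRF — below the instrument-limited lifetime
class but above the shortest reported transfer times, a documented
limitation), and extract spectra from the Gaussian pigment basis. All
generators are pure functions of (parameters, seed). What passing tests show
is that the estimators recover what generated the data under realistic noise;
they do not certify behaviour on real spectra with vibronic structure,
wavelength-dependent baselines or detector nonlinearity, none of which the
generators emulate.

## Degenerate inputs and tie-breaks

Duplicate wavelengths are rejected at parse time with the offending line
named; windows that miss the grid raise rather than return empty integrals;
zero-area normalisation, all-zero peak windows, flat calibration series,
all-equal replicate groups and fully blocked spectra all raise with specific
messages. Lifetime ratios below 1.05 in a fit trigger a degeneracy warning;
negative expected streak counts (possible with transfer components) are
clipped at zero with a warning before Poisson sampling.

## Problem sizes

Default analyses run on 1-nm spectra (201–451 points), 5-nm-binned streak
images of ~400 × 36 cells, 20-seed Monte-Carlo recovery checks and
100-seed unmixing checks; the complete test suite and the acceptance script
each run in seconds on one CPU.
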