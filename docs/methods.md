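# Methods

## Model

Each tissue layer is a homogeneous lossy dielectric characterised by a
complex permittivity in the engineering `e^{+jωt}` convention,

    ε*(ω) = ε(ω) − j σ(ω)/ω        [F/m],

so a parallel RC one-port collapses to one *complex capacitor*
`C* = ε*·g` with impedance `Z = 1/(jωC*)`; `g = C/ε` [m] is the purely
geometric factor of the layer under the given electrode pair.  All internal
arithmetic is SI (F/m, m, Ω, Hz); relative permittivities appear only at
I/O boundaries and inside the interdimensional-factor log arguments.

A stack of layers under a coplanar electrode pair decomposes into one
partial capacitor per layer.  The connection of a layer to the sub-network
below it follows the permittivity contrast at the interface, decided on
complex magnitudes with a relative tie tolerance of 1e-9:

* `|ε1*| > |ε2*|` (PPC): field shunts along the upper layer — parallel
  connection, `C_tot = (ε1−ε2)·I_PPC + ε2·g2`;
* `|ε1*| < |ε2*|` (SPC): field penetrates the upper layer — series
  connection, `1/C_tot = (1/ε1 − 1/ε2)/I_SPC + 1/(ε2·g2)`.

The interdimensional factors (IF)

    I_PPC = a0 + a1·ln|Δε_r| + a2·ln(h1)         (h1 in mm)
    I_SPC = (b0 + b1·ln(ε2r/ε1r))/h1 + c0

are regression-corrected geometric factors that absorb the error of
extending the planar partial-capacitance formulas to a finite 3-D electrode
geometry.  Their log arguments use magnitudes of relative permittivities so
the IF stays real for lossy media; the complex character of the layers
enters through the `(ε1−ε2)` and `1/ε` terms.  The classical PPC form is
printed in the source literature with `ln(ε2−ε1)` although PPC requires
`ε1 > ε2`; this package treats that as a typo and evaluates `ln|ε1−ε2|`.

N-layer stacks reduce recurrently from the top: the first pair is composed
into an integrated layer (effective permittivity `C/g2`, thickness
`h1+h2`), which is then paired with the next layer.  Per-layer network
elements come from each `(i, i+1)` interface (`(εi−εi+1)·I` for PPC,
`I/(1/εi − 1/εi+1)` for SPC); the infinite bottom layer contributes
`ε_N·g2`.  Classification is per frequency; if an interface's class flips
across the grid the composition follows the per-frequency class and a
crossover warning names the flip frequencies.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| IF coefficients | GF units | 10⁻³·(4.69,1.12,4.40) PPC; 10³·(2.83,1.00,1.30) SPC | published defaults; refit with `fit_if` |
| `calibration_scale` | — | 1.0 | unit interpretation of the IF (below) |
| `g2` | m | conformal estimate | bottom-layer geometric factor |
| gel resistance | Ω | 160 (forearm config) | series electrode-gel coupling |
| frequency grid | Hz | 201 points, 0.1–10⁴, log | mirrors the measurement protocol |
| harmonics | — | 4096, capped at material validity | pulse-synthesis truncation |

**The IF unit scale.**  The absolute unit of the printed coefficient
triples is not recoverable from their source: the PPC and SPC scales differ
by ~10⁵–10⁶, which no single unit convention explains, and the fitted
geometric factors came from an external field solver.  `calibration_scale`
multiplies every evaluated IF and defaults to 1.0; `calibrate_scale()`
performs a one-time anchoring of one layer's impedance magnitude to a
measured or literature value (every IF-derived layer impedance is exactly
inversely proportional to the scale, so one anchor fixes it).  The forearm
analyses in the tests anchor the baseline 1.5 mm skin layer at 30 kΩ
(scale ≈ 2.5e-5).

**g2 without a field solver.**  The effectively infinite bottom layer needs
a geometric factor.  Config may give it numerically; otherwise the package
estimates it by conformal mapping, treating the electrode pair as a
coplanar-strip line: `g2 = (L/2)·K(k′)/K(k)` with `k = s/(s+2w)`
(≈ 7.4e-3 m for 1 cm × 1 cm electrodes 1 cm apart).  End-fringing of the
finite strips is not modelled, so this is a lower-bound estimate.

**DC handling.**  All network algebra runs in admittance form
`Y = jωC*(ω)`, whose ω→0 limit is the conductance `σ·g`; the DC bin of the
pulse engine therefore maps the capacitor network onto a conductance
network with σ in the permittivity role and unchanged geometric factors.
The IF log arguments have no DC limit for PPC pairs (|Δε*| diverges), so
the DC bin evaluates them at the pulse fundamental; for SPC pairs the
ratio's DC limit is the σ ratio and the choice is immaterial.

**Infinite-layer rule.**  A bottom layer is treated as infinite when it is
at least ~10× thicker than the layer above; thinner bottoms warn rather
than fail.

## Coefficient fitting

`gf1_from_capacitance` inverts each two-layer capacitance into the observed
top-layer IF (`(C−ε2g2)/(ε1−ε2)` for PPC; `(1/ε1−1/ε2)/(1/C−1/(ε2g2))` for
SPC, the form consistent with the SPC composition equation), and `fit_if`
solves the exact linear-in-coefficients design by unweighted OLS
(regressors `1, ln|Δε|, ln h1` for PPC; `1/h1, ln(ratio)/h1, 1` for SPC) —
no nonlinear optimiser, hence no initialisation or convergence questions.
Rows with vanishing permittivity contrast are rejected with a reason.

A caution discovered while testing: at the shipped SPC coefficient scale
the series term `(1/ε1−1/ε2)/I` is ~3e-5 of the bottom term `1/(ε2g2)` on
the standard design, so the capacitance→IF transform subtracts two nearly
equal reciprocals.  Noise-free data round-trip exactly (float64 leaves
~1e-10 relative headroom), but 1% capacitance noise is amplified into
order-100% heavy-tailed errors on the observed SPC IF — the SPC
coefficients are effectively unidentifiable from noisy capacitance data at
this scale.  The surrogate generator therefore exposes
`noise_on={"capacitance","gf"}`: solver-output noise versus noise on the
regressed geometric-factor observation.

## Synthetic data

`generate_fem_surrogate` reproduces the full factorial fitting design (ten
relative-permittivity pairs per class from {10..50}, top thickness 2/4/6 mm
over a 50 mm bottom) with responses from the forward composition model —
it emulates the *design* of an electrostatic field-solver study, not solver
discretisation behaviour, so parameter-recovery tests certify the
transform+fit pipeline, not solver fidelity.

`gen_agar_pair` builds tabulated salted/pure agar spectra on the 201-point
grid: conductivities 0.05 vs 1.6 S/m (plausible for DI-water agar vs
10 g/L NaCl; the in-vitro study prints none), a water-like ε baseline, and
the strong low-frequency α-type dispersion that two-electrode measurements
of ionic hydrogels exhibit (apparent ε_r ~1e5 below 1 Hz decaying by
decades to 10 kHz, amplitude growing with ionic strength).  Magnitudes are
order-of-magnitude by design; the guaranteed invariant is
`|ε*_salted| > |ε*_pure|` everywhere.  The phantom agreement study is a
pipeline self-consistency harness (model vs model-plus-noise), not a
reproduction of a physical measurement: passing it shows the prediction
pipeline preserves spectral shape under 5% scatter, nothing about real
agar.

The tissue starter pack (`tissue_dielectrics.json`) is an approximate
transcription of the standard 4-term Cole-Cole tissue database (Gabriel et
al. 1996) for dry skin, (infiltrated) fat and muscle — external literature
values, swappable via config.  Dry skin was chosen over wet because the
stratum corneum dominates transcutaneous stimulation; this choice sets the
skin σ/ε corner and hence the predicted low-pass cutoff.

## Pulse engine

Pulses are periodic trapezoids (square with linear ramps, default 1 µs);
their Fourier coefficients are closed-form
(`c_k = A·W·F·sinc(kFW)·sinc(kFt_r)·e^{−jπkF(W+t_r)}`).  The network is
evaluated at every harmonic, phasor responses follow Ohm's law plus the
series/parallel chain, and one period is reconstructed by real inverse FFT
with all harmonics kept strictly below Nyquist (exact Parseval
correspondence).  Default truncation is 4096 harmonics or the material
validity limit, whichever is lower.

Sweep amplitude metric: the default is the **mean absolute current during
the pulse** (`mean_on`), with peak-in-period available via flag.  Peak was
rejected as the default because the reconstructed peak of a near-square
pulse is the band-limited inrush spike, set by the truncation bandwidth
K·F — at fixed K it varies severalfold across a 1–300 Hz repetition sweep
and is not monotone in pulse width, both artefacts of truncation rather
than physiology; the during-pulse mean is stable under truncation.

## Problem sizes used in the shipped tests

Coefficient recovery uses the full 30-row designs; noise-robustness runs
200 seeded replicates; the phantom agreement study 200 replicates × 201
frequencies; pulse checks use 2048–4096 harmonics.  The full suite runs in
a few seconds on one CPU.

## Known limitations

* The forearm magnitude checks are best-effort reproductions.  With the
  shipped dielectric table and the skin layer anchored at 30 kΩ the model
  yields: fat ≈ 300 Ω (literature-anchored claim ≈1 kΩ), muscle ≈ 640 Ω
  (claim ≈0.1 kΩ; this value depends only on the conformal g2 estimate —
  the claim implies an effective g2 ≈ 5e-2 m, ~7× the coplanar-strip
  value), low-pass cutoff ≈ 3.3 kHz (claim ≈100 Hz; set directly by the
  dry-skin σ/ε corner — a wet-skin table moves it to O(100 Hz)), total
  impedance 22–51 kΩ over 1–3 mm skin (claim 30–80 kΩ), width-sweep
  current 66→33 µA (claim 100→30), frequency-sweep ≈33 µA (claim ≈30),
  1 mA compliance ≈31 V (claim ≈40 V).  The corresponding acceptance tests
  assert the claimed bands and the out-of-band ones fail by design rather
  than being tuned.
* Magnitude-based PPC/SPC classification can produce a slightly negative
  real part of the composed capacitance (relative ~1e-6) when conduction
  makes `|ε1*| > |ε2*|` while `Re ε1* < Re ε2*`; the passivity property is
  guaranteed only when the magnitude and real-part orderings agree.
* No electrode–skin interface element beyond the series gel resistance, no
  electrode polarisation, no lateral discretisation (one capacitor per
  layer), no nerve activation downstream of the electrical response, and
  no Cole-Cole fitting of measured spectra (evaluation only).
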