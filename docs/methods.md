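# Methods

`hotspotmon` simulates non-invasive temperature monitoring of microwave
breast hyperthermia and studies two ways of turning differential microwave
measurements into a hotspot image: a convolutional encoder-decoder trained
directly on simulated data, and Born-iterative inversion with classical
regularization. This note records the models, the defaults and why, the
numerical choices, and what the synthetic data can and cannot show.

## Physical model

**Geometry.** The 2-D computation domain is a square grid of 2 mm cells
centered at the origin (50×50 at full scale, 0.1 m per side). x grows to
the right with the column index, y grows upward as the row index falls;
cell (0, 0) is top-left. Transmit/receive antennas are ideal line sources
of unit amplitude, equally spaced on a circle (16 antennas at 75 mm radius
at full scale), antenna 0 on the positive x-axis, counter-clockwise
ordering. Measurements are multi-static (each antenna transmits in turn,
all receive; the monostatic diagonal is computed and kept, with a flag to
mask it) and are repeated on a linearly spaced frequency grid, 16 points
over 0.5–2 GHz at full scale.

**Phantom.** The breast is a parametric tissue-class map: a 2 mm skin ring
on a circular breast outline, adipose bulk, randomly placed smooth
fibroglandular blobs and a circular tumor (radius 7.5 mm at (20, 0) mm at
full scale). Each class carries a single-pole Debye dispersion
ε_c(ω) = ε_∞ + Δε/(1 − jωτ) + jσ_s/(ωε_0) under the e^{−jωt} convention,
so ε_r falls and the effective conductivity σ = ωε_0·Im ε_c rises with
frequency, as biological tissue does over this band. The shipped Debye
parameters are literature-magnitude **substitutes** — the patient-specific
MRI-derived maps such a system would use are not public — chosen to
preserve the structural feature that matters here: low-permittivity fat
against high-permittivity fibroglandular/tumor tissue. The coupling medium
is non-dispersive with ε_r = 20, σ = 0.6 S/m. A `load_phantom` path accepts
user-supplied grids of any size; all label grids follow the phantom grid.

**Forward solver.** TM-polarized scattering is solved with a
method-of-moments discretization of the domain integral equation
E = E_inc + k_0² ∫ G χ E, with χ = ε_c − ε_cb and
G = (i/4)H_0^{(1)}(k_b|r−r′|). Cells are pulse basis functions on
equivalent-area circles (a = h/√π), giving closed Bessel/Hankel forms for
all cell integrals including the self term. The background wavenumber is
k_b = k_0 √(ε_rb + jσ_b/(ωε_0)) on the branch with Im k_b ≥ 0. One dense
LU factorization per (map, frequency) is shared by all transmitters, and
zero-contrast cells are eliminated from the system and recovered by
back-substitution. Receivers use the same cell-integral rule, which makes
the discrete multi-static matrix symmetric (reciprocal) to round-off.
Validation: against the exact Bessel-series solution for a homogeneous
cylinder in the lossy background the solver is within 2% relative L2 error
at ≥ 10 cells per background wavelength (measured ≈ 1.8% at the full-scale
geometry, 1 GHz, 32 cells/wavelength).

**Thermo-dielectric coupling.** Tissue heating changes dielectric
properties proportionally to the local reference values:
Δε_r = −ε_r·(0.0025·ΔT) and Δσ = σ·(0.0125·ΔT) per °C, applied at every
frequency (frequency enters only through the reference values), with one
global coefficient pair rather than tissue-specific ones. A quadratic
mismatch family substitutes ΔT_eff = (1−a)ΔT + aΔT²/24 into the same law
(degree a ∈ [0, 1]); it is anchored so every member agrees with the linear
law at ΔT = 0 and ΔT = 24 °C, the generator's range. The anchoring is this
package's construction for a "mildly nonlinear truth" family whose shape
matches measured tissue behavior. Coupling-medium cells are never
modified. The linear law inverts in closed form; the conductivity channel
(the stronger effect) is the default for temperature recovery, and cells
with near-zero reference values are flagged invalid rather than divided
through.

## Heating scenarios

Real treatment maps would come from a bioheat or electromagnetic-thermal
solver; training needs tens of thousands, so scenarios are sampled from a
generative recipe that reproduces the qualitative features of published
hyperthermia heating studies: smooth fields, layered fall-off around one
or more heating centers, a random region count, and a configurable chance
that the tumor is the focus at all. Defaults (all config-exposed, chosen
once): 1–3 regions uniform; peak rise uniform on [0, 24] °C; 2–5 annular
layers of 2–6 mm width with a linear peak-to-edge ramp; tumor heated with
probability 0.5 (the first region then centers on the tumor, the rest
uniform over breast-interior cells); Gaussian smoothing with σ = 1 cell;
cell-wise maximum when regions overlap, so the 24 °C cap is never
exceeded; baseline 37 °C (body temperature — the natural reference for a
40 °C danger threshold and a 40–45 °C therapeutic window). Externally
computed temperature maps (plain text matrices, e.g. exported from an
electromagnetic-thermal co-simulation) can be imported, with
nearest-neighbor resampling onto the phantom grid.

## Dataset, noise and labels

The cold forward problem is solved once per frequency and cached. Per
scenario: sample a temperature field, build the hot dielectric map, solve,
then corrupt hot and cold measurements **independently** with circular
complex AWGN at the prescribed SNR (10·log10 of signal-to-noise power;
power computed per frequency by default, since scattered power varies
strongly over the band; half the noise power in each quadrature). The
network input is the differential hot − cold, split into real and
imaginary channels per frequency (16×16×32 at full scale). The label is
the binary image of cells with T strictly above 40 °C (a cell at exactly
40 °C is not a hotspot). Splits are 70/15/15 of the scenario total
(35,000/7,500/7,500 at full scale); the fractions are config-exposed. Tensors are
normalized by the global standard deviation of the training split (the
differential fields are of order 10⁻⁵ of the incident field; the factor is
stored in the manifest and reapplied at evaluation; a no-normalization
mode exists). Clean pre-noise fields are retained so any test SNR can be
re-noised without re-solving physics.

## Detector

A convolutional encoder-decoder maps the input tensor to a probability
image on the phantom grid: zero-padded size-preserving 3×3 convolutions in
the encoder (64/128/256 filters, each block twice, at full scale), one
nearest-neighbor ×2 upsampling bridge, unpadded stride-1 transposed
convolutions in the decoder whose kernels (5,5,5,4,4 at full scale) grow
the map to the output size, ReLU + batch normalization on every hidden
layer, a 1×1 sigmoid output, and no pooling. The constraints above are fixed;
the concrete per-block filter counts are this package's realization,
validated at build time by an explicit spatial-size trace and fully
overridable. The
prediction is probability > α_dec, default 0.5; prediction sets are nested
in α_dec by construction.

The network and its training loop are implemented in NumPy (conv,
transposed conv, upsampling, batch norm, fused sigmoid/BCE gradient); all
gradients are verified against finite differences in the test suite.
Training: mean binary cross-entropy, SGD with momentum 0.8, batch 32, and
a continuous exponential decay η(t) = 0.01·0.1^(t/v) with v = ⌊N_epoch·
N_train/S_batch⌋ — one decade over the whole run; the formula is taken
literally rather than as a staircase. Weights use fan-in-scaled Gaussian
init with a recorded seed; data order and noise draws are seeded too. The
best-validation epoch's weights are restored at the end (a final-epoch
mode exists).

## Born-iterative baseline

The conventional comparator inverts the same differential data for a
temperature map. Both dielectric changes are proportional to ΔT, so the
frequency-dependent contrast change Δχ(ω) = [−0.0025·ε_r + j·0.0125·σ/(ωε_0)]·ΔT
is linear in the single real unknown map ΔT; folding the thermo-dielectric
factors into the Born operator is what makes stacking all frequencies into
one linear system coherent (a per-frequency Δχ unknown would not be
shared across the stack). The linearization about a *scattering* reference
must use the reference medium's Green's operator, not the coupling
medium's: a contrast perturbation also perturbs the internal field, which
re-radiates through the reference contrast. Algebraically the receiver
operator becomes Q_ref = Q + QX(I − MX)⁻¹M, which reduces to Q for zero
reference contrast; without this distorted-wave correction the
linearization error does not vanish for weak heating (verified in the
tests). The BIM loop alternates forward solve → linearize → regularized
update of ΔT (clamped to [0, 24] °C, supported on breast-interior cells)
until the relative residual stalls, 5 outer iterations by default.

Regularizers, from their textbook definitions on the real-stacked system:
Tikhonov (λ by the discrepancy principle when the noise norm is known,
else λ = 0.01·σ_max), TSVD (truncation index likewise by discrepancy, else
σ ≥ 0.01·σ_max), CGLS (iteration count as the regularizer, discrepancy
stop), FISTA (L1 proximal gradient, step 1/σ_max², weight 10⁻³·‖Aᵀd‖_∞ by
default). The expected differential-noise norm is computed from the SNR
(hot and cold noised independently → twice the single-measurement noise
power). The inverted channel and the parameter policies are config-exposed; the
defaults above are this package's choices.

## Problem sizes and what the tests show

Three presets resolve every default. `full`: the full-scale conditions
(50×50, 16 antennas, 16 frequencies, 50,000 scenarios, 40 epochs) —
provided and exercised only at the component level, since a full run is
multi-day on one CPU. `desk`: the scaled-down end-to-end condition used by
the acceptance checks and the acceptance script — 24×24 grid (2 mm cells,
breast radius 20 mm, tumor radius 4 mm at (8, 0) mm), 4 antennas at 40 mm,
4 frequencies over 0.5–2 GHz, 2,000 scenarios at 40 dB, 15 epochs,
detector width 24. `fixture`: a seconds-scale variant (50 scenarios, 2
frequencies, 3 epochs) for unit tests and examples. At the desk scale the
detector reaches ≈ 0.92 mean test accuracy against an ≈ 0.88 all-zeros
baseline, mean Dice ≈ 0.45, and shows the expected qualitative behaviors:
accuracy flat in test SNR above the training SNR and
degrading below; danger recall monotone in the decision threshold with an
interior accuracy optimum; the detector dominating every Born-iterative
regularizer on Dice, which collapses specifically on heated
low-permittivity tissue under measurement noise.

Scaling down changes absolute numbers: with 4 antennas and 4 frequencies
the data dimension (128 real values) is far leaner relative to the 576
unknown pixels than at full scale, so desk-scale scores undershoot
full-scale ones. Passing desk-scale checks therefore demonstrates the
pipeline's correctness and the orderings above, not clinical-grade
accuracy. The generator itself idealizes: one fixed 2-D phantom per
dataset (the method is patient-specific by design), no antenna coupling or
S-parameter calibration, AWGN only, and scenario statistics rather than
bioheat physics.

## Known limitations

* 2-D TM physics; no 3-D effects, realistic antenna patterns, or
  calibration chain.
* Tissue Debye parameters are documented substitutes; absolute dielectric
  values (hence absolute scattering levels) differ from any given patient.
* The equivalent-circle cell integrals are first-order accurate at tissue
  boundaries; staircasing dominates the ~2% cylinder-oracle error.
* Dice over scenarios with neither true nor predicted hotspots is
  undefined; such pairs are excluded from averages and counted separately
  in every report.
* FISTA's sparsity weight is a fixed fraction default, not tuned per
  scenario; its desk-scale scores should be read accordingly.
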