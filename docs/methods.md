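# Methods

## The measurement this package models

Wood secondary cell walls contain partially crystalline cellulose
microfibrils (lateral thickness 2–3 nm) packed side by side and
laterally aggregated into bundles (macrofibrils) a factor of five to
ten wider. In a fiber-diffraction SANS geometry — the cell axis
vertical, neutrons of wavelength 6.0 Å, detector distances of roughly
1.5 m, 8 m and 39 m jointly covering q = 0.002–0.3 Å⁻¹ — this lateral
structure scatters into a horizontal *equatorial* streak on top of an
isotropic background. Because neutrons see scattering-length-density
(SLD) contrast, water-filled voids dominate the signal unless they are
contrast-matched: impregnating the wall with PEG, whose solution SLD in
D₂O is close to that of cellulose and lignin, silences the large pores
and leaves the bundle-scale structure visible.

## Equatorial intensity model

The reduced equatorial anisotropic profile is modelled as the sum of
three physical terms plus a constant:

    I(q) = A_mf · ⟨Φ²(qR)⟩ · S_N(q)
         + A_b · exp(−q²/(2σ_b²))
         + B_pl · q^(−α)
         + C_bg

**Microfibril term.** Φ(x) = 2J₁(x)/x is the cross-section amplitude of
a long circular cylinder; the radius R is normal with mean `R_mean` and
std `R_sd`, truncated at R > 0, and ⟨Φ²⟩ is computed with 61-node
Gauss–Legendre quadrature against the normal weight on
[max(R_mean − 5 R_sd, 0), R_mean + 5 R_sd] (exact at `R_sd = 0`; agrees
with adaptive quadrature and Monte-Carlo references to better than
10⁻³). Packing interference is a finite one-dimensional paracrystal
along the hexagonal {100} stacking direction, spacing
d₁₀₀ = (√3/2)·a_cc, with cumulative Gaussian displacement disorder of
std g·d₁₀₀ across N coherent planes:

    S_N(q) = 1 + (2/N) Σ_{k=1}^{N−1} (N−k) F(q)^k cos(k q d₁₀₀),
    F(q) = exp(−q² (g d₁₀₀)² / 2).

This form is finite at q = 0 (S(0) = N), non-negative (it is an
averaged |Σ exp(iqx)|²), reduces to 1 for N = 1, and peaks near
q* = 2π/d₁₀₀ — the 0.1–0.2 Å⁻¹ packing peak from which the
centre-to-centre distance a_cc is read. A 1D stack was chosen over a
full 2D hexagonal paracrystal because only the peak position and width
are constrained by a single equatorial profile; the function is
isolated so a 2D variant can be swapped in.

**Bundle term.** A Gaussian centred at q = 0. It is identified with the
*cross-section* Guinier law of long oriented particles,
exp(−q² R_c²/2), giving R_c = 1/σ_b; a homogeneous circular
cross-section has R = √2·R_c, hence the reported diameter

    D = 2√2 / σ_b   (Å → nm at the reporting boundary).

A config switch (`convention="spherical"`) exposes the 3D alternative
R_g = √3/σ_b with the homogeneous-sphere relation R = √(5/3)·R_g, for
users who prefer the isotropic-particle reading; the cross-section form
is the default because the scatterers are long and oriented, and it
places D in the physically observed 12–19 nm range exactly when the
bundle term dominates the 0.01–0.05 Å⁻¹ window. Fitting the Gaussian to
the exact oriented-disc intensity over q·R_c < 1 reproduces the true
diameter within ~2% across D = 8–18.5 nm, which bounds the systematic
error of the Gaussian≡Guinier identification.

**Power law and background.** B_pl·q⁻⁴ (Porod, sharp interfaces of
pores and lumina; α may be freed within [3, 4]) and a flat C_bg.

Defaults (`WoodModelParams`): A_mf = 1, R_mean = 12 Å, R_sd = 2 Å,
a_cc = 43 Å, g = 0.2, N = 4, A_b = 30, σ_b = 0.0157 Å⁻¹, B_pl = 10⁻⁷,
α = 4, C_bg = 0. The amplitude ratio A_b/A_mf = 30 was set so that the
bundle Gaussian carries more than half of the non-background,
non-power-law intensity throughout 0.01–0.05 Å⁻¹, the qualitative shape
seen in softwood data; with these defaults the default σ_b maps to
D = 18.0 nm.

## Reduction of 2D patterns

Pixels map to (q, azimuth) through 2θ = arctan(r/sdd),
q = 4π sin θ/λ, with azimuth measured from the horizontal equator and
folded into [0°, 180°). Pixel intensities are counts divided by
exposure and by a cos³(2θ) solid-angle weight (full instrument
calibration is out of scope; profiles are in relative units unless
flagged absolute). Per log-spaced q-bin (40 bins/decade by default):

* equator band: azimuths within ±15° of the equator (both streak
  halves);
* isotropic estimate: mean pixel intensity in a 60°-wide reference band
  centred on the meridian (a mean, not a minimum — unbiased under
  Poisson noise);
* output: equator mean − reference mean, uncertainties in quadrature
  from Poisson counting statistics (summed band variance floored at one
  count). Negative values are retained as noise.

Profiles from different detector distances are rescaled onto a
reference configuration (default: longest distance) by a weighted
least-squares scalar over the q-overlap, chained through neighbours
when a profile does not overlap the reference directly, then
concatenated and rebinned with inverse-variance weights.

Two systematics are inherent and documented rather than hidden. First,
with 128×128-pixel frames the azimuth bands are sampled by few pixels
at small radii, so individual q-bins deviate from the analytic
band-average response by up to tens of percent; the deviation is
deterministic (it is the exact expectation of the estimator), identical
in reruns, and absorbed into the merge scale factors — shape parameters
of the fit are unaffected. Validation therefore compares noisy
reductions against the reduction of the noise-free expected-counts map,
which is the exact mean of the output because reduction is linear in
counts. Second, a *meridional* streak is not invisible to this
estimator: it sits in the reference band and produces a negative
equatorial profile; what is orthogonal is the equator-band numerator.

## Fitting

Weighted least squares on linear intensity (1/σ² weights; a log-I loss
is available for profiles spanning many decades) with
`scipy.optimize.least_squares` (trust-region reflective) inside bounds:
R_mean ∈ [8, 20] Å, a_cc ∈ [25, 60] Å, g ∈ [0.05, 0.45],
σ_b ∈ [0.005, 0.05] Å⁻¹, amplitudes ≥ 0. R_sd, N and α are frozen by
default — a single equatorial profile does not determine them. Because
the bundle Gaussian and the pore power law overlap strongly at low q, a
single local fit is unreliable; the default is 16 starts drawn from a
seeded Latin hypercube (amplitude axes sampled log-uniformly), keeping
the lowest cost. Intensities are normalised internally to the window
maximum, so the optimisation landscape is scale-free: identical seeds
give bit-identical results, and rescaling (I, σ) by c changes exactly
the amplitudes by c.

Standard errors come from the Jacobian at the optimum with
χ²-rescaling; columns are equilibrated before the pseudo-inverse
because parameter scales span ~10 orders of magnitude. For honest
intervals, a residual-resampling bootstrap refits profiles rebuilt as
model + σ·r* where r* are resampled *standardised* residuals
(raw residuals are not exchangeable across a curve spanning four
decades); refits restart from the full-data optimum. A guard warns when
the fitted Gaussian's half-maximum q exceeds the packing-peak position
(pathological term overlap), and when a fitted bundle diameter does not
exceed the fibril spacing.

## Polymer solution sizing

PEG coils are sized from isotropic profiles by (a) the Guinier law —
weighted regression of ln(I − bg) on q², Rg = √(−3·slope), with the
window shrunk iteratively until q_max·Rg ≤ 1.3 and the flat background
re-estimated from the mean tail residual above the fitted curve — and
(b) the Debye function of an ideal Gaussian coil,
I = I₀·(2/x²)(e⁻ˣ + x − 1) + bg, x = q²Rg², evaluated by series below
x = 10⁻⁴ to avoid cancellation. Debye with co-fitted background is the
default for PEG (a flexible coil); results are labelled by method
because the two radii differ outside q·Rg < 1. A profile whose decay
across the window is below ~3% raises "no Guinier decay" rather than
returning an arbitrary radius. Small coils (Rg ≈ 0.5 nm) need data to
q·Rg ≈ 3 (q ≈ 0.6 Å⁻¹) for the background to be separable.

## Synthetic data generator

`SyntheticSpec` emulates the study conditions: three 128×128-pixel
configurations (7.5 mm pixels, beam centred, 4.5-pixel beamstop mask)
at 1.5 m, 8 m and 39 m with λ = 6.0 Å, jointly covering
0.002–0.33 Å⁻¹ with overlaps. Per pixel the expectation is

    counts_scale · [I_an(q)·W(φ) + I_iso(q)] · cos³(2θ),

where I_an is the anisotropic model (microfibril + bundle + power law),
W a wrapped Gaussian in azimuth (period 180°, unit mean, default spread
10° for fiber misalignment — applied to *all* anisotropic terms, since
oriented lumina also streak equatorially), and I_iso a flat incoherent
level (default 0.05 in model units) plus an optional isotropic q⁻⁴
term. Counts are Poisson; `counts_scale = 100` expected counts per unit
model intensity at normal incidence gives count levels where the
packing peak is determined to well under a percent, as in a long
instrument run. One global seed expands to per-frame children via
`SeedSequence([seed, frame_index])`; 1D profiles use multiplicative
Gaussian noise I·(1 + ε·noise), default noise 3% of the model, typical
of reduced SANS data.

What the generator does **not** emulate: wavelength spread and
collimation smearing, detector efficiency maps, transmission and
absorption, multiple scattering, absolute calibration, and any
deviation of the real cell wall from the three-term model itself.
Passing tests therefore demonstrate that the chain
reduce → merge → fit → derive is unbiased and correctly error-propagated
under the model's own assumptions — not that the model is a complete
description of wood.

## Problem sizes and numerical choices

The validation suite runs three 128×128 frames per synthetic
measurement, 150-point 1D profiles, 16 multistarts per headline fit,
60-replicate bootstraps, and a 10⁶-draw Monte-Carlo oracle for the
size-averaged form factor. Peak positions come from a 2001-point grid
plus bounded local refinement (xatol 10⁻⁷). Merging nudges exactly
duplicated q values apart by 4 ulp before validation; empty rebin bins
are dropped; a fully masked or gapless-band q-bin is dropped with a
logged count rather than silently zeroed.

## Known limitations

* The exact sector widths, isotropic estimator and microfibril-term
  formulation used in earlier wood-SAS work are not uniquely specified
  in the open literature; the choices here (±15° equator band,
  mean-based 60° reference band, finite 1D paracrystal) are declared
  conventions, verified self-consistent, not claimed identical to any
  specific prior pipeline.
* The Gaussian≡Guinier bundle reading ignores inter-bundle correlation;
  it is adequate in the absence of a correlation peak, and carries the
  ~2–3% mapping systematics quantified above.
* Merge scale factors absorb band-sampling differences between
  configurations; amplitudes are therefore comparable only within one
  merged profile unless the data are absolutely calibrated.
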