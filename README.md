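# fibrilsans

Equatorial SANS analysis of cellulose microfibril bundles in
water-saturated wood.

Small-angle neutron scattering is one of the few probes that can see
the lateral nanostructure of an intact, never-dried wood cell wall:
cellulose microfibrils (2–3 nm thick) packed at center-to-center
distances of 3–4 nm and aggregated into bundles ~10–20 nm wide. With
the fiber axis vertical, that structure scatters into a horizontal
*equatorial* streak; filling the larger water-filled pores with PEG —
whose solution scattering-length density in D₂O nearly matches
cellulose and lignin — silences them by contrast matching, leaving the
bundle-scale signal visible. This package implements the full analysis
chain for that experiment, for people who reduce and fit fiber SANS
data from plant cell walls (or want to test such pipelines against
synthetic ground truth):

* **reduction** — map 2D detector frames to (q, φ), separate the
  equatorial anisotropic intensity from the isotropic background,
  merge detector distances, rebin on a log-q grid;
* **scattering_model** — the three-term equatorial model
  `I(q) = A_mf·⟨Φ²(qR)⟩·S_N(q) + A_b·e^(−q²/2σ_b²) + B_pl·q^(−α) + C_bg`,
  with Φ(x) = 2J₁(x)/x the cylinder cross-section amplitude and S_N a
  finite 1D paracrystal along the hexagonal {100} spacing
  d₁₀₀ = (√3/2)·a_cc;
* **fitting** — seeded multistart weighted least squares, per-term
  decomposition, bootstrap intervals, and the derived structure:
  interfibrillar distance a_cc and the bundle diameter from the
  cross-section Guinier reading of the Gaussian width,
  **D = 2√2/σ_b**;
* **solution_analysis** — Guinier and Debye (Gaussian-coil) sizing of
  PEG in solution;
* **sld** — neutron scattering-length densities from composition and
  density (bundled Sears table, H/D exchange, presets for cellulose,
  lignin, PEG, D₂O, H₂O);
* **synthetic_data** — seeded multi-distance detector frames and 1D
  profiles with known ground truth, so every stage is testable without
  instrument data.

The library is the interface: import `fibrilsans` from Python, or run
the narrative scripts in `examples/`. See `docs/methods.md` for the
model, estimators and their assumptions.

## Worked example

`examples/simulate_and_reduce.py` generates Poisson-noisy 128×128
frames at 1.5 m / 8 m / 39 m (λ = 6.0 Å) from a softwood-like truth
(a_cc = 43 Å, bundle diameter 18.5 nm) and reduces them:

```
frame sdd=1.5 m: 3.69e+05 counts total
frame sdd=8.0 m: 7.26e+06 counts total
frame sdd=39.0 m: 1.17e+09 counts total

merged equatorial profile: 94 points, q = 0.0009-0.3219 A^-1
inter-configuration scale factors: ['0.865', '0.957', '1.000']
```

`examples/fit_equatorial.py` fits the three-term model to such a
profile and derives the structure:

```
chi^2_reduced = 0.77
fibril spacing a_cc   = 42.89 A (+/- 0.05; truth 43.0)
Gaussian width sigma_b = 0.01529 A^-1

derived structure:
  bundle diameter        = 18.50 nm (truth 18.5)
  interfibrillar distance = 4.29 nm (truth 4.3)
  packing peak            = 0.1577 A^-1
```

The fibril spacing is read from the 0.1–0.2 Å⁻¹ packing peak; the
bundle diameter comes from the width of the Gaussian that dominates
0.01–0.05 Å⁻¹, converted through the cross-section Guinier law. Both
land on the known truth within their statistical errors.

`examples/sld_contrast.py` prints the contrast-variation argument in
numbers: a pore filled with 60% PEG/D₂O solution
(ρ = 3.32×10⁻⁶ Å⁻²) scatters ~42× more weakly against D-exchanged
cellulose than a D₂O-filled pore does. `examples/peg_sizing.py`
recovers a 1.0 nm PEG coil radius by both Debye (0.998 nm) and Guinier
(1.025 nm) fits.

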