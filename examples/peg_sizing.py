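"""Size a PEG coil in solution from an isotropic SANS profile.

Generates a Debye (Gaussian-coil) profile with a 1 nm radius of
gyration plus flat background and recovers Rg with both the Debye fit
(default for flexible polymers) and the Guinier law restricted to its
validity window q*Rg <= 1.3.
"""

import numpy as np

from fibrilsans import Profile1D, debye_function, fit_debye, fit_guinier

rg_true = 10.0  # A = 1.0 nm, mid-range for PEG in D2O
q = np.geomspace(2e-3, 0.6, 140)
model = 50.0 * debye_function((q * rg_true) ** 2) + 0.5
rng = np.random.default_rng(3)
sigma = 0.01 * model
profile = Profile1D(q=q, I=model + sigma * rng.standard_normal(q.size),
                    sigma=sigma)

debye = fit_debye(profile)
guinier = fit_guinier(profile, window=(q[0], 1.3 / rg_true))

print(f"truth:   Rg = {rg_true / 10:.2f} nm, background 0.5")
print(f"Debye:   Rg = {debye.Rg_nm:.3f} nm, "
      f"background {debye.background:.3f}")
print(f"Guinier: Rg = {guinier.Rg_nm:.3f} nm "
      f"(window q <= {guinier.fit_window[1]:.3f} A^-1)")
print(
    "\nBoth estimates sit inside the 0.5-2 nm range expected for PEG "
    "coils in D2O;\nthe method label matters because Guinier and Debye "
    "radii differ outside q*Rg < 1."
)
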