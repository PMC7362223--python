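"""Strut-spreading kinetics of a printed bioink filament.

After deposition a hydrogel strut widens toward an equilibrium diameter A
as d(t) = A·[1 − exp(−(t + t₀)/τ_s)].  The characteristic time τ_s sets
shape fidelity: slower spreading (larger τ_s) preserves the printed
geometry longer.  This script fits noisy synthetic series at the scales
measured for 3% and 4% alginate inks and compares their spreading times.
"""

import numpy as np

import saosfit as sf

t = np.linspace(0, 60, 50)
inks = {"3% alginate": (3.90, 10.65, 10.49), "4% alginate": (3.24, 15.61, 13.92)}

fits = {}
for label, (A, t0, tau_s) in inks.items():
    series = sf.generate_strut_series(A, t0, tau_s, t, noise_sd=0.02, seed=1)
    kin = sf.fit_strut_spreading(series)
    fits[label] = kin
    print(f"{label}: A = {kin.A:.2f} mm, t0 = {kin.t0:.2f} s, "
          f"tau_s = {kin.tau_s:.2f} s")

ratio = fits["4% alginate"].tau_s / fits["3% alginate"].tau_s
print(f"\nspreading-time ratio tau_s(4%)/tau_s(3%) = {ratio:.2f}")
print("The stiffer 4% ink spreads ~1.3x more slowly — mirroring the ratio "
      "of the inks'\nMaxwell characteristic times tau1 = eta1/E1 from their "
      "Burgers parameters.")
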