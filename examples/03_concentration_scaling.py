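"""Concentration scaling of a Burgers viscosity across an alginate series.

Polymer-solution parameters follow a quasi power law
value(c) = prefactor·(1 + c/c̃)^exponent.  Here the free-dashpot
viscosity η₁ is generated for concentrations 2–8% with the solvent
viscosity (1 mPa·s, water) as prefactor, mild noise is added, and the law
is refit twice: exponent free, and exponent pinned at the theoretical
isotropic-scaling value 3.
"""

import numpy as np

import saosfit as sf

rng = np.random.default_rng(0)
concentrations = [2, 3, 4, 5, 6, 7, 8]
data = [(c, 0.001 * (1 + c / 0.14) ** 3 * (1 + 0.03 * rng.standard_normal()))
        for c in concentrations]

free = sf.fit_concentration_scaling(data, "eta1", fixed={"prefactor": 0.001})
fixed = sf.fit_concentration_scaling(
    data, "eta1", fixed={"prefactor": 0.001, "exponent": 3.0})

print("free exponent:  c~ = {:.3f} ± {:.3f}, n = {:.2f} ± {:.2f}, RSS = {:.3g}"
      .format(free.c_tilde, free.standard_errors["c_tilde"],
              free.exponent, free.standard_errors["exponent"], free.rss))
print("fixed n = 3:    c~ = {:.3f} ± {:.3f},               RSS = {:.3g}"
      .format(fixed.c_tilde, fixed.standard_errors["c_tilde"], fixed.rss))
print("\nBoth fits land near the generating characteristic concentration "
      "(0.14).  With the\nexponent pinned at 3 the residuals stay at the "
      "noise level (~1% of the largest\nvalues) with one fewer adjustable "
      "parameter.")
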