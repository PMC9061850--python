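"""Estimate an off-rate from two-site exchange lineshapes.

For a fast-exchanging complex the 1D lineshape of each residue across a
titration encodes the dissociation rate.  Synthetic spectra at three
bound fractions are jointly fitted for a single shared k_off.
"""

import numpy as np

from amykin import fit_koff_lineshape, lineshape_two_site

grid = np.linspace(-600.0, 600.0, 1201)        # Hz
site_freqs = {13: (-120.0, 140.0), 17: (-80.0, 90.0)}
populations = {0: 0.2, 1: 0.45, 2: 0.7}        # bound fractions
koff_true = 6000.0                             # s^-1

rng = np.random.default_rng(0)
spectra = {
    res: {
        pt: lineshape_two_site(pb, *site_freqs[res], 8.0, 60.0, koff_true, grid)
        + rng.normal(0, 1e-5, len(grid))
        for pt, pb in populations.items()
    }
    for res in site_freqs
}

fit = fit_koff_lineshape(spectra, populations, site_freqs, 8.0, 60.0, grid)
print(f"true k_off   : {koff_true:.0f} 1/s (residence time ~170 µs)")
print(f"fitted k_off : {fit.koff:.0f} 1/s")
print(
    "\nRead-out: a k_off in the thousands per second puts the complex in "
    "fast exchange on the chemical-shift timescale, consistent with "
    "population-averaged peak positions."
)
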