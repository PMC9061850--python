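"""Fit a 1:1 fast-exchange dissociation constant to a CSP titration.

The bound fraction at each titration point follows the exact quadratic
isotherm; the global fit shares K_D across residues, profiles out each
residue's bound-state shift change, and estimates the error by a
residue-resampling bootstrap.
"""

from amykin import (
    default_exchange_model,
    fit_kd_titration,
    select_responsive_residues,
    simulate_titration,
    titration_csp_table,
)

model = default_exchange_model(KD=61.0)
ratios = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0]
series = simulate_titration(
    model, ratios, shift_noise_H=0.002, shift_noise_X=0.016, rng_seed=7
)

table = select_responsive_residues(titration_csp_table(series))
nonzero = [pt for pt in series.points if pt.ratio > 0]
fit = fit_kd_titration(
    table,
    P_total=[pt.P_total for pt in nonzero],
    L_total=[pt.L_total for pt in nonzero],
    n_boot=1000,
    rng_seed=7,
)

print(f"ground truth K_D : 61.0 µM")
print(f"fitted K_D       : {fit.KD:.1f} ± {fit.KD_err:.1f} µM (bootstrap SD)")
print(
    "\nRead-out: despite realistic peak-picking noise the shared-K_D fit "
    "over the responsive residues lands within a few µM of the truth; "
    "the bootstrap SD quantifies how much single residues sway the fit."
)
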