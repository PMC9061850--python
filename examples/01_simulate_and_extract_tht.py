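"""Simulate a ThT dose-series plate and extract the kinetic parameters.

A 5 µM amyloidogenic peptide aggregates de novo while an inhibitory
chaperone is titrated across ten logarithmically spaced molar ratios
(1:5000 to 1:1) plus an inhibitor-free control, in triplicate.  The
extraction pipeline smooths each curve, takes numerical derivatives,
segments the growth phase at the 5%-of-maximum-derivative threshold and
reports the kinetic parameters per condition.
"""

import numpy as np

from amykin import (
    AssayDesign,
    default_aggregation_model,
    generate_tht_assay,
    parameter_table,
)

design = AssayDesign(rng_seed=1)
dataset = generate_tht_assay(default_aggregation_model(), design)
table = parameter_table(dataset, align=True)

summary = table.groupby("ratio")[
    ["lag_time", "growth_duration", "max_growth_rate", "plateau_height"]
].mean()
print(summary.round(2).to_string())
print(
    "\nRead-out: increasing inhibitor:monomer ratio slows growth "
    "(smaller max_growth_rate, longer growth_duration) and lowers the "
    "final ThT plateau -- the signature of sub-stoichiometric "
    "interference with elongation and secondary nucleation rather than "
    "monomer sequestration.  At the strongest inhibition the fluorescence "
    "amplitude approaches the noise floor, so derivative-based lag "
    "estimates become unreliable there."
)
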