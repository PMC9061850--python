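# amykin

Analysis of chaperone inhibition of amyloid formation: aggregation
kinetics, NMR interface mapping, binding affinity and exchange-rate
fitting, and docking-restraint generation — with synthetic ground-truth
generators for every stage.

Amyloid formation by intrinsically disordered peptides such as the
37-residue islet amyloid polypeptide (IAPP/amylin) proceeds through
primary nucleation, fibril elongation and fibril-surface-catalyzed
secondary nucleation.  Molecular chaperones like prefoldin can suppress
this cascade at sub-stoichiometric concentrations by binding fibril ends
and surfaces while also engaging the free monomer weakly and transiently.
`amykin` is for structural biologists and biophysicists who need to turn
the raw read-outs of such a study — plate-reader ThT time courses, NMR
peak lists, BLI steady-state tables — into quantitative, reproducible
numbers.

## What it computes

- **ThT kinetics** (`amykin.kinetics`): smoothing (11-point moving
  average), symmetric-difference derivatives, growth-phase segmentation at
  the 5%-of-maximum-derivative threshold, replicate lag alignment, and the
  standard parameters per curve — lag time, growth duration, maximal /
  average / initial growth rate, plateau height, acceleration maximum —
  plus the logarithmic 1:5000→1:1 dose-series builder and a raw-vs-
  normalized trend comparison.
- **Binding analysis** (`amykin.binding`): chemical shift perturbations
  Δδ = √(0.14·ΔN² + ΔH²), peak-broadening ratios I/I₀ (threshold 0.26),
  PRE classification at >50% intensity loss, a global 1:1 fast-exchange
  K_D fit against the quadratic isotherm with residue-resampling
  bootstrap, a two-site Bloch–McConnell lineshape with a joint k_off fit,
  and Langmuir steady-state BLI fitting R_eq = [A]·R_max/([A]+K_D).
- **Restraints** (`amykin.restraints`): active-residue selection on both
  binding partners from the CSP-majority and PRE-loss rules, exported as
  plain lists or ambiguous-interaction-restraint (AIR) stanzas for
  data-driven docking.
- **Peptide constructs** (`amykin.peptides`): average mass and formal
  charge of synthesized constructs with amidation, disulfides and
  N-terminal adducts (β-alanine, biotinyl, acetyl, DOTA).
- **Synthetic data** (`amykin.synthetic`): a nucleation–elongation moment
  ODE with Langmuir end/surface inhibition, a plate-assay generator with
  noise and lag jitter, fast-exchange titration and PRE profile
  simulators, and Langmuir BLI tables — all pure functions of their
  parameters and seed.

## Worked example

Fit a dissociation constant to a noisy synthetic NMR titration
(`examples/03_fit_kd_titration.py`):

```python
from amykin import (default_exchange_model, simulate_titration,
                    titration_csp_table, select_responsive_residues,
                    fit_kd_titration)

model = default_exchange_model(KD=61.0)              # ground truth, µM
series = simulate_titration(
    model, [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0],
    shift_noise_H=0.002, shift_noise_X=0.016, rng_seed=7)

table = select_responsive_residues(titration_csp_table(series))
nonzero = [pt for pt in series.points if pt.ratio > 0]
fit = fit_kd_titration(table,
                       P_total=[pt.P_total for pt in nonzero],
                       L_total=[pt.L_total for pt in nonzero],
                       n_boot=1000, rng_seed=7)
print(f"fitted K_D: {fit.KD:.1f} ± {fit.KD_err:.1f} µM")
```

This prints

```
fitted K_D: 58.6 ± 3.8 µM (bootstrap SD)
```

i.e. the shared-K_D global fit over the responsive residues recovers the
61 µM ground truth within the bootstrap uncertainty despite realistic
peak-picking noise.  The other `examples/` scripts walk through the
remaining capabilities (ThT extraction, CSP mapping, BLI, PRE restraints,
lineshape k_off, construct masses), each printing a short read-out of
what its numbers mean.

A thin CLI mirrors the stages:

```sh
amykin simulate --seed 1 --out plate.csv --anno wells.csv
amykin extract plate.csv --anno wells.csv --window 11 --deriv-depth 4 --out kin/
amykin mass KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY --amide --disulfide 2-7
amykin run --seed 0 --out demo/         # full synthetic pipeline
```

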