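# Methods

`amykin` quantifies how a molecular chaperone inhibits amyloid formation by
an intrinsically disordered peptide.  It covers four experimental read-outs
— ThT aggregation kinetics, NMR titrations (CSP and line broadening), PRE
interface mapping, and steady-state BLI — plus the conversion of interface
maps into docking restraints, and ships synthetic-data generators that act
as ground truth for every stage.

## ThT kinetic-parameter extraction

A ThT fluorescence time course reports fibril mass.  Each curve is

1. smoothed with an 11-point centered unweighted moving average (the window
   shrinks symmetrically at the boundaries so length is preserved),
2. differentiated with a symmetric difference quotient
   d(i) = (y[i+h] − y[i−h]) / (t[i+h] − t[i−h]) with half-width
   h = depth//2 (default depth 4, so h = 2); points near a boundary use
   the largest symmetric half-width available and the two endpoints use a
   one-sided quotient.  The second derivative applies the same operator to
   the smoothed first derivative.  The symmetric quotient is exact for
   quadratics on uniform grids, which the tests exploit,
3. segmented: growth starts at the first index where the first derivative
   reaches 5% of its maximum and ends at the first sub-threshold crossing
   after the derivative maximum (falling back to the last index if the
   curve never plateaus).  The first-crossing tie-break is deliberate — it
   is robust to pre-maximum noise and is what a linear scan of the rule
   gives.

From the segmentation: lag time (time of growth start), growth duration,
maximal growth rate (max of d1), average growth rate (fluorescence gain
over the growth phase divided by its duration), initial growth rate (mean
of the first 20 d1 values from the start of the recording — meaningful for
seeded elongation assays whose linear phase begins at t = 0), plateau
height (mean of the 50 points after growth end; fewer with a warning when
the record ends early) and acceleration maximum (max of d2).  Flat or
decreasing curves yield parameters flagged *undefined*, never zeros.

Replicates of a condition can be lag-aligned before averaging: each curve
is shifted along time by (mean lag − own lag) with linear re-interpolation
(edge values held), so the set's mean lag is preserved and shifts sum to
zero.

The dose series is a geometric progression of inhibitor:monomer molar
ratios, ten points from 1:5000 to 1:1 with exact endpoints, optionally
preceded by a ratio-0 control (11 conditions).  Three log steps below
equimolar the ratio is 1:5000^(3/9) ≈ 1:17.1, printed 1:17.

`compare_normalization` re-runs the extraction on per-curve max-normalized
data and reports the Spearman rank correlation of condition-mean trends
between raw and normalized tables — scale-free parameters are identical,
monotone dose responses give correlation 1.

## Aggregation simulator

Ground truth for the kinetics pipeline is the standard two-moment
nucleation–elongation model, state P (fibril number) and M (fibril mass,
monomer equivalents), free monomer m = m_tot − M:

    dP/dt = kn·m^nc + k2·θ_surf·m^n2·M
    dM/dt = 2·k+·θ_end·m·P

The factor 2 counts both growing ends of a fibril.  Inhibitor action is
fast equilibrium binding: θ_end = 1/(1 + c/K_end) throttles elongation,
θ_surf = 1/(1 + c/K_surf) throttles secondary nucleation, and the reported
mass is scaled by an empirical plateau factor 1/(1 + c/K_plat) describing
the dose-dependent drop of the final ThT plateau, for which no mechanism
is modelled.  Integration uses LSODA with rtol 1e-8 and atol 1e-10 µM so
the plateau is flat to solver precision; monomer conservation holds by
construction and trajectories that leave [0, m_tot] beyond tolerance raise
an integration error naming the parameter set.

Default study conditions: 5 µM monomer, nc = n2 = 2, kn = 8e-6, k+ = 25,
k2 = 1.2e-3 (units as in the dataclass), K_end = 0.12 µM, K_surf = 0.06 µM,
K_plat = 0.8 µM.  These were chosen once to give a de novo curve with a
few-hour lag and a plateau within 72 h, with growth durations stretching
by more than an order of magnitude across the 1:5000→1:1 dose series —
the qualitative fingerprint of sub-stoichiometric end/surface inhibition.
Plate curves are fluorescence = 100·M + 10 plus Gaussian noise (SD 2 FI)
and a per-replicate Gaussian lag jitter (SD 0.3 h, ≈6% of the lag) applied
as a time shift; each well draws from an independent RNG substream spawned
from the design seed, so output is bit-reproducible.  Seeded modes add
8.5% seed mass; sonicated seeds are 10× shorter than unsonicated ones,
multiplying the number of growth-competent ends.

## NMR binding analysis

**CSP.**  Δδ = sqrt(0.14·ΔN² + ΔH²) per residue between matched peak
lists; the *above-average* flag compares against the mean over residues
measurable in both lists (an explicit threshold can override).  Unmatched
residues are warned about, never dropped silently.  CSP is invariant under
a global reference offset.

**Broadening.**  I/I0 (complex over free); residues with I/I0 ≤ 0.26 are
flagged broadened.

**PRE.**  Per chain, residues with 1 − I_para/I_dia > 0.5 are PRE-active.
The synthetic ground truth keeps active/inactive losses strictly separated
across the 50% line so the rule is exactly recoverable before noise.

**K_D from CSPs.**  Fast-exchange observed shifts are population averages,
so csp(r, j) = Δδ_bound(r) · p_b(j), with the bound fraction from the
exact 1:1 quadratic isotherm
p_b = [(P0+L0+K_D) − sqrt((P0+L0+K_D)² − 4·P0·L0)] / (2·L0).
For fixed K_D the per-residue amplitudes are linear and profiled out,
reducing the fit to a bounded 1-D search in log10 K_D (10⁻³–10⁵ µM).
Errors come from a residue-resampling bootstrap (default 1000 draws,
seeded).  Fits are performed on residues with above-average mean CSP
(`select_responsive_residues`): because |Δδ| is non-negative, residues
with near-zero true response contribute folded noise that looks like an
instantly saturating component and biases K_D low.  This mirrors standard
practice of fitting selected well-responding, well-resolved peaks.  A fit
whose maximum saturation stays below 20% is returned with an
identifiability warning.  Default titration: L0 = 50 µM, chaperone:peptide
ratios 0.25–4 (saturation ≈ 0.7 at K_D = 61 µM — ratios only up to 2 leave
K_D ≈ L0 poorly identified), peak-position noise 0.002 ppm (¹H) and
0.016 ppm (¹⁵N), typical picking precision for resolved 2D spectra.

**k_off from lineshapes.**  A reduced 1-D two-site exchange model: the
absorptive spectrum is −Re[𝟙ᵀ L(ω)⁻¹ p] with the 2×2 Bloch–McConnell
matrix L built from site frequencies, R2 rates and exchange rates obeying
detailed balance (k_fb = k_off·p_b/p_f).  Its integral is independent of
k_off (verified numerically with log-spaced tails, since Lorentzian tails
decay as 1/ω).  k_off is fitted jointly across residues and titration
points by bounded search in log k_off, with per-spectrum scale factors
profiled out so intensity calibration cannot bias the rate.  This is a
deliberate reduction of full 2-D lineshape fitting: populations come from
the isotherm, not from the lineshape fit itself, and the shift-based K_D
and lineshape-based k_off remain separate estimators.

**BLI.**  R_eq = [A]·Rmax/([A]+K_D) by nonlinear least squares
(requires ≥3 distinct concentrations spanning a 10-fold range and
non-flat responses), with a concentration-point bootstrap; resamples with
fewer than 3 distinct concentrations are skipped.

## Restraint selection and export

Ligand (peptide) actives: above-average CSP in strictly more than half of
the titration ratios ("most of the ratios" formalized as a strict,
configurable majority).  Receptor actives: the per-chain 50%-loss PRE rule,
chains (α, β, β′) kept separate.  Both selections are monotone in their
thresholds — raising a threshold never adds residues.  Export styles:
`plain` (one `CHAIN: id,id,…` line, round-trips through the reader) and
`air` (one ambiguous-interaction stanza per active residue restraining it
to any active residue on any partner chain, TBL-like, byte-deterministic).
Docking itself is out of scope; the module ends at restraint files.

## Peptide construct accounting

Average masses (ExPASy residue table): sum of residue masses + water,
−0.98476 Da for C-terminal amidation, −2.01588 Da per disulfide, plus per
adduct its free-molecule average mass minus one water per amide bond
formed (β-alanine 71.079, biotinyl 226.29, acetyl 42.04, DOTA 386.40).
Values are reported to 0.1 Da, the precision of synthesis certificates;
the function returns the unrounded value so mass differences stay exact.
The computed masses of the amidated, Cys2–Cys7-bridged IAPP constructs sit
within 0.15 Da of certificate values — certificate rounding conventions
account for the last 0.1 Da, which is why tests assert to ±0.2 Da.  The
DOTA construct's printed mass is not asserted: it depends on which acetate
arm forms the amide, a linkage detail the certificate does not specify.
Charge uses the side-chain convention by default (Lys/Arg +1, Asp/Glu −1,
His neutral, termini ignored) — the only convention under which the IAPP
sequence is +2; a `full` convention adding free-termini charges is
available.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the real experiments —
sigmoidal dose-dependent kinetics with replicate noise and lag jitter,
fast-exchange titration shifts with two perturbed binding segments,
bimodal PRE losses, Langmuir BLI responses — with known ground truth, so
every estimator can be tested as a round trip.  They do not emulate
instrument drift or baseline artifacts, peak overlap and assignment
ambiguity in crowded spectra, partial peak doubling of near-equivalent
subunits, deviations from two-state exchange, or non-1:1 binding.
Passing round-trip tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every pathology of
real instrument data.

## Problem sizes and numerical choices

Test and demo runs use an 11-condition × 3-replicate plate on a 0.1 h grid
over 72 h, a 9-point titration of a 37-residue peptide, three receptor
chains of 117–140 residues, 8 BLI concentrations (0.5–150 µM), and
1000-draw bootstraps (fewer in unit tests); the full demo pipeline
completes in seconds.  Ties in segmentation resolve to the first index
satisfying the rule; degenerate inputs (flat curves, zero reference
intensities, missing partners) produce flagged results or errors rather
than silent zeros.  All simulators and fits are pure functions of their
parameters and seeds; file writers use fixed column order and 6
significant digits so repeated runs are byte-identical.

## Known limitations

- The K_D fit assumes fast exchange throughout; near-intermediate exchange
  would bias CSP-based affinities (the lineshape module exists precisely
  to probe that regime).
- The aggregation model is a minimal two-moment description: no
  fragmentation, length-dependent rates, or monomer-inhibitor binding.
- Restraint export targets a generic TBL-like dialect, not any specific
  docking engine's full grammar.
- The one-sided derivative endpoints are first-order accurate; parameters
  that depend on them (initial growth rate on very short records) inherit
  that accuracy.
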