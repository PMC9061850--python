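"""Synthetic ground-truth generators for every stage of the analysis.

These simulators emulate the structure of the study's raw instrument data
so the full pipeline is testable without any deposited dataset:

* a nucleation–elongation moment-equation ODE for amyloid mass growth,
  with sub-stoichiometric inhibitor action on fibril ends (elongation)
  and fibril surfaces (secondary nucleation) through fast Langmuir
  occupancies, and an empirical plateau attenuation;
* a plate-reader assay generator producing noisy, lag-jittered ThT
  fluorescence triplicates across a logarithmic dose series;
* a fast-exchange NMR titration generator with two perturbed binding
  segments on the peptide;
* paired diamagnetic/paramagnetic PRE intensity tables with a defined
  active-residue ground truth;
* Langmuir steady-state BLI responses.

All generators are pure functions of their parameters and RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .binding import Peak, bound_fraction, compute_csp
from .kinetics import ThTCurve, ThTReplicateSet, build_dose_series

__all__ = [
    "AggregationModel",
    "AssayDesign",
    "ExchangeModel",
    "PREGroundTruth",
    "IntegrationError",
    "simulate_aggregation",
    "generate_tht_assay",
    "simulate_titration",
    "titration_csp_table",
    "TitrationSeries",
    "TitrationPoint",
    "simulate_pre_profile",
    "simulate_bli",
    "default_aggregation_model",
    "default_exchange_model",
    "default_pre_truth",
    "IAPP_CSP_SEGMENTS",
]

# Ground-truth CSP-active residues on the 37-residue peptide: two binding
# segments (N-terminal/central and amyloidogenic region) plus flanking
# single sites, totalling 12 residues.
IAPP_CSP_SEGMENTS: frozenset[int] = frozenset(
    [6, 10, 11, 12, 13, 17, 18, 19, 24, 26, 27, 28]
)


class IntegrationError(RuntimeError):
    """ODE integration produced a non-finite state."""


@dataclass(frozen=True)
class AggregationModel:
    """Nucleation–elongation moment model with inhibitor action.

    State is fibril number P (µM) and fibril mass M (µM monomer
    equivalent), with free monomer m = m_tot − M:

        dP/dt = kn·m^nc + k2·θ_surf·m^n2·M
        dM/dt = 2·kplus·θ_end·m·P

    θ_end = 1/(1 + c_inh/Kend) and θ_surf = 1/(1 + c_inh/Ksurf) are the
    equilibrium fractions of inhibitor-free fibril ends and surface
    sites.  The reported (observable) mass is additionally scaled by the
    empirical plateau factor 1/(1 + c_inh/K_plat), describing the
    dose-dependent drop of the final ThT plateau.
    """

    m_tot: float = 5.0       # total monomer, µM
    kn: float = 8e-6         # primary nucleation, µM^(1-nc) h^-1
    nc: int = 2              # primary nucleus size
    kplus: float = 25.0      # elongation, µM^-1 h^-1
    k2: float = 1.2e-3       # secondary nucleation, µM^(-n2) h^-1
    n2: int = 2              # secondary nucleus size
    P0: float = 0.0          # initial fibril number, µM
    M0: float = 0.0          # initial fibril mass, µM
    Kend: float = 0.12       # inhibitor/fibril-end K_D, µM
    Ksurf: float = 0.06      # inhibitor/fibril-surface K_D, µM
    K_plat: float = 0.8      # plateau-attenuation scale, µM
    c_inh: float = 0.0       # inhibitor concentration, µM

    def __post_init__(self) -> None:
        for name in ("m_tot", "kn", "kplus", "k2", "P0", "M0", "c_inh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nc < 1 or self.n2 < 1:
            raise ValueError("nucleus sizes nc, n2 must be >= 1")
        if self.M0 > self.m_tot:
            raise ValueError("seed mass M0 cannot exceed total monomer")
        if self.Kend <= 0 or self.Ksurf <= 0 or self.K_plat <= 0:
            raise ValueError("inhibitor dissociation constants must be positive")

    def theta_end(self) -> float:
        return 1.0 / (1.0 + self.c_inh / self.Kend)

    def theta_surf(self) -> float:
        return 1.0 / (1.0 + self.c_inh / self.Ksurf)

    def plateau_factor(self) -> float:
        return 1.0 / (1.0 + self.c_inh / self.K_plat)


def simulate_aggregation(
    model: AggregationModel,
    t_grid: Sequence[float],
    raw: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Fibril mass trajectory M(t) in µM on ``t_grid`` (hours).

    Integrates the moment equations with a stiff-capable adaptive solver
    (LSODA, rtol 1e-8 / atol 1e-10 µM so the plateau is flat to solver
    precision, not by accident).  The returned trajectory is scaled by
    the plateau factor unless ``raw``; the raw trajectory satisfies
    monomer conservation m(t) + M(t) = m_tot by construction and is
    clipped to [0, m_tot] only within integration tolerance.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    th_e = model.theta_end()
    th_s = model.theta_surf()

    def rhs(_t: float, state: np.ndarray) -> list[float]:
        P, M = state
        m = max(model.m_tot - M, 0.0)
        dP = model.kn * m ** model.nc + model.k2 * th_s * m ** model.n2 * M
        dM = 2.0 * model.kplus * th_e * m * P
        return [dP, dM]

    t0, t1 = float(t[0]), float(t[-1])
    sol = solve_ivp(
        rhs, (t0, t1), [model.P0, model.M0], t_eval=t,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"aggregation ODE failed for parameters {model!r}: {sol.message}"
        )
    M = sol.y[1]
    # within-tolerance clip only; a genuine overshoot is an integration bug
    if np.any(M > model.m_tot * (1 + 1e-6)) or np.any(M < -model.m_tot * 1e-6):
        raise IntegrationError(
            f"mass left [0, m_tot] beyond tolerance for {model!r}"
        )
    M = np.clip(M, 0.0, model.m_tot)
    if raw:
        return M
    return M * model.plateau_factor()


@dataclass(frozen=True)
class AssayDesign:
    """Layout and noise model of a ThT plate assay.

    Defaults mirror a standard dose design: ten non-zero inhibitor
    conditions logarithmically equidistant between molar ratios 1:5000
    and 1:1 plus an inhibitor-free control, in triplicate.  Seeded modes
    add preformed fibrils at 8–9% of total monomer: sonicated seeds are
    short (many ends, elongation assay), non-sonicated long (surface for
    secondary nucleation).
    """

    n_ratios: int = 10
    ratio_min: float = 1 / 5000
    ratio_max: float = 1.0
    include_control: bool = True
    n_replicates: int = 3
    seed_mode: str = "none"      # none | sonicated | non-sonicated
    seed_fraction: float = 0.085
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 72.0 + 1e-9, 0.1)
    )
    noise_sd: float = 2.0        # additive FI noise
    lag_jitter_sd: float = 0.3   # per-replicate time shift SD, h
    rng_seed: int = 0
    gain: float = 100.0          # FI per µM fibril mass
    baseline: float = 10.0       # FI offset

    def __post_init__(self) -> None:
        if not (0 < self.ratio_min < self.ratio_max <= 1):
            raise ValueError("need 0 < ratio_min < ratio_max <= 1")
        if not (0 <= self.seed_fraction <= 0.2):
            raise ValueError("seed_fraction must be in [0, 0.2]")
        if self.seed_mode not in ("none", "sonicated", "non-sonicated"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")
        t = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "t_grid", t)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")


# mean seed length in monomer units: sonication fragments fibrils,
# multiplying the number of growth-competent ends
_SEED_LENGTH = {"sonicated": 50.0, "non-sonicated": 500.0}


def generate_tht_assay(model: AggregationModel, design: AssayDesign) -> ThTReplicateSet:
    """Simulate a full plate: one noisy curve per (condition, replicate).

    Fluorescence is gain·M(t) + baseline + Gaussian noise; each replicate
    carries an independent Gaussian lag jitter applied as a time shift
    with linear re-interpolation.  Independent RNG substreams per well
    are derived from ``design.rng_seed``, so output is bit-reproducible.
    """
    if len(design.t_grid) < 60:
        raise ValueError(
            "t_grid must have at least 60 points: the downstream 11/20/50-"
            "point analysis windows would be degenerate"
        )
    ratios = build_dose_series(
        design.ratio_min, design.ratio_max, design.n_ratios,
        include_control=design.include_control,
    )
    if design.seed_mode != "none":
        M0 = design.seed_fraction * model.m_tot
        P0 = M0 / _SEED_LENGTH[design.seed_mode]
        model = replace(model, M0=M0, P0=P0)

    ss = np.random.SeedSequence(design.rng_seed)
    children = ss.spawn(len(ratios) * design.n_replicates)
    curves = []
    for i, ratio in enumerate(ratios):
        cond_model = replace(model, c_inh=ratio * model.m_tot)
        M = simulate_aggregation(cond_model, design.t_grid)
        y_clean = design.gain * M + design.baseline
        for rep in range(design.n_replicates):
            rng = np.random.default_rng(children[i * design.n_replicates + rep])
            shift = rng.normal(0.0, design.lag_jitter_sd) if design.lag_jitter_sd > 0 else 0.0
            y = np.interp(design.t_grid - shift, design.t_grid, y_clean)
            if design.noise_sd > 0:
                y = y + rng.normal(0.0, design.noise_sd, size=len(y))
            curves.append(
                ThTCurve(
                    t=design.t_grid.copy(), y=y,
                    condition=f"ratio_{ratio:.6g}", ratio=float(ratio),
                    replicate=rep, seed_mode=design.seed_mode,
                )
            )
    return ThTReplicateSet(curves)


@dataclass(frozen=True)
class ExchangeModel:
    """Two-state fast-exchange binding ground truth for an NMR titration.

    ``delta_free``/``delta_bound`` map residue id to (¹H ppm, ¹⁵N ppm)
    site shifts.  Transverse rates interpolate linearly with the bound
    fraction, so peak intensities drop as binding to the large chaperone
    slows peptide tumbling.
    """

    KD: float = 61.0                 # µM
    koff: float = 6000.0             # s^-1
    P0: float = 0.0                  # chaperone, µM (set per titration point)
    L0: float = 50.0                 # peptide, µM
    delta_free: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    delta_bound: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    R2_free: float = 8.0             # s^-1
    R2_bound: float = 220.0          # s^-1
    spectrometer_freq: float = 600.0  # MHz

    def __post_init__(self) -> None:
        if self.KD <= 0 or self.koff <= 0:
            raise ValueError("KD and koff must be positive")
        if self.L0 <= 0 or self.P0 < 0:
            raise ValueError("concentrations must be positive")
        if set(self.delta_free) != set(self.delta_bound):
            raise ValueError("delta_free and delta_bound must cover the same residues")


@dataclass(frozen=True)
class TitrationPoint:
    ratio: float
    P_total: float
    L_total: float
    p_bound: float
    peaks: tuple[Peak, ...]


@dataclass(frozen=True)
class TitrationSeries:
    points: tuple[TitrationPoint, ...]

    def ratios(self) -> list[float]:
        return [pt.ratio for pt in self.points]


def simulate_titration(
    model: ExchangeModel,
    ratios: Sequence[float],
    shift_noise_H: float = 0.0,
    shift_noise_X: float = 0.0,
    rng_seed: int = 0,
) -> TitrationSeries:
    """Fast-exchange peak lists across chaperone:peptide molar ratios.

    At each ratio the chaperone concentration is ratio·L0; the bound
    fraction follows the exact 1:1 quadratic isotherm and every observed
    shift is the population-weighted average of the free and bound site
    shifts.  Intensities scale as R2_free/R2_obs.  Optional Gaussian
    peak-position noise (ppm) emulates peak-picking uncertainty.
    """
    rng = np.random.default_rng(rng_seed)
    pts = []
    for ratio in ratios:
        if ratio < 0:
            raise ValueError("molar ratios must be non-negative")
        P0 = ratio * model.L0
        p_b = float(bound_fraction(model.KD, P0, model.L0)) if P0 > 0 else 0.0
        R2_obs = model.R2_free + p_b * (model.R2_bound - model.R2_free)
        peaks = []
        for res in sorted(model.delta_free):
            hf, xf = model.delta_free[res]
            hb, xb = model.delta_bound[res]
            eH = rng.normal(0.0, shift_noise_H) if shift_noise_H > 0 else 0.0
            eX = rng.normal(0.0, shift_noise_X) if shift_noise_X > 0 else 0.0
            peaks.append(
                Peak(
                    residue_id=res,
                    shift_H=hf + p_b * (hb - hf) + eH,
                    shift_X=xf + p_b * (xb - xf) + eX,
                    intensity=model.R2_free / R2_obs,
                    linewidth=R2_obs / math.pi,
                )
            )
        pts.append(
            TitrationPoint(
                ratio=float(ratio), P_total=P0, L_total=model.L0,
                p_bound=p_b, peaks=tuple(peaks),
            )
        )
    return TitrationSeries(tuple(pts))


def titration_csp_table(series: TitrationSeries) -> pd.DataFrame:
    """CSP matrix (residues × non-zero titration points) vs the apo point.

    The first point of the series must be the apo (ratio 0) reference.
    """
    if not series.points or series.points[0].ratio != 0:
        raise ValueError("series must start with the apo (ratio 0) point")
    apo = list(series.points[0].peaks)
    cols = {}
    for pt in series.points[1:]:
        profiles = compute_csp(apo, list(pt.peaks))
        cols[pt.ratio] = {p.residue_id: p.csp for p in profiles}
    return pd.DataFrame(cols).sort_index()


def default_exchange_model(
    KD: float = 61.0, koff: float = 6000.0, L0: float = 50.0
) -> ExchangeModel:
    """IAPP-like 37-residue titration ground truth.

    Residues in :data:`IAPP_CSP_SEGMENTS` (two binding segments) receive
    large bound-state shift changes; all others small ones, so the
    above-average CSP rule recovers exactly the segment set at any
    saturation level.  Site shifts are drawn once from a fixed-seed RNG,
    making the model a pure constant.
    """
    rng = np.random.default_rng(20220325)
    delta_free: dict[int, tuple[float, float]] = {}
    delta_bound: dict[int, tuple[float, float]] = {}
    for res in range(1, 38):
        hf = 8.1 + 0.35 * math.sin(0.9 * res) + rng.normal(0, 0.05)
        xf = 115.0 + 6.0 * math.sin(0.5 * res + 1.0) + rng.normal(0, 0.5)
        if res in IAPP_CSP_SEGMENTS:
            dh = rng.uniform(0.10, 0.16) * rng.choice([-1, 1])
            dx = rng.uniform(0.35, 0.60) * rng.choice([-1, 1])
        else:
            dh = rng.uniform(0.004, 0.012) * rng.choice([-1, 1])
            dx = rng.uniform(0.01, 0.04) * rng.choice([-1, 1])
        delta_free[res] = (hf, xf)
        delta_bound[res] = (hf + dh, xf + dx)
    return ExchangeModel(
        KD=KD, koff=koff, L0=L0,
        delta_free=delta_free, delta_bound=delta_bound,
    )


@dataclass(frozen=True)
class PREGroundTruth:
    """Ground truth for a paramagnetic broadening experiment.

    ``active_residues`` maps chain label (e.g. alpha/beta/beta') to the
    residues within PRE reach of the paramagnetic tag; active sites lose
    ``loss_active`` of their intensity, the rest ``loss_inactive``, so the
    more-than-50%-loss classification is exactly recoverable before noise.
    """

    active_residues: Mapping[str, frozenset[int]]
    loss_active: float = 0.8
    loss_inactive: float = 0.1
    noise_sd: float = 0.0   # multiplicative noise on intensities

    def __post_init__(self) -> None:
        if not (self.loss_active > 0.5 >= self.loss_inactive >= 0):
            raise ValueError(
                "need loss_active > 0.5 >= loss_inactive >= 0 so the 50% "
                "rule can recover the ground truth"
            )


def simulate_pre_profile(
    truth: PREGroundTruth,
    residues: Mapping[str, Sequence[int]],
    rng_seed: int = 0,
) -> dict[str, tuple[list[Peak], list[Peak]]]:
    """Paired (diamagnetic, paramagnetic) peak lists per chain.

    Diamagnetic intensities are unity; paramagnetic intensities are
    1 − loss for the residue's class, with optional multiplicative
    Gaussian noise on both spectra.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[str, tuple[list[Peak], list[Peak]]] = {}
    for chain, res_ids in residues.items():
        if len(set(res_ids)) != len(res_ids):
            raise ValueError(f"duplicate residue ids on chain {chain!r}")
        active = truth.active_residues.get(chain, frozenset())
        dia, para = [], []
        for res in res_ids:
            loss = truth.loss_active if res in active else truth.loss_inactive
            i_dia, i_para = 1.0, 1.0 - loss
            if truth.noise_sd > 0:
                i_dia *= max(1.0 + rng.normal(0, truth.noise_sd), 1e-6)
                i_para *= max(1.0 + rng.normal(0, truth.noise_sd), 1e-6)
            dia.append(Peak(residue_id=res, chain=chain, shift_H=8.0,
                            shift_X=118.0, intensity=i_dia))
            para.append(Peak(residue_id=res, chain=chain, shift_H=8.0,
                             shift_X=118.0, intensity=i_para))
        out[chain] = (dia, para)
    return out


def default_pre_truth() -> PREGroundTruth:
    """Chaperone-like PRE ground truth: binding localized to the
    coiled-coil tentacles (alpha 8–31 and 118–135, beta/beta' 1–32),
    nothing on top of the barrel body."""
    return PREGroundTruth(
        active_residues={
            "alpha": frozenset(range(8, 32)) | frozenset(range(118, 136)),
            "beta": frozenset(range(1, 33)),
            "beta_prime": frozenset(range(1, 33)),
        }
    )


def default_aggregation_model() -> AggregationModel:
    """De novo IAPP-like aggregation at 5 µM monomer: a few-hour lag,
    a steep growth phase and a stable plateau within 48 h."""
    return AggregationModel()


def simulate_bli(
    KD: float,
    Rmax: float,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Steady-state BLI table: R_eq = [A]·Rmax/([A]+K_D) plus noise."""
    c = np.asarray(concs, dtype=float)
    if np.any(c <= 0):
        raise ValueError("analyte concentrations must be positive")
    r = c * Rmax / (c + KD)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        r = r + rng.normal(0.0, noise_sd, size=len(r))
    return pd.DataFrame({"conc_uM": c, "response": r})
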