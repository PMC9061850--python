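"""NMR and BLI analysis of monomeric-peptide/chaperone binding.

Covers the observables by which a weak, fast-exchanging interaction between
an intrinsically disordered peptide and a large chaperone is quantified:

* chemical shift perturbations (CSP), combined across ¹H and ¹⁵N/¹³C as
  Δδ = sqrt(alpha·ΔX² + ΔH²) with the conventional nitrogen weight 0.14;
* peak broadening ratios I/I0 from complex vs free-peptide spectra;
* paramagnetic relaxation enhancement (PRE) intensity losses from paired
  paramagnetic/diamagnetic spectra, classified at the 50%-loss rule;
* a global 1:1 fast-exchange K_D fit of CSPs against the quadratic binding
  isotherm, with residue-resampling bootstrap errors;
* a reduced one-dimensional two-site exchange lineshape (Bloch–McConnell
  2×2 propagator) and a joint k_off fit across residues;
* Langmuir steady-state fitting of biolayer interferometry responses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "ResidueProfile",
    "BindingFit",
    "bound_fraction",
    "compute_csp",
    "broadening_ratios",
    "classify_pre",
    "fit_kd_titration",
    "select_responsive_residues",
    "lineshape_two_site",
    "fit_koff_lineshape",
    "fit_bli_steady_state",
    "langmuir",
]

CSP_ALPHA = 0.14            # nitrogen weight in the combined shift
BROADENING_THRESHOLD = 0.26  # I/I0 at or below which a residue is broadened
PRE_LOSS_THRESHOLD = 0.5     # fractional intensity loss above which PRE-active


@dataclass(frozen=True)
class Peak:
    """One assigned 2D correlation peak."""

    residue_id: int
    shift_H: float            # ppm
    shift_X: float            # ppm, 15N or 13C
    intensity: float = 1.0
    chain: str = "A"
    linewidth: float | None = None  # Hz

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class ResidueProfile:
    """Per-residue binding observables and threshold flags."""

    residue_id: int
    chain: str = "A"
    csp: float = math.nan             # ppm
    intensity_ratio: float = math.nan  # I/I0
    pre_ratio: float = math.nan        # I_para/I_dia
    csp_above_avg: bool = False
    broadened: bool = False
    pre_active: bool = False


@dataclass
class BindingFit:
    """Result of an affinity fit."""

    KD: float                 # µM
    KD_err: float = math.nan  # bootstrap SD, µM
    koff: float | None = None  # s^-1
    Rmax: float | None = None  # BLI response units
    Rmax_err: float | None = None
    residuals: np.ndarray | None = None
    n_boot: int = 0
    rng_seed: int | None = None
    warnings_: list[str] = field(default_factory=list)


def _match_peaks(
    a: Sequence[Peak], b: Sequence[Peak]
) -> tuple[dict[tuple[str, int], Peak], dict[tuple[str, int], Peak], list[tuple[str, int]]]:
    """Index two peak lists by (chain, residue) and report unmatched ids."""
    out = []
    for peaks in (a, b):
        idx: dict[tuple[str, int], Peak] = {}
        for p in peaks:
            key = (p.chain, p.residue_id)
            if key in idx:
                raise ValueError(f"duplicate residue id {key} in peak list")
            idx[key] = p
        out.append(idx)
    ia, ib = out
    unmatched = sorted(set(ia) ^ set(ib))
    return ia, ib, unmatched


def compute_csp(
    apo: Sequence[Peak],
    holo: Sequence[Peak],
    alpha: float = CSP_ALPHA,
    avg_threshold: float | None = None,
) -> list[ResidueProfile]:
    """Chemical shift perturbations Δδ = sqrt(alpha·ΔX² + ΔH²) per residue.

    The ``csp_above_avg`` flag compares each residue against the mean CSP
    over all residues measurable in both lists (or against
    ``avg_threshold`` when given explicitly).  Residues present in only
    one list are reported as unmatched via a warning, never dropped
    silently.
    """
    ia, ib, unmatched = _match_peaks(apo, holo)
    if unmatched:
        warnings.warn(f"residues without a partner peak: {unmatched}", stacklevel=2)
    profiles = []
    for key in sorted(set(ia) & set(ib)):
        pa, pb = ia[key], ib[key]
        dH = pb.shift_H - pa.shift_H
        dX = pb.shift_X - pa.shift_X
        csp = math.sqrt(alpha * dX * dX + dH * dH)
        profiles.append(ResidueProfile(residue_id=key[1], chain=key[0], csp=csp))
    if profiles:
        cut = avg_threshold if avg_threshold is not None else float(
            np.mean([p.csp for p in profiles])
        )
        for p in profiles:
            p.csp_above_avg = p.csp >= cut
    return profiles


def broadening_ratios(
    apo: Sequence[Peak],
    holo: Sequence[Peak],
    threshold: float = BROADENING_THRESHOLD,
) -> list[ResidueProfile]:
    """Intensity ratios I/I0 (complex over free) with the broadened flag
    set where I/I0 ≤ ``threshold``."""
    ia, ib, unmatched = _match_peaks(apo, holo)
    if unmatched:
        warnings.warn(f"residues without a partner peak: {unmatched}", stacklevel=2)
    profiles = []
    for key in sorted(set(ia) & set(ib)):
        i0, i1 = ia[key].intensity, ib[key].intensity
        p = ResidueProfile(residue_id=key[1], chain=key[0])
        if i0 <= 0:
            warnings.warn(f"reference intensity zero for residue {key}", stacklevel=2)
        else:
            p.intensity_ratio = i1 / i0
            p.broadened = p.intensity_ratio <= threshold
        profiles.append(p)
    return profiles


def classify_pre(
    dia: Sequence[Peak],
    para: Sequence[Peak],
    loss_threshold: float = PRE_LOSS_THRESHOLD,
) -> list[ResidueProfile]:
    """Classify residues by paramagnetic intensity loss.

    A residue is PRE-active when 1 − I_para/I_dia exceeds
    ``loss_threshold`` (default: more than 50% signal loss).  Residues
    lacking a diamagnetic partner are excluded with a warning.
    """
    ia, ib, unmatched = _match_peaks(dia, para)
    if unmatched:
        warnings.warn(f"residues excluded (missing partner): {unmatched}", stacklevel=2)
    profiles = []
    for key in sorted(set(ia) & set(ib)):
        i_dia, i_para = ia[key].intensity, ib[key].intensity
        if i_dia <= 0:
            warnings.warn(f"diamagnetic intensity zero for residue {key}", stacklevel=2)
            continue
        ratio = i_para / i_dia
        profiles.append(
            ResidueProfile(
                residue_id=key[1], chain=key[0], pre_ratio=ratio,
                pre_active=(1.0 - ratio) > loss_threshold,
            )
        )
    return profiles


def bound_fraction(KD: float, P0, L0):
    """Bound fraction of the ligand under the exact 1:1 quadratic isotherm.

    bound = ((P0+L0+KD) − sqrt((P0+L0+KD)² − 4·P0·L0)) / 2;  p_b = bound/L0.
    Vectorized over P0/L0.
    """
    P0 = np.asarray(P0, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if np.any(P0 < 0) or np.any(L0 <= 0):
        raise ValueError("concentrations must be non-negative (L0 positive)")
    s = P0 + L0 + KD
    bound = (s - np.sqrt(s * s - 4.0 * P0 * L0)) / 2.0
    return bound / L0


def select_responsive_residues(csp_table: pd.DataFrame) -> pd.DataFrame:
    """Keep residues whose mean CSP across the titration is above average.

    Affinity fits are performed on the well-responding residues only, the
    tabular analogue of fitting selected strongly-shifting, well-resolved
    peaks: residues with near-zero true CSP contribute only folded
    measurement noise (|Δδ| is non-negative), which masquerades as an
    instantly saturating component and biases K_D low.
    """
    mean_csp = csp_table.mean(axis=1)
    return csp_table.loc[mean_csp >= mean_csp.mean()]


def fit_kd_titration(
    csp_table: pd.DataFrame,
    P_total: Sequence[float],
    L_total: Sequence[float],
    n_boot: int = 1000,
    rng_seed: int | None = None,
) -> BindingFit:
    """Global 1:1 fast-exchange K_D fit to a CSP titration.

    ``csp_table`` has one row per residue and one column per titration
    point (CSP in ppm, relative to the apo spectrum); ``P_total`` and
    ``L_total`` give the chaperone and peptide concentrations (µM) of
    each column.  The model is csp(r, j) = Δδ_bound(r) · p_b(K_D; j) with
    the bound fraction from the quadratic isotherm.  For fixed K_D the
    per-residue amplitudes Δδ_bound are linear and profiled out, leaving
    a one-dimensional optimization in log K_D.  The error is the SD of
    K_D over ``n_boot`` residue-resampling bootstrap refits.
    """
    P0 = np.asarray(P_total, dtype=float)
    L0 = np.asarray(L_total, dtype=float)
    Y = csp_table.to_numpy(dtype=float)
    if Y.shape[1] != len(P0) or len(P0) != len(L0):
        raise ValueError("concentration arrays must match table columns")
    if Y.shape[1] < 4:
        raise ValueError("need at least 4 titration points")
    if not np.any(np.nanmax(Y, axis=1) > 0):
        raise ValueError("no residue shows a CSP above zero")

    def sse(log10_kd: float, rows: np.ndarray) -> float:
        pb = bound_fraction(10.0 ** log10_kd, P0, L0)
        denom = float(pb @ pb)
        if denom <= 0:
            return float(np.sum(rows * rows))
        amps = rows @ pb / denom
        resid = rows - np.outer(amps, pb)
        return float(np.sum(resid * resid))

    def solve(rows: np.ndarray) -> float:
        res = minimize_scalar(
            sse, bounds=(-3.0, 5.0), args=(rows,), method="bounded",
            options={"xatol": 1e-8},
        )
        return float(10.0 ** res.x)

    kd = solve(Y)
    pb_hat = bound_fraction(kd, P0, L0)
    amps = Y @ pb_hat / float(pb_hat @ pb_hat)
    residuals = Y - np.outer(amps, pb_hat)

    fit = BindingFit(KD=kd, residuals=residuals, n_boot=n_boot, rng_seed=rng_seed)
    if float(np.max(pb_hat)) < 0.2:
        fit.warnings_.append(
            "saturation never exceeds 20%: K_D weakly identified"
        )
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        n_res = Y.shape[0]
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n_res, size=n_res)
            draws.append(solve(Y[idx]))
        fit.KD_err = float(np.std(draws, ddof=1))
    return fit


def lineshape_two_site(
    p_b: float,
    nu_free: float,
    nu_bound: float,
    R2_free: float,
    R2_bound: float,
    koff: float,
    freq_grid: np.ndarray,
) -> np.ndarray:
    """Absorptive 1D spectrum of a two-site exchanging spin.

    Frequencies in Hz (site positions ``nu_free``/``nu_bound`` and the
    evaluation grid), transverse rates R2 in s⁻¹, ``koff`` the
    bound→free rate in s⁻¹; the free→bound pseudo-first-order rate
    follows from detailed balance at the bound population ``p_b``.  The
    spectrum is −Re[𝟙ᵀ L(ω)⁻¹ p] with L the 2×2 Bloch–McConnell matrix;
    its integral over frequency is independent of ``koff``.
    """
    if not (0.0 <= p_b <= 1.0):
        raise ValueError("p_b must be in [0, 1]")
    if R2_free <= 0 or R2_bound <= 0:
        raise ValueError("linewidths (R2) must be positive")
    if koff <= 0:
        raise ValueError("koff must be positive")
    p_f = 1.0 - p_b
    k_bf = koff
    # detailed balance: p_f * k_fb = p_b * k_bf
    k_fb = koff * p_b / p_f if p_f > 0 else 0.0
    w_f = 2.0 * math.pi * nu_free
    w_b = 2.0 * math.pi * nu_bound
    w = 2.0 * math.pi * np.asarray(freq_grid, dtype=float)
    # closed-form inverse of the 2x2 matrix L = [[a, k_bf], [k_fb, b]]
    a = -R2_free - k_fb + 1j * (w_f - w)
    b = -R2_bound - k_bf + 1j * (w_b - w)
    det = a * b - k_bf * k_fb
    num = b * p_f - k_bf * p_b - k_fb * p_f + a * p_b
    return -np.real(num / det)


def fit_koff_lineshape(
    spectra: Mapping[int, Mapping[int, np.ndarray]],
    populations: Mapping[int, float],
    site_freqs: Mapping[int, tuple[float, float]],
    R2_free: float,
    R2_bound: float,
    freq_grid: np.ndarray,
) -> BindingFit:
    """Joint k_off fit of two-site lineshapes across residues and points.

    ``spectra[residue][point]`` are measured 1D absorptive lineshapes,
    ``populations[point]`` the bound fraction at each titration point
    (from the isotherm), ``site_freqs[residue]`` the free/bound site
    frequencies in Hz.  k_off is shared across all residues and points
    and found by least squares in log k_off; per-spectrum scale factors
    are profiled out so intensity calibration does not bias the rate.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)

    def sse(log10_koff: float) -> float:
        koff = 10.0 ** log10_koff
        total = 0.0
        for res, by_point in spectra.items():
            nu_f, nu_b = site_freqs[res]
            for point, y in by_point.items():
                model = lineshape_two_site(
                    populations[point], nu_f, nu_b, R2_free, R2_bound,
                    koff, freq_grid,
                )
                denom = float(model @ model)
                scale = float(np.dot(y, model)) / denom if denom > 0 else 0.0
                r = y - scale * model
                total += float(r @ r)
        return total

    res = minimize_scalar(
        sse, bounds=(1.0, 6.0), method="bounded", options={"xatol": 1e-6}
    )
    koff = float(10.0 ** res.x)
    return BindingFit(KD=math.nan, koff=koff)


def langmuir(conc, Rmax: float, KD: float):
    """Steady-state one-site Langmuir response R_eq = [A]·Rmax/([A]+K_D)."""
    conc = np.asarray(conc, dtype=float)
    return conc * Rmax / (conc + KD)


def fit_bli_steady_state(
    concs: Sequence[float],
    responses: Sequence[float],
    n_boot: int = 1000,
    rng_seed: int | None = None,
) -> BindingFit:
    """Fit K_D and R_max to steady-state BLI responses.

    Nonlinear least squares on the Langmuir isotherm; errors from a
    concentration-point bootstrap.  At least three distinct analyte
    concentrations spanning a 10-fold range are required and the
    responses must not be flat.
    """
    c = np.asarray(concs, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) != len(r):
        raise ValueError("concs and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("analyte concentrations must be positive")
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.max(c) / np.min(c) < 10:
        raise ValueError("concentrations must span at least a 10-fold range")
    if np.std(r) == 0:
        raise ValueError("responses have zero variance: K_D unidentifiable")

    def solve(cc: np.ndarray, rr: np.ndarray) -> tuple[float, float]:
        p0 = (float(np.max(rr)) * 1.2 + 1e-12, float(np.median(cc)))
        popt, _ = curve_fit(
            langmuir, cc, rr, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
        return float(popt[0]), float(popt[1])

    rmax, kd = solve(c, r)
    fit = BindingFit(
        KD=kd, Rmax=rmax, residuals=r - langmuir(c, rmax, kd),
        n_boot=n_boot, rng_seed=rng_seed,
    )
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        kds, rmaxs = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, len(c), size=len(c))
            cc, rr = c[idx], r[idx]
            if len(np.unique(cc)) < 3 or np.std(rr) == 0:
                continue
            try:
                rm, k = solve(cc, rr)
            except RuntimeError:
                continue
            kds.append(k)
            rmaxs.append(rm)
        if len(kds) >= 2:
            fit.KD_err = float(np.std(kds, ddof=1))
            fit.Rmax_err = float(np.std(rmaxs, ddof=1))
        else:
            fit.warnings_.append("bootstrap produced too few successful refits")
    return fit
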