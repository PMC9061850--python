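"""Kinetic-parameter extraction from ThT fluorescence aggregation curves.

A sigmoidal ThT time course is segmented into lag, growth and plateau
phases from its numerical first derivative: growth starts where the first
derivative first reaches 5% of its maximum and ends at the first
sub-threshold crossing after the derivative maximum.  From the segmented,
smoothed curve six parameters are extracted per replicate:

* lag time — time before the first derivative reaches 5% of its maximum;
* growth phase duration — time between growth start and end;
* maximal growth rate — maximum of the first derivative;
* average growth rate — fluorescence gain over the growth phase divided
  by its duration;
* initial growth rate — mean of the first 20 first-derivative values
  (meaningful for seeded elongation assays whose linear phase starts at
  t = 0);
* final plateau height — mean of the 50 points following growth end;
* acceleration maximum — maximum of the second time derivative.

Smoothing is an 11-point centered moving average; derivatives are
symmetric difference quotients with a configurable depth window.
Replicates of one condition can be aligned to their mean lag time by
shifting unmodified curves along the time axis before averaging.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "ThTCurve",
    "ThTReplicateSet",
    "KineticParameters",
    "KineticsConfig",
    "NoGrowthError",
    "smooth",
    "derivative",
    "segment_growth",
    "align_replicates",
    "extract_parameters",
    "build_dose_series",
    "compare_normalization",
    "parameter_table",
]

MIN_CURVE_POINTS = 60  # smoothing/derivative/plateau windows need headroom

PARAMETER_NAMES = (
    "lag_time",
    "growth_start",
    "growth_end",
    "growth_duration",
    "max_growth_rate",
    "average_growth_rate",
    "initial_growth_rate",
    "plateau_height",
    "acceleration_max",
)


class NoGrowthError(ValueError):
    """Raised when a curve has no detectable growth phase."""


@dataclass(frozen=True)
class ThTCurve:
    """One well's fluorescence time course.

    ``t`` in hours, strictly increasing and near-uniform; ``y`` in
    arbitrary fluorescence units.  ``ratio`` is the inhibitor:monomer
    molar ratio of the condition (0 for the control), ``replicate`` the
    replicate index within the condition.
    """

    t: np.ndarray
    y: np.ndarray
    condition: str = ""
    ratio: float = 0.0
    replicate: int = 0
    seed_mode: str = "none"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(t) < MIN_CURVE_POINTS:
            raise ValueError(
                f"curve has {len(t)} points; at least {MIN_CURVE_POINTS} "
                "are required for the smoothing/derivative/plateau windows"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class ThTReplicateSet:
    """A plate's worth of curves with condition metadata."""

    curves: list[ThTCurve] = field(default_factory=list)

    def ratios(self) -> list[float]:
        return sorted({c.ratio for c in self.curves})

    def by_ratio(self, ratio: float) -> list[ThTCurve]:
        return [c for c in self.curves if math.isclose(c.ratio, ratio, rel_tol=1e-12, abs_tol=1e-15)]

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)


@dataclass
class KineticParameters:
    """The extracted per-curve kinetic parameters (NaN when undefined)."""

    lag_time: float = math.nan          # h
    growth_start: float = math.nan      # h
    growth_end: float = math.nan        # h
    growth_duration: float = math.nan   # h
    max_growth_rate: float = math.nan   # FI/h
    average_growth_rate: float = math.nan  # FI/h
    initial_growth_rate: float = math.nan  # FI/h
    plateau_height: float = math.nan    # FI
    acceleration_max: float = math.nan  # FI/h^2
    defined: bool = True
    undefined_reason: str = ""
    provenance: dict = field(default_factory=dict)  # 0-based indices used
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass(frozen=True)
class KineticsConfig:
    """Extraction settings; defaults follow the analysis-script conventions."""

    window: int = 11            # moving-average width, odd
    deriv_depth: int = 4        # symmetric-quotient span in index steps
    threshold_frac: float = 0.05
    n_initial: int = 20         # first-derivative points for initial rate
    n_plateau: int = 50         # points after growth end for plateau


def smooth(curve: ThTCurve, window: int = 11) -> ThTCurve:
    """Centered unweighted moving average over ``window`` points.

    Output length equals input length; near the boundaries the window
    shrinks symmetrically so edge values average fewer points but stay
    centered.
    """
    y = _moving_average(curve.y, window)
    return replace(curve, y=y)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = len(y)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window >= n:
        raise ValueError(f"window {window} must be shorter than the series ({n})")
    half = window // 2
    # cumulative-sum windowed mean for the interior, shrunk windows at edges
    out = np.empty(n)
    cs = np.concatenate(([0.0], np.cumsum(y)))
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (cs[i + h + 1] - cs[i - h]) / (2 * h + 1)
    return out


def derivative(t: np.ndarray, y: np.ndarray, depth: int = 4) -> np.ndarray:
    """Symmetric difference quotient d(i) = (y[i+h] − y[i−h]) / (t[i+h] − t[i−h]).

    ``depth`` is the full index span of the stencil; the half-width is
    ``depth // 2``.  Points closer to a boundary use the largest symmetric
    half-width still available; the two endpoints fall back to one-sided
    quotients.  Exact for polynomials up to degree 2 on uniform grids.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    if n != len(y):
        raise ValueError("t and y must have equal length")
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if n < depth + 1:
        raise ValueError(f"need at least depth+1={depth + 1} points, got {n}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    h = depth // 2
    d = np.empty(n)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        if hi == 0:  # endpoint: one-sided
            j = 1 if i == 0 else n - 2
            d[i] = (y[i] - y[j]) / (t[i] - t[j])
        else:
            d[i] = (y[i + hi] - y[i - hi]) / (t[i + hi] - t[i - hi])
    return d


@dataclass(frozen=True)
class GrowthSegmentation:
    start_index: int
    end_index: int
    lag_time: float
    threshold: float
    argmax_index: int


def segment_growth(
    t: np.ndarray, d1: np.ndarray, threshold_frac: float = 0.05
) -> GrowthSegmentation:
    """Locate growth start/end from the first derivative.

    Start is the first index at which ``d1`` reaches ``threshold_frac``
    of its maximum (the first crossing, even if noise produces several);
    end is the first index after the derivative maximum at which ``d1``
    drops back to or below the threshold, falling back to the last index
    when the curve never leaves the growth phase.  Lag time is the time
    at the start index.
    """
    t = np.asarray(t, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    dmax = float(np.max(d1))
    if dmax <= 0:
        raise NoGrowthError("first derivative never positive: no growth phase")
    thr = threshold_frac * dmax
    above = np.nonzero(d1 >= thr)[0]
    start = int(above[0])
    imax = int(np.argmax(d1))
    after = np.nonzero(d1[imax + 1:] <= thr)[0]
    end = int(imax + 1 + after[0]) if len(after) else len(d1) - 1
    return GrowthSegmentation(start, end, float(t[start]), thr, imax)


def _shift_curve(curve: ThTCurve, shift: float) -> ThTCurve:
    """Shift a curve along time by ``shift`` hours, re-interpolating onto
    the original grid; values shifted past an edge hold the boundary value."""
    y_new = np.interp(curve.t - shift, curve.t, curve.y)
    return replace(curve, y=y_new)


def align_replicates(
    curves: Sequence[ThTCurve], config: KineticsConfig | None = None
) -> tuple[list[ThTCurve], list[float]]:
    """Set each replicate's lag time to the replicate-set mean lag.

    Curves are shifted (unmodified, i.e. un-smoothed data) along the time
    axis by (mean lag − own lag) with linear re-interpolation.  Returns the
    shifted curves and the applied shifts, which sum to zero.  If any
    replicate has no detectable growth the set is returned unshifted with
    a warning.
    """
    config = config or KineticsConfig()
    if len(curves) < 2:
        raise ValueError("need at least two replicates to align")
    lags = []
    for c in curves:
        try:
            ys = _moving_average(c.y, config.window)
            d1 = derivative(c.t, ys, config.deriv_depth)
            seg = segment_growth(c.t, d1, config.threshold_frac)
        except NoGrowthError:
            warnings.warn(
                f"replicate {c.replicate} of condition {c.condition!r} has no "
                "growth phase; alignment skipped for the set",
                stacklevel=2,
            )
            return list(curves), [0.0] * len(curves)
        lags.append(seg.lag_time)
    mean_lag = float(np.mean(lags))
    shifts = [mean_lag - lag for lag in lags]
    aligned = [_shift_curve(c, s) for c, s in zip(curves, shifts)]
    return aligned, shifts


def extract_parameters(
    curve: ThTCurve, config: KineticsConfig | None = None
) -> KineticParameters:
    """Extract the six kinetic parameters from one curve.

    The curve is smoothed, first and second derivatives are taken (the
    second by differentiating the smoothed first derivative), and the
    growth phase is segmented at the 5%-of-maximum derivative threshold.
    Curves without a growth phase yield parameters flagged undefined
    rather than zeros.
    """
    config = config or KineticsConfig()
    ys = _moving_average(curve.y, config.window)
    d1 = derivative(curve.t, ys, config.deriv_depth)
    d2 = derivative(curve.t, d1, config.deriv_depth)
    try:
        seg = segment_growth(curve.t, d1, config.threshold_frac)
    except NoGrowthError as exc:
        return KineticParameters(defined=False, undefined_reason=str(exc))

    p = KineticParameters()
    p.lag_time = seg.lag_time
    p.growth_start = float(curve.t[seg.start_index])
    p.growth_end = float(curve.t[seg.end_index])
    p.growth_duration = p.growth_end - p.growth_start
    p.max_growth_rate = float(np.max(d1))
    if p.growth_duration > 0:
        p.average_growth_rate = float(
            (ys[seg.end_index] - ys[seg.start_index]) / p.growth_duration
        )
    else:
        p.average_growth_rate = math.nan
        p.warnings.append("zero-length growth phase; average rate undefined")
    n0 = min(config.n_initial, len(d1))
    p.initial_growth_rate = float(np.mean(d1[:n0]))
    plateau_slice = ys[seg.end_index + 1: seg.end_index + 1 + config.n_plateau]
    if len(plateau_slice) == 0:
        plateau_slice = ys[seg.end_index:]
        p.warnings.append("no points after growth end; plateau uses last value")
    elif len(plateau_slice) < config.n_plateau:
        p.warnings.append(
            f"only {len(plateau_slice)} points after growth end; plateau "
            f"averaged over available points instead of {config.n_plateau}"
        )
    p.plateau_height = float(np.mean(plateau_slice))
    p.acceleration_max = float(np.max(d2))
    p.provenance = {
        "start_index": seg.start_index,
        "end_index": seg.end_index,
        "argmax_d1_index": seg.argmax_index,
        "initial_rate_indices": [0, n0 - 1],
        "plateau_indices": [seg.end_index + 1,
                            seg.end_index + len(plateau_slice)],
    }
    return p


def build_dose_series(
    ratio_min: float = 1 / 5000,
    ratio_max: float = 1.0,
    n: int = 10,
    include_control: bool = False,
) -> np.ndarray:
    """Logarithmically equidistant inhibitor:monomer molar ratios.

    A geometric progression of ``n`` ratios with exact endpoints,
    optionally preceded by the ratio-0 control.  The default ten-point
    series spans 1:5000 to 1:1.
    """
    if not (0 < ratio_min < ratio_max):
        raise ValueError("need 0 < ratio_min < ratio_max")
    if n < 2:
        raise ValueError("need at least 2 ratios")
    ratios = np.geomspace(ratio_min, ratio_max, n)
    ratios[0], ratios[-1] = ratio_min, ratio_max  # endpoints exact
    if include_control:
        ratios = np.concatenate(([0.0], ratios))
    return ratios


def parameter_table(
    dataset: ThTReplicateSet,
    config: KineticsConfig | None = None,
    normalize: bool = False,
    align: bool = False,
) -> pd.DataFrame:
    """Per-curve parameter table, one row per (ratio, replicate).

    With ``normalize`` each curve is divided by its own maximum first;
    with ``align`` replicates of each condition are lag-aligned before
    extraction.
    """
    config = config or KineticsConfig()
    rows = []
    for ratio in dataset.ratios():
        group = dataset.by_ratio(ratio)
        if align and len(group) >= 2:
            group, _ = align_replicates(group, config)
        for c in group:
            if normalize:
                m = float(np.max(c.y))
                c = replace(c, y=c.y / m) if m > 0 else c
            p = extract_parameters(c, config)
            row = {"condition": c.condition, "ratio": c.ratio,
                   "replicate": c.replicate, "defined": p.defined}
            row.update(p.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NormalizationComparison:
    raw: pd.DataFrame
    normalized: pd.DataFrame
    rank_correlation: dict[str, float]


def compare_normalization(
    dataset: ThTReplicateSet, config: KineticsConfig | None = None
) -> NormalizationComparison:
    """Compare parameter trends from raw vs per-curve max-normalized data.

    For each parameter, condition means are computed across the dose
    series in both tables and their Spearman rank correlation is
    reported: scale-free parameters and monotone dose responses give
    correlation 1.
    """
    raw = parameter_table(dataset, config, normalize=False)
    norm = parameter_table(dataset, config, normalize=True)
    if raw["ratio"].nunique() < 2:
        raise ValueError("need at least two conditions to compare trends")
    corr: dict[str, float] = {}
    for name in PARAMETER_NAMES:
        a = raw.groupby("ratio")[name].mean()
        b = norm.groupby("ratio")[name].mean()
        both = pd.concat([a, b], axis=1, keys=["raw", "norm"]).dropna()
        if len(both) < 2 or both["raw"].nunique() < 2 or both["norm"].nunique() < 2:
            corr[name] = math.nan
        else:
            corr[name] = float(spearmanr(both["raw"], both["norm"]).statistic)
    return NormalizationComparison(raw, norm, corr)
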