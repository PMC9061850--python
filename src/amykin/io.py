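"""Plain-text readers and writers: plate tables, peak lists, run configs.

All tables are comma-separated UTF-8 with '.' decimal and LF endings;
times are hours, shifts ppm, concentrations µM.  Writers are
deterministic (stable column order, 6 significant digits) so repeated
runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import Peak
from .kinetics import ThTCurve, ThTReplicateSet

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_peak_list",
    "write_peak_list",
    "RunConfig",
]

FLOAT_FMT = "%.6g"


def write_plate_table(
    dataset: ThTReplicateSet, plate_path: str | Path, anno_path: str | Path
) -> None:
    """Write curves as a wide table (time + one column per well) plus a
    well-annotation table mapping well -> (ratio, replicate, seed_mode)."""
    curves = dataset.curves
    if not curves:
        raise ValueError("empty dataset")
    t = curves[0].t
    data = {"time_h": t}
    anno_rows = []
    for i, c in enumerate(curves):
        if len(c.t) != len(t) or not np.allclose(c.t, t):
            raise ValueError("all curves must share one time grid to share a plate")
        well = f"W{i + 1:03d}"
        data[well] = c.y
        anno_rows.append(
            {"well": well, "ratio": c.ratio, "replicate": c.replicate,
             "seed_mode": c.seed_mode, "condition": c.condition}
        )
    pd.DataFrame(data).to_csv(plate_path, index=False, float_format=FLOAT_FMT)
    pd.DataFrame(anno_rows).to_csv(anno_path, index=False, float_format=FLOAT_FMT)


def read_plate_table(
    plate_path: str | Path, anno_path: str | Path
) -> ThTReplicateSet:
    """Read a plate table and its well annotation into a replicate set.

    Every well column must be annotated; non-numeric cells and
    non-monotone time axes are rejected with the offending location.
    """
    plate = pd.read_csv(plate_path)
    anno = pd.read_csv(anno_path)
    if plate.shape[1] < 2:
        raise ValueError("plate table needs a time column plus at least one well")
    time_col = plate.columns[0]
    for col in plate.columns:
        bad = pd.to_numeric(plate[col], errors="coerce").isna() & plate[col].notna()
        if bad.any():
            rows = [int(r) + 2 for r in plate.index[bad][:5]]  # 1-based + header
            raise ValueError(
                f"non-numeric cells in column {col!r} at file line(s) {rows}"
            )
        plate[col] = pd.to_numeric(plate[col])
    t = plate[time_col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"time column {time_col!r} is not strictly increasing")
    ann = anno.set_index("well")
    curves = []
    for well in plate.columns[1:]:
        if well not in ann.index:
            raise ValueError(f"well {well!r} missing from annotation table")
        meta = ann.loc[well]
        curves.append(
            ThTCurve(
                t=t.copy(), y=plate[well].to_numpy(dtype=float),
                condition=str(meta.get("condition", "")),
                ratio=float(meta["ratio"]), replicate=int(meta["replicate"]),
                seed_mode=str(meta.get("seed_mode", "none")),
            )
        )
    return ThTReplicateSet(curves)


def write_peak_list(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        {"residue": p.residue_id, "chain": p.chain, "shift_H_ppm": p.shift_H,
         "shift_X_ppm": p.shift_X, "intensity": p.intensity}
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_peak_list(path: str | Path) -> list[Peak]:
    """Read a tabular peak list (residue, chain, ¹H ppm, X ppm, intensity).

    Lines starting with '#' are comments; duplicate (chain, residue)
    pairs are an error.
    """
    df = pd.read_csv(path, comment="#")
    required = {"residue", "shift_H_ppm", "shift_X_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    peaks = []
    seen = set()
    for _, row in df.iterrows():
        key = (str(row.get("chain", "A")), int(row["residue"]))
        if key in seen:
            raise ValueError(f"duplicate residue id {key} in {path}")
        seen.add(key)
        peaks.append(
            Peak(
                residue_id=key[1], chain=key[0],
                shift_H=float(row["shift_H_ppm"]),
                shift_X=float(row["shift_X_ppm"]),
                intensity=float(row.get("intensity", 1.0)),
            )
        )
    return peaks


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults at the standard values.

    Serializes losslessly to and from YAML.
    """

    run_id: str = "demo"
    out_dir: str = "amykin_out"
    rng_seed: int = 0
    # ThT extraction
    window: int = 11
    deriv_depth: int = 4
    threshold_frac: float = 0.05
    align_replicates: bool = True
    normalize: str = "both"        # raw | max | both
    # dose design
    n_ratios: int = 10
    ratio_min: float = 1 / 5000
    ratio_max: float = 1.0
    n_replicates: int = 3
    noise_sd: float = 2.0
    lag_jitter_sd: float = 0.3
    t_max_h: float = 72.0
    t_step_h: float = 0.1
    # binding analysis thresholds
    csp_avg_threshold: float | None = None   # None -> data-driven mean
    broadening_threshold: float = 0.26
    pre_loss_threshold: float = 0.5
    majority_frac: float = 0.5
    # simulators
    KD_titration: float = 61.0
    koff: float = 6000.0
    L0: float = 50.0
    KD_bli: float = 11.0
    Rmax_bli: float = 1.0
    bli_noise_sd: float = 0.01
    titration_ratios: list[float] = field(
        default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0]
    )
    # bootstraps
    n_boot: int = 1000

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded), so
        identical analyses are recognizable across output directories."""
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        data.pop("run_id")
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
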