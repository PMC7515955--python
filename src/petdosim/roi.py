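"""Organ ROI quantification from labelled phantom frames.

Reproduces the manual ROI step of a whole-body dosimetry study: mean
activity concentration per organ per scan, and total activity plus volume
for the bladder (whose ROI grows as the bladder fills).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom


@dataclass(frozen=True)
class RoiSample:
    """Mean concentration over one organ ROI at one scan."""

    organ: str
    scan_index: int
    t_min: float
    mean_conc_kBq_per_ml: float
    roi_voxels: int

    def __post_init__(self) -> None:
        if self.roi_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")
        if self.mean_conc_kBq_per_ml < 0:
            raise ValueError("mean concentration must be non-negative")


@dataclass(frozen=True)
class BladderSample:
    """Total bladder activity and ROI volume at one scan."""

    scan_index: int
    t_min: float
    volume_ml: float
    total_MBq: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("bladder volume must be positive")
        if self.total_MBq < 0:
            raise ValueError("total activity must be non-negative")


def roi_mean_concentration(
    frame: np.ndarray,
    mask: np.ndarray,
    organ_label: int,
    organ: str = "",
    scan_index: int = 0,
    t_min: float = 0.0,
) -> RoiSample:
    """Arithmetic mean of frame voxels under ``organ_label``."""
    sel = mask == organ_label
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"label {organ_label} ({organ or 'unnamed'}) absent from mask")
    return RoiSample(
        organ=organ,
        scan_index=scan_index,
        t_min=t_min,
        mean_conc_kBq_per_ml=float(frame[sel].mean()),
        roi_voxels=n,
    )


def bladder_total_activity(
    frame: np.ndarray,
    mask: np.ndarray,
    voxel_volume_ml: float,
    bladder_label: int,
    scan_index: int = 0,
    t_min: float = 0.0,
) -> BladderSample:
    """Total activity (MBq) and volume (mL) of the outlined bladder ROI.

    Voxel values are kBq/mL, so total = Σ values · voxel volume / 1000.
    """
    sel = mask == bladder_label
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"bladder label {bladder_label} absent from mask")
    total_kBq = float(frame[sel].sum()) * voxel_volume_ml
    return BladderSample(
        scan_index=scan_index,
        t_min=t_min,
        volume_ml=n * voxel_volume_ml,
        total_MBq=total_kBq / 1000.0,
    )


@dataclass
class TimeActivityCurve:
    """Time-ordered concentration samples for one source region.

    ``missing_scans`` flags (organ, scan) pairs expected but not measured;
    gaps are reported, never silently dropped.
    """

    organ: str
    t_min: np.ndarray
    conc_kBq_per_ml: np.ndarray
    scan_index: np.ndarray
    missing_scans: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError(f"{self.organ}: times must be strictly increasing")


def assemble_tacs(samples: list[RoiSample]) -> dict[str, TimeActivityCurve]:
    """Group ROI samples into per-organ curves, ordered by time.

    Order-invariant; duplicate (organ, scan) pairs are an error; pairs
    missing relative to the full organ × scan grid are flagged on the curve.
    """
    if not samples:
        raise ValueError("no samples")
    seen: set[tuple[str, int]] = set()
    for s in samples:
        key = (s.organ, s.scan_index)
        if key in seen:
            raise ValueError(f"duplicate sample for {key}")
        seen.add(key)
    all_scans = sorted({s.scan_index for s in samples})
    curves: dict[str, TimeActivityCurve] = {}
    df = pd.DataFrame(
        {
            "organ": [s.organ for s in samples],
            "scan_index": [s.scan_index for s in samples],
            "t_min": [s.t_min for s in samples],
            "conc": [s.mean_conc_kBq_per_ml for s in samples],
        }
    )
    for organ, g in df.groupby("organ", sort=True):
        g = g.sort_values("t_min")
        missing = tuple(si for si in all_scans if si not in set(g["scan_index"]))
        curves[organ] = TimeActivityCurve(
            organ=organ,
            t_min=g["t_min"].to_numpy(float),
            conc_kBq_per_ml=g["conc"].to_numpy(float),
            scan_index=g["scan_index"].to_numpy(int),
            missing_scans=missing,
        )
    return curves


def quantify_phantom(phantom: VoxelPhantom) -> pd.DataFrame:
    """Run ROI quantification over every frame and organ of a phantom.

    Returns a table in the simulator's TAC dialect (organ, scan_index,
    t_min, conc_kBq_per_ml).
    """
    rows = []
    times = phantom.frame_times_min or tuple(
        float(i) for i in range(phantom.frames.shape[0])
    )
    for fi in range(phantom.frames.shape[0]):
        for organ, label in sorted(phantom.labels.items()):
            s = roi_mean_concentration(
                phantom.frames[fi],
                phantom.mask,
                label,
                organ=organ,
                scan_index=fi + 1,
                t_min=times[fi],
            )
            rows.append(
                {
                    "organ": s.organ,
                    "scan_index": s.scan_index,
                    "t_min": s.t_min,
                    "conc_kBq_per_ml": s.mean_conc_kBq_per_ml,
                }
            )
    return pd.DataFrame(rows)
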