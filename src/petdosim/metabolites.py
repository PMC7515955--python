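"""Plasma parent-fraction analysis from radio-HPLC chromatograms.

Peaks are quantified by trapezoidal integration over retention-time
windows; the parent fraction is the parent-peak share of the total peak
area. Peaks are labelled by retention window only — no chemical identity
is asserted for metabolite peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import DEFAULT_CHROMATOGRAPHY, ChromatographyConfig, SubjectDataset

__all__ = [
    "Chromatogram",
    "ParentFractionCurve",
    "integrate_peak",
    "parent_fraction",
    "group_parent_summary",
    "measure_parent_fractions",
]


@dataclass
class Chromatogram:
    """One radio-HPLC trace: retention time (min) vs. counts per minute."""

    time_min: np.ndarray
    cpm: np.ndarray
    sample_time_min: float = 0.0
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.cpm = np.asarray(self.cpm, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.cpm < 0):
            raise ValueError("counts must be non-negative")
        if self.matrix not in ("plasma", "urine"):
            raise ValueError("matrix must be 'plasma' or 'urine'")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_time_min: float = 0.0, matrix: str = "plasma"
    ) -> "Chromatogram":
        return cls(
            time_min=df["time_min"].to_numpy(float),
            cpm=df["cpm"].to_numpy(float),
            sample_time_min=sample_time_min,
            matrix=matrix,
        )


def integrate_peak(
    chrom: Chromatogram,
    window: tuple[float, float],
    baseline_policy: str = "flat_from_flanks",
    n_flank: int = 5,
) -> float:
    """Trapezoidal peak area (counts) above baseline within a window.

    ``flat_from_flanks`` estimates a flat baseline as the mean of the
    medians of up to ``n_flank`` samples just outside each window edge;
    ``zero`` integrates the raw trace.
    """
    t1, t2 = window
    if t2 <= t1:
        raise ValueError("empty integration window")
    if t1 < chrom.time_min[0] or t2 > chrom.time_min[-1]:
        raise ValueError("window outside the chromatogram span")
    if baseline_policy not in ("flat_from_flanks", "zero"):
        raise ValueError(f"unknown baseline_policy {baseline_policy!r}")
    sel = (chrom.time_min >= t1) & (chrom.time_min <= t2)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    t = chrom.time_min[sel]
    y = chrom.cpm[sel].copy()
    if baseline_policy == "flat_from_flanks":
        left = chrom.cpm[chrom.time_min < t1][-n_flank:]
        right = chrom.cpm[chrom.time_min > t2][:n_flank]
        flanks = [np.median(v) for v in (left, right) if len(v)]
        level = float(np.mean(flanks)) if flanks else 0.0
        y = y - level
    return float(np.trapezoid(y, t))


def parent_fraction(
    chrom: Chromatogram,
    parent_window: tuple[float, float],
    metabolite_windows: list[tuple[float, float]],
    baseline_policy: str = "flat_from_flanks",
) -> float:
    """Parent-peak share of total peak area; NaN (with warning) if no area.

    Windows must be pairwise disjoint. Invariant to uniform scaling of
    counts. Clamped to [0, 1] against baseline-subtraction jitter.
    """
    windows = [parent_window] + list(metabolite_windows)
    for i, (a1, a2) in enumerate(windows):
        for b1, b2 in windows[i + 1 :]:
            if max(a1, b1) < min(a2, b2):
                raise ValueError(f"overlapping windows {(a1, a2)} and {(b1, b2)}")
    parent = integrate_peak(chrom, parent_window, baseline_policy)
    metab = sum(integrate_peak(chrom, wdw, baseline_policy) for wdw in metabolite_windows)
    total = parent + metab
    if total <= 0:
        warnings.warn("total peak area is zero; parent fraction undefined")
        return float("nan")
    return float(np.clip(parent / total, 0.0, 1.0))


@dataclass
class ParentFractionCurve:
    """Per-subject parent fraction vs. plasma sampling time."""

    subject_id: str
    diet: str
    t_min: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        ok = ~np.isnan(self.fraction)
        if np.any((self.fraction[ok] < 0) | (self.fraction[ok] > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def measure_parent_fractions(
    ds: SubjectDataset,
    subject_id: str = "",
    config: ChromatographyConfig = DEFAULT_CHROMATOGRAPHY,
    baseline_policy: str = "flat_from_flanks",
) -> ParentFractionCurve:
    """Parent-fraction curve for one subject's chromatogram set."""
    times = sorted(ds.chromatograms)
    fracs = [
        parent_fraction(
            Chromatogram.from_frame(ds.chromatograms[t], sample_time_min=t),
            config.parent_window,
            config.metabolite_windows,
            baseline_policy,
        )
        for t in times
    ]
    return ParentFractionCurve(
        subject_id=subject_id or f"seed{ds.seed}",
        diet=ds.diet,
        t_min=np.array(times),
        fraction=np.array(fracs),
    )


def group_parent_summary(
    curves: list[ParentFractionCurve],
    grouping: str = "diet",
) -> pd.DataFrame:
    """Per-timepoint mean ± SD parent fraction, in percent.

    grouping 'diet' summarises fed and fasted separately; 'all' pools.
    """
    if not curves:
        raise ValueError("no curves")
    if grouping not in ("diet", "all"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for cv in curves:
        for t, f in zip(cv.t_min, cv.fraction):
            rows.append(
                {
                    "group": cv.diet if grouping == "diet" else "all",
                    "t_min": float(t),
                    "percent": 100.0 * f,
                }
            )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "t_min"])["percent"]
        .agg(mean_percent="mean", sd_percent=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out
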