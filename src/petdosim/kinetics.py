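"""From measured TACs to fractional-uptake curves and organ residence times.

The chain: each organ sample is decay-corrected to the midpoint of its
whole-body scan (within-scan correction only — curves remain
non-decay-corrected between scans, since the residence time integrates
physical disintegrations); concentration is converted to whole-organ
activity with reference-man volumes and normalised by the injected
activity; the resulting fractional-uptake curve is trapezoidally
integrated with a decay-only tail beyond the last scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import ADULT, SEX_SPECIFIC_ORGANS, ReferenceAnatomy
from .physics import F18, PhysicsConstants
from .roi import BladderSample, RoiSample

__all__ = [
    "FractionalUptakeCurve",
    "ResidenceTimeTable",
    "decay_correct_to_midpoint",
    "fractional_uptake",
    "bladder_fraction",
    "residence_time",
    "remainder_residence_time",
    "group_mean_taus",
    "subject_residence_times",
]


@dataclass
class FractionalUptakeCurve:
    """Non-decay-corrected fraction of injected activity vs. time."""

    organ: str
    t_min: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t_min.shape != self.F.shape:
            raise ValueError("t and F must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError(f"{self.organ}: times must be strictly increasing")
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ValueError(f"{self.organ}: F must lie in [0, 1]")


@dataclass
class ResidenceTimeTable:
    """Organ → residence time τ in MBq·h/MBq (equivalently hours).

    May describe one subject (sex/diet labels) or a group mean with SD.
    The total of all entries cannot exceed the ¹⁸F mean lifetime 1/λ
    (2.640 h): every disintegration happens somewhere.
    """

    taus: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    group: str = "all"
    sex: str | None = None
    diet: str | None = None
    n_subjects: int = 1

    def __post_init__(self) -> None:
        for organ, tau in self.taus.items():
            if tau < 0:
                raise ValueError(f"negative residence time for {organ}")
        total = sum(self.taus.values())
        limit = F18.mean_life_h + 1e-6
        if total > limit:
            raise ValueError(
                f"total residence time {total:.4f} h exceeds the physical "
                f"limit {limit:.4f} h"
            )

    @property
    def total_h(self) -> float:
        return sum(self.taus.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": list(self.taus),
                "tau_h": list(self.taus.values()),
                "sd_h": [self.sd.get(o, 0.0) for o in self.taus],
                "group": self.group,
            }
        )


def decay_correct_to_midpoint(
    sample: RoiSample,
    scan_window: tuple[float, float],
    c: PhysicsConstants = F18,
) -> RoiSample:
    """Rescale a sample to the midpoint of its whole-body scan.

    corrected = measured · e^(λ·(t_sample − midpoint)): a sample acquired
    after the midpoint is scaled up to undo the extra decay. Correction is
    within-scan only.
    """
    start, end = scan_window
    if not start <= sample.t_min <= end:
        raise ValueError(
            f"sample at t={sample.t_min} outside scan window [{start}, {end}]"
        )
    mid = 0.5 * (start + end)
    corrected = sample.mean_conc_kBq_per_ml * math.exp(
        c.lambda_per_min * (sample.t_min - mid)
    )
    return RoiSample(
        organ=sample.organ,
        scan_index=sample.scan_index,
        t_min=mid,
        mean_conc_kBq_per_ml=corrected,
        roi_voxels=sample.roi_voxels,
    )


def fractional_uptake(
    conc_kBq_per_ml: float,
    organ: str,
    anat: ReferenceAnatomy = ADULT,
    injected_MBq: float = 1.0,
) -> float:
    """Fraction of injected activity in an organ from its mean concentration.

    F = conc · reference volume / injected activity (kBq → MBq). Values
    above 1 are physically impossible for a measurement and are clipped
    with a warning rather than silently propagated.
    """
    if injected_MBq <= 0:
        raise ValueError("injected activity must be positive")
    f = conc_kBq_per_ml * anat.volume_ml(organ) / (injected_MBq * 1000.0)
    if f > 1.0:
        warnings.warn(
            f"{organ}: fractional uptake {f:.3f} > 1 clipped to 1", stacklevel=2
        )
        f = 1.0
    return f


def bladder_fraction(
    sample: BladderSample,
    anat: ReferenceAnatomy = ADULT,
    injected_MBq: float = 1.0,
) -> tuple[float, float]:
    """Bladder fractional uptake and nominal concentration.

    The bladder uses the measured TOTAL activity directly:
    F = total / injected. The nominal concentration (total divided by the
    reference bladder volume, kBq/mL) is the standard-sized-bladder value
    retained for reporting; changing the reference volume changes only it.
    """
    if injected_MBq <= 0:
        raise ValueError("injected activity must be positive")
    f = sample.total_MBq / injected_MBq
    nominal_kBq_per_ml = sample.total_MBq * 1000.0 / anat.reference_bladder_volume_ml
    return f, nominal_kBq_per_ml


def residence_time(
    curve: FractionalUptakeCurve,
    c: PhysicsConstants = F18,
    t0_policy: str = "zero_at_injection",
    tail: str = "decay",
) -> float:
    """Residence time τ (hours): trapezoid over samples plus extrapolations.

    Before the first scan, either a linear rise from (0, 0) at injection
    (default) or a flat back-extrapolation of the first sample. Beyond the
    last scan the only significant change is radioactive decay, so the
    tail integrates F_last·e^(−λ(t−t_last)) analytically to F_last/λ;
    ``tail='none'`` omits it (used for the bladder, whose late filling a
    decay-only tail would misrepresent).
    """
    if t0_policy not in ("zero_at_injection", "flat_back_extrapolation"):
        raise ValueError(f"unknown t0_policy {t0_policy!r}")
    if tail not in ("decay", "none"):
        raise ValueError(f"unknown tail {tail!r}")
    t = curve.t_min
    F = curve.F
    if t[0] > 0:
        f0 = 0.0 if t0_policy == "zero_at_injection" else F[0]
        t = np.concatenate([[0.0], t])
        F = np.concatenate([[f0], F])
    tau_min = float(np.trapezoid(F, t))
    if tail == "decay":
        tau_min += float(F[-1]) / c.lambda_per_min
    return tau_min / 60.0


def remainder_residence_time(
    organ_taus: dict[str, float],
    c: PhysicsConstants = F18,
    whole_body_curve: FractionalUptakeCurve | None = None,
    tau_excreted_h: float = 0.0,
    t0_policy: str = "zero_at_injection",
) -> float:
    """Residence time of the remainder (body minus delineated organs).

    With a whole-body curve: τ_rem = τ(whole body) − Σ organ τ. Without
    one, activity balance: every injected atom decays somewhere, so
    τ_rem = 1/λ − τ_excreted − Σ organ τ, with τ_excreted the
    disintegration equivalent of voided urine. Floored at zero (with a
    warning) — a negative remainder means organ τs are overestimated.
    """
    total_organs = sum(organ_taus.values())
    if whole_body_curve is not None:
        tau_wb = residence_time(whole_body_curve, c, t0_policy)
        rem = tau_wb - total_organs
    else:
        rem = c.mean_life_h - tau_excreted_h - total_organs
    if rem < 0:
        warnings.warn(
            f"remainder residence time {rem:.4f} h negative; floored at 0",
            stacklevel=2,
        )
        rem = 0.0
    return rem


def group_mean_taus(
    tables: list[ResidenceTimeTable],
    grouping: str = "all",
) -> dict[str, ResidenceTimeTable]:
    """Arithmetic mean and SD of per-subject residence times.

    grouping ∈ {'all', 'sex', 'diet'}. Sex-specific organs are averaged
    only over subjects of the relevant sex, so a male cohort never
    contributes zeros to the ovary mean.
    """
    if grouping not in ("all", "sex", "diet"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if not tables:
        raise ValueError("no subject tables")

    def key(tb: ResidenceTimeTable) -> str:
        if grouping == "all":
            return "all"
        v = tb.sex if grouping == "sex" else tb.diet
        if v is None:
            raise ValueError(f"subject table lacks a {grouping} label")
        return v

    groups: dict[str, list[ResidenceTimeTable]] = {}
    for tb in tables:
        groups.setdefault(key(tb), []).append(tb)

    out: dict[str, ResidenceTimeTable] = {}
    for gname, members in groups.items():
        organs: list[str] = []
        for tb in members:
            for o in tb.taus:
                if o not in organs:
                    organs.append(o)
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for o in organs:
            required_sex = SEX_SPECIFIC_ORGANS.get(o)
            vals = [
                tb.taus[o]
                for tb in members
                if o in tb.taus
                and (required_sex is None or tb.sex == required_sex)
            ]
            if not vals:
                continue
            means[o] = float(np.mean(vals))
            sds[o] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[gname] = ResidenceTimeTable(
            taus=means, sd=sds, group=gname, n_subjects=len(members)
        )
    return out


def subject_residence_times(
    ds,
    anat: ReferenceAnatomy = ADULT,
    c: PhysicsConstants = F18,
    t0_policy: str = "zero_at_injection",
    required_organs: set[str] | None = None,
) -> ResidenceTimeTable:
    """Full kinetics chain for one subject dataset.

    Decay-corrects every organ sample to its scan midpoint, converts to
    fractional uptake, integrates to organ residence times (decay tail),
    treats the bladder by direct trapezoid on measured totals (no tail),
    and closes the activity balance into the remainder. ``required_organs``
    makes a missing organ an error naming the offender.
    """
    scans = ds.schedule.scans
    windows = {i + 1: (s.start_min, s.end_min) for i, s in enumerate(scans)}
    present = set(ds.tacs["organ"].unique())
    if required_organs:
        missing = sorted(required_organs - present)
        if missing:
            raise ValueError(f"kinetics stage: missing organ TACs for {missing}")

    taus: dict[str, float] = {}
    for organ, g in ds.tacs.groupby("organ", sort=True):
        ts, fs = [], []
        for row in g.sort_values("t_min").itertuples():
            s = RoiSample(
                organ=organ,
                scan_index=int(row.scan_index),
                t_min=float(row.t_min),
                mean_conc_kBq_per_ml=float(row.conc_kBq_per_ml),
                roi_voxels=1,
            )
            s = decay_correct_to_midpoint(s, windows[s.scan_index], c)
            ts.append(s.t_min)
            fs.append(
                fractional_uptake(
                    s.mean_conc_kBq_per_ml, organ, anat, ds.injected_activity_MBq
                )
            )
        curve = FractionalUptakeCurve(organ=organ, t_min=np.array(ts), F=np.array(fs))
        taus[organ] = residence_time(curve, c, t0_policy)

    # bladder: direct trapezoid on measured totals, no decay-only tail
    tau_excreted_h = 0.0
    if len(ds.bladder):
        b = ds.bladder.sort_values("t_min")
        fs_b = [
            bladder_fraction(
                BladderSample(
                    scan_index=int(r.scan_index),
                    t_min=float(r.t_min),
                    volume_ml=float(r.volume_ml),
                    total_MBq=float(r.total_MBq),
                ),
                anat,
                ds.injected_activity_MBq,
            )[0]
            for r in b.itertuples()
        ]
        curve_b = FractionalUptakeCurve(
            organ="Urinary bladder",
            t_min=b["t_min"].to_numpy(float),
            F=np.clip(np.asarray(fs_b), 0.0, 1.0),
        )
        taus["Urinary bladder"] = residence_time(
            curve_b, c, t0_policy="zero_at_injection", tail="none"
        )
        tau_excreted_h = _estimate_excreted_tau(ds, curve_b, c)

    taus["Remainder"] = remainder_residence_time(
        taus, c, tau_excreted_h=tau_excreted_h
    )
    return ResidenceTimeTable(taus=taus, group="subject", sex=ds.sex, diet=ds.diet)


def _estimate_excreted_tau(ds, bladder_curve: FractionalUptakeCurve, c) -> float:
    """Disintegration equivalent (hours) of urine voided mid-protocol.

    The voided fraction is estimated from the drop between the bladder
    samples bracketing the void, each decayed to the void time; atoms
    removed from the body still complete their decays, contributing
    F_voided/λ.
    """
    tv = ds.schedule.void_time_min
    if tv is None:
        return 0.0
    t, F = bladder_curve.t_min, bladder_curve.F
    before = t < tv
    if not before.any() or before.all():
        return 0.0
    i_pre = int(np.where(before)[0][-1])
    f_pre_at_void = F[i_pre] * c.decay_factor(tv - t[i_pre])
    f_post_at_void = F[i_pre + 1] / c.decay_factor(t[i_pre + 1] - tv)
    f_voided = max(0.0, f_pre_at_void - f_post_at_void)
    return f_voided / c.lambda_per_min / 60.0
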