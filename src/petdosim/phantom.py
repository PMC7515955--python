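"""Synthetic whole-body biodistribution simulator.

Generates subjects with known ground-truth kinetics so the full chain —
ROI quantification, residence-time estimation, MIRD dosimetry, and
parent-fraction analysis — can be exercised and validated without any
human imaging data.

The ground-truth kinetic law for each organ is a single-compartment
uptake–washout curve multiplied by physical decay:

    F(t) = f0 · (1 − e^(−k_up·t)) · e^(−k_bio·t) · e^(−λ·t)

with F the non-decay-corrected fraction of injected activity in the organ.
This is the simplest form that reproduces rapid hepatic uptake with gradual
elimination and admits a closed-form residence time for oracle tests.

Urine is routed to a monotonically filling bladder (fraction
u·(1−e^(−k_renal·t)), times physical decay) that drops to a configurable
residual at void times; plasma metabolism converts parent tracer to a
metabolite at a constant rate, so the parent fraction declines as
e^(−metabolite_rate·t).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .physics import F18, PhysicsConstants
from .anatomy import ADULT, ReferenceAnatomy

__all__ = [
    "OrganKinetics",
    "SubjectKinetics",
    "Scan",
    "ScanSchedule",
    "SubjectDataset",
    "VoxelPhantom",
    "ChromatographyConfig",
    "default_protocol",
    "default_kinetics",
    "organ_fraction_curve",
    "closed_form_residence_time",
    "bladder_biological_content",
    "simulate_subject",
    "render_phantom_frames",
    "simulate_chromatogram",
    "CHROMATOGRAM_TIMES_MIN",
]

#: Plasma sampling grid (minutes post-injection) for metabolite analysis.
CHROMATOGRAM_TIMES_MIN: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class OrganKinetics:
    """Ground-truth kinetic parameters for one source organ.

    f0 is the dimensionless peak fractional uptake (decay-corrected
    asymptote of the uptake phase), k_up and k_bio are biological uptake
    and clearance rates in 1/min.
    """

    organ: str
    f0: float
    k_up: float
    k_bio: float
    reference_volume_ml: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"{self.organ}: f0 must be in [0, 1]")
        if self.k_up < 0 or self.k_bio < 0:
            raise ValueError(f"{self.organ}: rates must be non-negative")
        if self.reference_volume_ml <= 0:
            raise ValueError(f"{self.organ}: reference volume must be positive")


@dataclass(frozen=True)
class SubjectKinetics:
    """Per-subject ground truth: organ kinetics plus excretion and metabolism."""

    organs: tuple[OrganKinetics, ...]
    urinary_fraction: float = 0.30
    k_renal: float = 0.01
    metabolite_rate: float = 4.8e-4
    injected_activity_MBq: float = 159.48
    sex: str = "male"
    diet: str = "fed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.urinary_fraction <= 1.0:
            raise ValueError("urinary_fraction must be in [0, 1]")
        total = sum(k.f0 for k in self.organs) + self.urinary_fraction
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"sum of organ f0 plus urinary fraction is {total:.3f} > 1"
            )
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.diet not in ("fed", "fasted"):
            raise ValueError("diet must be 'fed' or 'fasted'")

    @property
    def organ_map(self) -> dict[str, OrganKinetics]:
        return {k.organ: k for k in self.organs}


@dataclass(frozen=True)
class Scan:
    """One whole-body pass: start time, per-bed duration, bed count, direction."""

    start_min: float
    minutes_per_bed: float
    n_beds: int
    direction: str = "caudocranial"

    def __post_init__(self) -> None:
        if not 1 <= self.n_beds <= 10:
            raise ValueError("n_beds must be in [1, 10]")
        if self.minutes_per_bed <= 0:
            raise ValueError("minutes_per_bed must be positive")
        if self.direction not in ("craniocaudal", "caudocranial"):
            raise ValueError("direction must be craniocaudal or caudocranial")

    @property
    def end_min(self) -> float:
        return self.start_min + self.minutes_per_bed * self.n_beds

    @property
    def midpoint_min(self) -> float:
        return 0.5 * (self.start_min + self.end_min)

    def bed_time(self, bed_from_head: int) -> float:
        """Acquisition time of a bed position, counted from the head end.

        The bed order is set by the scan direction: a caudocranial scan
        images the most caudal bed first, so head beds are acquired last.
        """
        if not 0 <= bed_from_head < self.n_beds:
            raise ValueError("bed index outside scan")
        order = (
            bed_from_head
            if self.direction == "craniocaudal"
            else self.n_beds - 1 - bed_from_head
        )
        return self.start_min + order * self.minutes_per_bed


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered whole-body scans with an optional mid-protocol void.

    ``void_after_scan_index`` counts scans from 1: a value of 4 means the
    subject voids in the break after the fourth scan.
    """

    scans: tuple[Scan, ...]
    void_after_scan_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.scans) == 0:
            raise ValueError("schedule must contain at least one scan")
        for a, b in zip(self.scans, self.scans[1:]):
            if b.start_min < a.end_min:
                raise ValueError("scans overlap or are out of order")
        if self.void_after_scan_index is not None:
            if not 1 <= self.void_after_scan_index < len(self.scans):
                raise ValueError("void index must be < number of scans")

    @property
    def void_time_min(self) -> float | None:
        """Void placed midway through the break following the void scan."""
        if self.void_after_scan_index is None:
            return None
        i = self.void_after_scan_index - 1
        return 0.5 * (self.scans[i].end_min + self.scans[i + 1].start_min)

    @property
    def span_min(self) -> float:
        return self.scans[-1].end_min

    def to_dict(self) -> dict:
        return {
            "scans": [
                {
                    "start_min": s.start_min,
                    "minutes_per_bed": s.minutes_per_bed,
                    "n_beds": s.n_beds,
                    "direction": s.direction,
                }
                for s in self.scans
            ],
            "void_after_scan_index": self.void_after_scan_index,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanSchedule":
        return cls(
            scans=tuple(Scan(**s) for s in d["scans"]),
            void_after_scan_index=d.get("void_after_scan_index"),
        )


#: Default bed position (from the head, 6-bed vertex→mid-thigh pass) of each
#: organ's centroid. Table rows without an entry fall in the trunk bed.
DEFAULT_BED_MAP: dict[str, int] = {
    "Brain": 0,
    "Thyroid": 1,
    "Lungs": 2,
    "Heart": 2,
    "Breasts": 2,
    "Thymus": 2,
    "Liver": 3,
    "Stomach": 3,
    "Spleen": 3,
    "Pancreas": 3,
    "Kidneys": 3,
    "Adrenals": 3,
    "Gallbladder": 3,
    "Red marrow": 3,
    "Cortical bone": 3,
    "Muscle": 3,
    "Small intestine": 4,
    "Upper large intestine": 4,
    "Lower large intestine": 4,
    "Urinary bladder": 5,
    "Ovaries": 5,
    "Uterus": 5,
    "Testes": 5,
}
_TRUNK_BED = 3
_BLADDER_BED = 5


def default_protocol() -> ScanSchedule:
    """Six whole-body passes within a 4-h window, voiding after the fourth.

    Per-bed durations are 1, 2, 5, 5, 7 and 7 min over six bed positions
    (vertex to mid-thigh), acquired caudocranially; scanning starts 6 min
    after injection and a ~20-min break (void plus repeat attenuation CT)
    separates the fourth and fifth passes.
    """
    mpb = (1.0, 2.0, 5.0, 5.0, 7.0, 7.0)
    starts = (6.0, 14.0, 30.0, 64.0, 115.0, 160.0)
    scans = tuple(
        Scan(start_min=s, minutes_per_bed=m, n_beds=6, direction="caudocranial")
        for s, m in zip(starts, mpb)
    )
    return ScanSchedule(scans=scans, void_after_scan_index=4)


def organ_fraction_curve(
    k: OrganKinetics, c: PhysicsConstants, t: float | np.ndarray
) -> float | np.ndarray:
    """Non-decay-corrected fractional uptake F(t) of one organ.

    F(t) = f0 · (1 − e^(−k_up·t)) · e^(−(k_bio+λ)·t). k_up = inf is the
    instantaneous-uptake limit (uptake factor 1 for t > 0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if math.isinf(k.k_up):
        uptake = np.where(t_arr > 0, 1.0, 0.0)
    else:
        uptake = -np.expm1(-k.k_up * t_arr)
    out = k.f0 * uptake * np.exp(-(k.k_bio + c.lambda_per_min) * t_arr)
    return float(out) if np.isscalar(t) else out


def closed_form_residence_time(k: OrganKinetics, c: PhysicsConstants) -> float:
    """Analytic residence time (hours) of the ground-truth kinetic law.

    ∫F dt = f0·[1/(λ+k_bio) − 1/(λ+k_bio+k_up)] minutes, converted to hours.
    """
    lam_b = c.lambda_per_min + k.k_bio
    if math.isinf(k.k_up):
        tail = 0.0
    else:
        tail = 1.0 / (lam_b + k.k_up)
    return k.f0 * (1.0 / lam_b - tail) / 60.0


def _parent_fraction_at(kin: SubjectKinetics, t_min: float) -> float:
    return math.exp(-kin.metabolite_rate * t_min)


def bladder_biological_content(
    kin: SubjectKinetics,
    t: float,
    void_time_min: float | None,
    void_residual: float,
) -> float:
    """Decay-corrected fraction of injected activity in the bladder at ``t``.

    Renal inflow accumulates as u·(1−e^(−k_renal·t)); at the void the
    content drops to ``void_residual`` of itself and filling resumes.
    Multiply by e^(−λt) for the physical (measured) fraction.
    """
    u, kr = kin.urinary_fraction, kin.k_renal

    def cum(tt: float) -> float:
        if math.isinf(kr):
            return u if tt > 0 else 0.0
        return u * -math.expm1(-kr * tt)

    if void_time_min is None or t < void_time_min:
        return cum(t)
    return void_residual * cum(void_time_min) + (cum(t) - cum(void_time_min))


def voided_fraction(
    kin: SubjectKinetics,
    void_time_min: float | None,
    void_residual: float,
    c: PhysicsConstants,
) -> float:
    """Non-decay-corrected fraction of injected activity removed at the void."""
    if void_time_min is None:
        return 0.0
    b = bladder_biological_content(kin, void_time_min, None, void_residual)
    return (1.0 - void_residual) * b * c.decay_factor(void_time_min)


@dataclass(frozen=True)
class ChromatographyConfig:
    """Radio-HPLC geometry: retention times and peak widths in minutes.

    Peaks are labelled by retention window only; no chemical identity is
    asserted for the metabolite peak.
    """

    parent_rt_min: float = 9.0
    metabolite_rt_min: float = 4.0
    peak_sigma_min: float = 0.15
    run_min: float = 20.0
    dt_min: float = 0.05
    baseline_cpm: float = 50.0

    @property
    def parent_window(self) -> tuple[float, float]:
        return (self.parent_rt_min - 0.8, self.parent_rt_min + 0.8)

    @property
    def metabolite_windows(self) -> list[tuple[float, float]]:
        return [(self.metabolite_rt_min - 0.8, self.metabolite_rt_min + 0.8)]


DEFAULT_CHROMATOGRAPHY = ChromatographyConfig()


def simulate_chromatogram(
    parent_fraction: float,
    total_counts: float,
    seed: int | np.random.Generator | None = 0,
    config: ChromatographyConfig = DEFAULT_CHROMATOGRAPHY,
    noise: bool = True,
) -> pd.DataFrame:
    """Two-Gaussian radio-HPLC trace with Poisson counting noise.

    Total peak area (above baseline) is ``total_counts`` split
    ``parent_fraction`` : ``1 − parent_fraction`` between the parent and
    metabolite retention times. Returns columns ``time_min`` and ``cpm``.
    """
    if not 0.0 <= parent_fraction <= 1.0:
        raise ValueError("parent_fraction must be in [0, 1]")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    cfg = config
    t = np.arange(0.0, cfg.run_min + cfg.dt_min / 2, cfg.dt_min)

    def peak(rt: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - rt) / cfg.peak_sigma_min) ** 2) / (
            cfg.peak_sigma_min * math.sqrt(2.0 * math.pi)
        )

    cpm = cfg.baseline_cpm + total_counts * (
        parent_fraction * peak(cfg.parent_rt_min)
        + (1.0 - parent_fraction) * peak(cfg.metabolite_rt_min)
    )
    if noise:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        counts = rng.poisson(cpm * cfg.dt_min)
        cpm = counts / cfg.dt_min
    return pd.DataFrame({"time_min": t, "cpm": cpm.astype(float)})


@dataclass
class SubjectDataset:
    """Everything measured for one subject.

    tacs: organ, scan_index (1-based), t_min, conc_kBq_per_ml
    bladder: scan_index, t_min, volume_ml, total_MBq
    chromatograms: sample time (min) → DataFrame(time_min, cpm)
    """

    tacs: pd.DataFrame
    bladder: pd.DataFrame
    chromatograms: dict[float, pd.DataFrame]
    injected_activity_MBq: float
    sex: str
    diet: str
    seed: int | None
    schedule: ScanSchedule
    ground_truth: SubjectKinetics | None = None

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.tacs.to_csv(d / "tacs.csv", index=False)
        self.bladder.to_csv(d / "bladder.csv", index=False)
        cdir = d / "chromatograms"
        cdir.mkdir(exist_ok=True)
        for t, df in self.chromatograms.items():
            df.to_csv(cdir / f"t{t:g}.csv", index=False)
        meta = {
            "injected_activity_MBq": self.injected_activity_MBq,
            "sex": self.sex,
            "diet": self.diet,
            "seed": self.seed,
            "schedule": self.schedule.to_dict(),
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SubjectDataset":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        chroms = {}
        for f in sorted((d / "chromatograms").glob("t*.csv")):
            chroms[float(f.stem[1:])] = pd.read_csv(f)
        return cls(
            tacs=pd.read_csv(d / "tacs.csv"),
            bladder=pd.read_csv(d / "bladder.csv"),
            chromatograms=chroms,
            injected_activity_MBq=meta["injected_activity_MBq"],
            sex=meta["sex"],
            diet=meta["diet"],
            seed=meta["seed"],
            schedule=ScanSchedule.from_dict(meta["schedule"]),
        )


def simulate_subject(
    kin: SubjectKinetics,
    sched: ScanSchedule | None = None,
    noise_cv: float = 0.0,
    seed: int | None = 0,
    c: PhysicsConstants = F18,
    bed_map: Mapping[str, int] | None = None,
    void_residual: float = 0.2,
    bladder_v0_ml: float = 80.0,
    urine_rate_ml_per_min: float = 0.9,
    chromatogram_times: Sequence[float] = CHROMATOGRAM_TIMES_MIN,
    chromatogram_counts: float = 1e6,
    chromatography: ChromatographyConfig = DEFAULT_CHROMATOGRAPHY,
) -> SubjectDataset:
    """Simulate the measurement process for one subject.

    Each organ is sampled once per whole-body scan at its bed-acquisition
    time; measured concentration = F(t)·injected/volume with multiplicative
    lognormal noise of the given CV. The bladder series carries total
    activity and volume; chromatograms are drawn at the plasma sampling
    times with Poisson counting noise.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    sched = sched or default_protocol()
    bed_map = dict(DEFAULT_BED_MAP if bed_map is None else bed_map)
    rng = np.random.default_rng(seed)
    # lognormal with unit mean and the requested CV
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma == 0.0:
            return x
        return x * math.exp(rng.normal(-0.5 * sigma**2, sigma))

    rows = []
    for i, scan in enumerate(sched.scans, start=1):
        for k in kin.organs:
            bed = min(bed_map.get(k.organ, _TRUNK_BED), scan.n_beds - 1)
            t = scan.bed_time(bed)
            frac = organ_fraction_curve(k, c, t)
            conc = frac * kin.injected_activity_MBq * 1000.0 / k.reference_volume_ml
            rows.append(
                {
                    "organ": k.organ,
                    "scan_index": i,
                    "t_min": t,
                    "conc_kBq_per_ml": noisy(conc),
                }
            )
    tacs = pd.DataFrame(rows)

    void_t = sched.void_time_min
    brows = []
    for i, scan in enumerate(sched.scans, start=1):
        bed = min(_BLADDER_BED, scan.n_beds - 1)
        t = scan.bed_time(bed)
        b = bladder_biological_content(kin, t, void_t, void_residual)
        total = b * c.decay_factor(t) * kin.injected_activity_MBq
        if void_t is None or t < void_t:
            vol = bladder_v0_ml + urine_rate_ml_per_min * t
        else:
            pre = bladder_v0_ml + urine_rate_ml_per_min * void_t
            vol = void_residual * pre + urine_rate_ml_per_min * (t - void_t)
        brows.append(
            {
                "scan_index": i,
                "t_min": t,
                "volume_ml": vol,
                "total_MBq": noisy(total),
            }
        )
    bladder = pd.DataFrame(brows)

    chroms = {
        float(t): simulate_chromatogram(
            _parent_fraction_at(kin, t),
            chromatogram_counts,
            seed=rng,
            config=chromatography,
            noise=noise_cv > 0,
        )
        for t in chromatogram_times
    }
    return SubjectDataset(
        tacs=tacs,
        bladder=bladder,
        chromatograms=chroms,
        injected_activity_MBq=kin.injected_activity_MBq,
        sex=kin.sex,
        diet=kin.diet,
        seed=seed,
        schedule=sched,
        ground_truth=kin,
    )


# ---------------------------------------------------------------------------
# Packaged parameter sets
# ---------------------------------------------------------------------------

#: (f0, k_up 1/min, k_bio 1/min) per organ for the two dietary states.
#: Hepatic uptake is higher in the fed state; renal/urinary clearance
#: dominates elimination; all other organs show low, slowly clearing uptake.
_DIET_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "fed": {
        "Liver": (0.130, 0.08, 0.0005),
        "Kidneys": (0.030, 0.15, 0.0005),
        "Muscle": (0.220, 0.03, 0.0004),
        "Brain": (0.009, 0.05, 0.0005),
        "Heart": (0.014, 0.20, 0.0005),
        "Lungs": (0.016, 0.20, 0.0005),
        "Spleen": (0.0025, 0.15, 0.0005),
        "Red marrow": (0.009, 0.05, 0.0005),
        "Small intestine": (0.012, 0.05, 0.0005),
        "Stomach": (0.005, 0.05, 0.0005),
        "Upper large intestine": (0.004, 0.04, 0.0005),
        "Lower large intestine": (0.003, 0.04, 0.0005),
        "Gallbladder": (0.002, 0.06, 0.0005),
        "Adrenals": (0.0003, 0.10, 0.0005),
        "Pancreas": (0.0015, 0.10, 0.0005),
        "Thyroid": (0.0003, 0.10, 0.0005),
        "Cortical bone": (0.012, 0.02, 0.0003),
        "Testes": (0.0004, 0.05, 0.0005),
        "Ovaries": (0.00006, 0.05, 0.0005),
        "Uterus": (0.0012, 0.05, 0.0005),
        "Breasts": (0.0015, 0.05, 0.0005),
    },
    "fasted": {
        "Liver": (0.100, 0.08, 0.0005),
        "Kidneys": (0.027, 0.15, 0.0005),
        "Muscle": (0.240, 0.03, 0.0004),
        "Brain": (0.010, 0.05, 0.0005),
        "Heart": (0.015, 0.20, 0.0005),
        "Lungs": (0.018, 0.20, 0.0005),
        "Spleen": (0.003, 0.15, 0.0005),
        "Red marrow": (0.010, 0.05, 0.0005),
        "Small intestine": (0.014, 0.05, 0.0005),
        "Stomach": (0.007, 0.05, 0.0005),
        "Upper large intestine": (0.0045, 0.04, 0.0005),
        "Lower large intestine": (0.0035, 0.04, 0.0005),
        "Gallbladder": (0.002, 0.06, 0.0005),
        "Adrenals": (0.0004, 0.10, 0.0005),
        "Pancreas": (0.0012, 0.10, 0.0005),
        "Thyroid": (0.0003, 0.10, 0.0005),
        "Cortical bone": (0.014, 0.02, 0.0003),
        "Testes": (0.0004, 0.05, 0.0005),
        "Ovaries": (0.00006, 0.05, 0.0005),
        "Uterus": (0.0010, 0.05, 0.0005),
        "Breasts": (0.0015, 0.05, 0.0005),
    },
}

#: Plasma parent fraction at 120 min implied by each default parameter set.
PARENT_FRACTION_120: dict[str, float] = {"fed": 0.944, "fasted": 0.959}


def default_kinetics(
    diet: str = "fed",
    sex: str = "male",
    injected_activity_MBq: float = 159.48,
    anat: ReferenceAnatomy = ADULT,
) -> SubjectKinetics:
    """Packaged fed/fasted ground-truth parameter set.

    The metabolite conversion rate is calibrated so the plasma parent
    fraction at 120 min equals 94.4% (fed) or 95.9% (fasted); liver uptake
    is higher fed than fasted; 30% of administered activity is routed to
    urine with a 0.01/min renal rate.
    """
    if diet not in _DIET_PARAMS:
        raise ValueError("diet must be 'fed' or 'fasted'")
    from .anatomy import SEX_SPECIFIC_ORGANS

    organs = tuple(
        OrganKinetics(
            organ=o, f0=f0, k_up=ku, k_bio=kb, reference_volume_ml=anat.volume_ml(o)
        )
        for o, (f0, ku, kb) in _DIET_PARAMS[diet].items()
        if SEX_SPECIFIC_ORGANS.get(o, sex) == sex
    )
    rate = -math.log(PARENT_FRACTION_120[diet]) / 120.0
    return SubjectKinetics(
        organs=organs,
        urinary_fraction=0.30,
        k_renal=0.01,
        metabolite_rate=rate,
        injected_activity_MBq=injected_activity_MBq,
        sex=sex,
        diet=diet,
    )


# ---------------------------------------------------------------------------
# Voxel phantom rendering
# ---------------------------------------------------------------------------


@dataclass
class VoxelPhantom:
    """Per-frame 3-D activity grids (kBq/mL) with one shared label mask."""

    frames: np.ndarray  # (n_frames, nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) integer labels, 0 = background
    voxel_volume_ml: float
    labels: dict[str, int]
    frame_times_min: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.frames.shape[1:] != self.mask.shape:
            raise ValueError("frame and mask shapes differ")

    def save(self, directory: str | Path) -> None:
        import nibabel as nib

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        for i in range(self.frames.shape[0]):
            nib.save(
                nib.Nifti1Image(self.frames[i].astype(np.float64), affine),
                d / f"frame_{i + 1:02d}.nii",
            )
        nib.save(
            nib.Nifti1Image(self.mask.astype(np.int16), affine), d / "mask.nii"
        )
        (d / "labels.json").write_text(
            json.dumps(
                {
                    "labels": self.labels,
                    "voxel_volume_ml": self.voxel_volume_ml,
                    "frame_times_min": list(self.frame_times_min),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "VoxelPhantom":
        import nibabel as nib

        d = Path(directory)
        meta = json.loads((d / "labels.json").read_text())
        frames = np.stack(
            [
                np.asarray(nib.load(f).dataobj, dtype=float)
                for f in sorted(d.glob("frame_*.nii"))
            ]
        )
        mask = np.asarray(nib.load(d / "mask.nii").dataobj, dtype=int)
        return cls(
            frames=frames,
            mask=mask,
            voxel_volume_ml=meta["voxel_volume_ml"],
            labels={k: int(v) for k, v in meta["labels"].items()},
            frame_times_min=tuple(meta["frame_times_min"]),
        )


def render_phantom_frames(
    ds: SubjectDataset,
    grid_shape: tuple[int, int, int] = (8, 8, 96),
    seed: int | None = 0,
    voxel_noise_cv: float = 0.0,
    background: float = 0.0,
    voxel_volume_ml: float = 1.0,
    block_shape: tuple[int, int, int] = (4, 4, 3),
) -> VoxelPhantom:
    """Rasterise a subject's organ concentrations into labelled voxel frames.

    Each organ becomes a contiguous rectangular block stacked along z with a
    one-voxel gap; the mask is identical across frames and the block's mean
    value equals the organ's concentration sample for that scan (before any
    voxel noise).
    """
    organs = sorted(ds.tacs["organ"].unique())
    bx, by, bz = block_shape
    nx, ny, nz = grid_shape
    if bx > nx or by > ny:
        raise ValueError("block larger than grid in x/y")
    if len(organs) * (bz + 1) > nz + 1:
        raise ValueError(
            f"grid too small: {len(organs)} organs need z ≥ {len(organs) * (bz + 1) - 1}"
        )
    mask = np.zeros(grid_shape, dtype=int)
    labels: dict[str, int] = {}
    for j, organ in enumerate(organs):
        z0 = j * (bz + 1)
        region = mask[:bx, :by, z0 : z0 + bz]
        if np.any(region != 0):
            raise ValueError(f"organ regions overlap at {organ}")
        region[...] = j + 1
        labels[organ] = j + 1

    scan_indices = sorted(ds.tacs["scan_index"].unique())
    conc = ds.tacs.set_index(["organ", "scan_index"])["conc_kBq_per_ml"]
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(voxel_noise_cv**2)) if voxel_noise_cv > 0 else 0.0
    frames = np.full((len(scan_indices), *grid_shape), background, dtype=float)
    times = []
    for fi, si in enumerate(scan_indices):
        for organ in organs:
            vals = np.full(int((mask == labels[organ]).sum()), conc[(organ, si)])
            if sigma > 0:
                vals = vals * np.exp(rng.normal(-0.5 * sigma**2, sigma, vals.shape))
            frames[fi][mask == labels[organ]] = vals
        times.append(float(ds.tacs.loc[ds.tacs["scan_index"] == si, "t_min"].min()))
    return VoxelPhantom(
        frames=frames,
        mask=mask,
        voxel_volume_ml=voxel_volume_ml,
        labels=labels,
        frame_times_min=tuple(times),
    )
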