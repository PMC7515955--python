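"""End-to-end orchestration: simulate → quantify → kinetics → dosimetry →
metabolites, with per-stage artifacts and provenance.

A single :class:`RunConfig` drives everything so that group analyses
(male/female, fed/fasted) are reproducible from one file; identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import ADULT, ReferenceAnatomy
from .dosimetry import (
    BladderScenario,
    DoseReport,
    SMatrix,
    dose_report,
    load_smatrix,
    synthetic_smatrix,
)
from .kinetics import ResidenceTimeTable, group_mean_taus, subject_residence_times
from .metabolites import group_parent_summary, measure_parent_fractions
from .phantom import (
    ScanSchedule,
    SubjectDataset,
    default_kinetics,
    default_protocol,
    simulate_subject,
)
from .physics import F18, PhysicsConstants

logger = logging.getLogger("petdosim")

#: Canonical residence-time row order for reports and case files.
ORGAN_ORDER: tuple[str, ...] = (
    "Adrenals",
    "Brain",
    "Breasts",
    "Gallbladder",
    "Lower large intestine",
    "Small intestine",
    "Stomach",
    "Upper large intestine",
    "Heart",
    "Kidneys",
    "Liver",
    "Lungs",
    "Muscle",
    "Ovaries",
    "Pancreas",
    "Red marrow",
    "Cortical bone",
    "Spleen",
    "Testes",
    "Thyroid",
    "Urinary bladder",
    "Uterus",
    "Remainder",
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "petdosim_out"
    n_fed: int = 12
    n_fasted: int = 12
    noise_cv: float = 0.05
    seed: int = 1
    t0_policy: str = "zero_at_injection"
    baseline_policy: str = "flat_from_flanks"
    voiding_interval_h: float = 2.0
    use_dynamic_bladder: bool = False
    grouping: str = "diet"
    smatrix_path: str | None = None
    half_life_min: float = F18.half_life_min
    subject_dirs: list[str] = field(default_factory=list)
    required_organs: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    subjects: list[SubjectDataset]
    subject_taus: list[ResidenceTimeTable]
    group_taus: dict[str, ResidenceTimeTable]
    doses: DoseReport
    parent_summary: pd.DataFrame


def simulate_cohort(
    n_fed: int,
    n_fasted: int,
    seed: int,
    noise_cv: float,
    sched: ScanSchedule | None = None,
    anat: ReferenceAnatomy = ADULT,
    c: PhysicsConstants = F18,
) -> list[SubjectDataset]:
    """Simulate a cohort with the packaged fed/fasted defaults.

    Sexes alternate within each dietary group; each subject gets a
    deterministic sub-seed derived from the cohort seed.
    """
    sched = sched or default_protocol()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_fed + n_fasted)]
    subjects = []
    diets = ["fed"] * n_fed + ["fasted"] * n_fasted
    for i, diet in enumerate(diets):
        sex = "male" if i % 2 == 0 else "female"
        kin = default_kinetics(diet=diet, sex=sex, anat=anat)
        subjects.append(
            simulate_subject(kin, sched, noise_cv=noise_cv, seed=child_seeds[i], c=c)
        )
    return subjects


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name} stage failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full chain and (optionally) write all artifacts."""
    c = PhysicsConstants(half_life_min=cfg.half_life_min)
    outdir = Path(cfg.outdir)

    @_stage("simulate")
    def _simulate() -> list[SubjectDataset]:
        if cfg.subject_dirs:
            return [SubjectDataset.load(d) for d in cfg.subject_dirs]
        return simulate_cohort(cfg.n_fed, cfg.n_fasted, cfg.seed, cfg.noise_cv, c=c)

    subjects = _simulate()
    logger.info("simulated/loaded %d subjects", len(subjects))

    required = set(cfg.required_organs) or None

    @_stage("kinetics")
    def _kinetics() -> list[ResidenceTimeTable]:
        return [
            subject_residence_times(
                ds, c=c, t0_policy=cfg.t0_policy, required_organs=required
            )
            for ds in subjects
        ]

    subject_taus = _kinetics()
    group_taus = group_mean_taus(subject_taus, grouping="all")
    by_group = group_mean_taus(subject_taus, grouping=cfg.grouping) if cfg.grouping != "all" else {}
    group_taus.update(by_group)

    @_stage("dosimetry")
    def _dose() -> DoseReport:
        sm: SMatrix = (
            load_smatrix(cfg.smatrix_path)
            if cfg.smatrix_path
            else synthetic_smatrix(c=c)
        )
        scenario = (
            BladderScenario(voiding_interval_h=cfg.voiding_interval_h)
            if cfg.use_dynamic_bladder
            else None
        )
        bladder_inputs = None
        if scenario is not None:
            kin = subjects[0].ground_truth or default_kinetics()
            bladder_inputs = (kin.k_renal, kin.urinary_fraction)
        return dose_report(
            subject_taus, sm, scenario=scenario, bladder_inputs=bladder_inputs, c=c
        )

    doses = _dose()

    @_stage("metabolites")
    def _metab() -> pd.DataFrame:
        curves = [
            measure_parent_fractions(
                ds, subject_id=f"s{i + 1:02d}", baseline_policy=cfg.baseline_policy
            )
            for i, ds in enumerate(subjects)
        ]
        return group_parent_summary(curves, grouping=cfg.grouping if cfg.grouping == "diet" else "all")

    parent_summary = _metab()

    result = PipelineResult(
        subjects=subjects,
        subject_taus=subject_taus,
        group_taus=group_taus,
        doses=doses,
        parent_summary=parent_summary,
    )
    if write:
        write_artifacts(result, cfg, outdir)
    return result


def write_artifacts(result: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tau_frames = []
    for gname, table in sorted(result.group_taus.items()):
        df = table.to_frame()
        df["group"] = gname
        tau_frames.append(df)
    taus_df = pd.concat(tau_frames, ignore_index=True)
    order = {o: i for i, o in enumerate(ORGAN_ORDER)}
    taus_df["__o"] = taus_df["organ"].map(lambda o: order.get(o, len(order)))
    taus_df = taus_df.sort_values(["group", "__o"]).drop(columns="__o")
    taus_df.to_csv(outdir / "residence_times.csv", index=False)

    write_olinda_case(result.group_taus["all"], outdir / "olinda_case.txt")

    dose_df = result.doses.to_frame()
    dose_df["__o"] = dose_df["organ"].map(lambda o: order.get(o, len(order)))
    dose_df = dose_df.sort_values("__o").drop(columns="__o")
    ed_row = pd.DataFrame(
        {
            "organ": ["Effective dose (mSv/MBq)"],
            "mean_mGy_per_MBq": [result.doses.effective_dose_mSv_per_MBq],
            "sd_mGy_per_MBq": [result.doses.effective_dose_sd],
        }
    )
    pd.concat([dose_df, ed_row], ignore_index=True).to_csv(
        outdir / "dose_report.csv", index=False
    )
    payload = {
        "bladder_scenario": result.doses.bladder_scenario,
        "effective_dose_mSv_per_MBq": result.doses.effective_dose_mSv_per_MBq,
        "effective_dose_sd": result.doses.effective_dose_sd,
        "organ_doses_mGy_per_MBq": result.doses.organ_doses,
        "per_source_contributions": (
            result.doses.contributions.round(12).to_dict()
            if result.doses.contributions is not None
            else None
        ),
    }
    (outdir / "dose_report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    result.parent_summary.to_csv(outdir / "parent_fraction.csv", index=False)

    cfg_dict = cfg.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": cfg.seed,
                "config": cfg_dict,
                "config_sha256": digest,
                "n_subjects": len(result.subjects),
            },
            indent=2,
            sort_keys=True,
        )
    )


def write_olinda_case(
    taus: ResidenceTimeTable, path: str | Path, phantom: str = "adult_reference_man"
) -> None:
    """Plain-text residence-time case file for external dose software.

    Header line ``# phantom: <name>``, then one tab-separated line per
    organ with τ to 6 significant digits, in canonical row order.
    """
    lines = [f"# phantom: {phantom}"]
    ordered = [o for o in ORGAN_ORDER if o in taus.taus]
    extra = [o for o in taus.taus if o not in ORGAN_ORDER]
    for organ in ordered + sorted(extra):
        lines.append(f"{organ}\t{taus.taus[organ]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_olinda_case(path: str | Path) -> ResidenceTimeTable:
    taus: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        organ, val = line.rsplit("\t", 1)
        taus[organ] = float(val)
    return ResidenceTimeTable(taus=taus, group="case_file")
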