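"""Packaged reference tables for ¹⁸F-FPIA whole-body dosimetry.

Mean organ absorbed doses and residence times for ¹⁸F-fluoropivalate in
24 healthy adults (12 male / 12 female; 12 fed / 12 fasted), as published
for its first-in-human dosimetry study. Used as parsing fixtures and as
the organ-dose input for the ICRP-60 effective-dose computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_organ_doses",
    "reference_organ_dose_map",
    "load_reference_residence_times",
    "REPORTED_EFFECTIVE_DOSE_MSV_PER_MBQ",
]

#: Published mean effective dose (mSv/MBq) over the 24-subject cohort.
REPORTED_EFFECTIVE_DOSE_MSV_PER_MBQ = 1.54e-2


def _read(name: str) -> pd.DataFrame:
    with resources.files("petdosim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_organ_doses() -> pd.DataFrame:
    """Mean organ absorbed doses (mGy/MBq) ± SD, including the Total Body row."""
    return _read("reference_organ_doses.csv")


def reference_organ_dose_map() -> dict[str, float]:
    """The 22 per-organ mean absorbed doses as a mapping (Total Body excluded)."""
    df = load_reference_organ_doses()
    df = df[df["organ"] != "Total Body"]
    return dict(zip(df["organ"], df["mean_mGy_per_MBq"].astype(float)))


def load_reference_residence_times() -> pd.DataFrame:
    """Mean residence times τ (MBq·h/MBq) ± SD by sex and dietary group.

    Sex-specific organs are blank (NaN) in the inapplicable sex column.
    """
    return _read("reference_residence_times.csv")
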