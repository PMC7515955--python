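"""Reference anatomy: organ volumes and masses of the adult reference man.

Activity concentrations measured in an ROI are converted to whole-organ
activity with these reference volumes (ICRP-23 style adult reference man),
and the effective-dose remainder rule weights organs by reference mass.
Values are nominal adult values in mL and g; users working with a different
phantom can supply their own :class:`ReferenceAnatomy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: organ -> (reference volume mL, reference mass g)
_ADULT_REFERENCE: dict[str, tuple[float, float]] = {
    "Adrenals": (14.0, 14.0),
    "Brain": (1400.0, 1400.0),
    "Breasts": (360.0, 360.0),
    "Gallbladder": (60.0, 60.0),
    "Lower large intestine": (160.0, 160.0),
    "Small intestine": (640.0, 640.0),
    "Stomach": (250.0, 250.0),
    "Upper large intestine": (210.0, 210.0),
    "Heart": (600.0, 600.0),
    "Kidneys": (310.0, 310.0),
    "Liver": (1800.0, 1800.0),
    "Lungs": (1000.0, 1000.0),
    "Muscle": (28000.0, 28000.0),
    "Ovaries": (11.0, 11.0),
    "Pancreas": (100.0, 100.0),
    "Red marrow": (1500.0, 1500.0),
    "Cortical bone": (4000.0, 4000.0),
    "Spleen": (180.0, 180.0),
    "Testes": (35.0, 35.0),
    "Thymus": (20.0, 20.0),
    "Thyroid": (20.0, 20.0),
    "Urinary bladder": (200.0, 245.0),
    "Uterus": (80.0, 80.0),
}

#: Organs that exist only in one sex.
SEX_SPECIFIC_ORGANS: dict[str, str] = {
    "Ovaries": "female",
    "Uterus": "female",
    "Breasts": "female",  # blank for males in the study's residence-time table
    "Testes": "male",
}


@dataclass(frozen=True)
class ReferenceAnatomy:
    """Reference organ volumes (mL) and masses (g) for one phantom."""

    phantom: str = "adult_reference_man"
    volumes_ml: dict[str, float] = field(
        default_factory=lambda: {o: v for o, (v, _) in _ADULT_REFERENCE.items()}
    )
    masses_g: dict[str, float] = field(
        default_factory=lambda: {o: m for o, (_, m) in _ADULT_REFERENCE.items()}
    )
    reference_bladder_volume_ml: float = 200.0

    def __post_init__(self) -> None:
        for name, v in self.volumes_ml.items():
            if v <= 0:
                raise ValueError(f"non-positive reference volume for {name!r}")
        for name, m in self.masses_g.items():
            if m <= 0:
                raise ValueError(f"non-positive reference mass for {name!r}")
        if self.reference_bladder_volume_ml <= 0:
            raise ValueError("reference bladder volume must be positive")

    def volume_ml(self, organ: str) -> float:
        try:
            return self.volumes_ml[organ]
        except KeyError:
            raise KeyError(
                f"unknown organ {organ!r}; known: {sorted(self.volumes_ml)}"
            ) from None

    def mass_g(self, organ: str) -> float:
        try:
            return self.masses_g[organ]
        except KeyError:
            raise KeyError(
                f"unknown organ {organ!r}; known: {sorted(self.masses_g)}"
            ) from None


ADULT = ReferenceAnatomy()
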