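"""Radionuclide physics: decay constants and decay-correction helpers.

All internal times are minutes; residence times are reported in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical decay constants for the radionuclide (default: ¹⁸F).

    Attributes
    ----------
    half_life_min:
        Physical half-life in minutes.
    lambda_per_min:
        Decay constant ln2 / half-life, per minute. Derived automatically;
        do not set it independently of the half-life.
    """

    half_life_min: float = F18_HALF_LIFE_MIN
    lambda_per_min: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")
        object.__setattr__(self, "lambda_per_min", math.log(2.0) / self.half_life_min)

    @property
    def mean_life_h(self) -> float:
        """Mean lifetime 1/λ in hours — the residence time of activity that
        never leaves the body (2.640 h for ¹⁸F)."""
        return 1.0 / self.lambda_per_min / 60.0

    def decay_factor(self, dt_min: float) -> float:
        """e^(−λ·dt): survival fraction after ``dt_min`` minutes."""
        return math.exp(-self.lambda_per_min * dt_min)


F18 = PhysicsConstants()
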