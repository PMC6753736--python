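"""Machine constants and geometric test plans.

A test plan is the set of (collimator angle, gantry angle) pairs at which
EPID images are acquired, together with the localization noise level and the
nominal machine constants.  Angles are degrees; gantry angles live in
[-180, 180] and collimator angles in [-165, 165] (typical C-arm travel
ranges).  The noise sigma is quoted in mm on the detector plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Collimator angle set used by 5-angle plans (spanning the travel range).
FIVE_COLLIMATOR_ANGLES = (-165.0, -90.0, 0.0, 90.0, 165.0)


@dataclass(frozen=True)
class MachineConstants:
    """Nominal linac constants: SAD/SDD in cm, square field size in cm."""

    sad: float = 100.0
    sdd: float = 180.0
    field_size: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        if not 0 < self.sad < self.sdd:
            raise ConfigurationError(f"require 0 < SAD < SDD, got SAD={self.sad}, SDD={self.sdd}")
        if min(self.field_size) <= 0:
            raise ConfigurationError("field size must be positive")

    @property
    def magnification(self) -> float:
        """Isocentric-plane to detector-plane magnification SDD/SAD."""
        return self.sdd / self.sad


@dataclass(frozen=True)
class TestPlan:
    """Set of (collimator, gantry) angle pairs plus noise level and machine."""

    __test__ = False  # not a pytest class, despite the name

    pairs: tuple[tuple[float, float], ...]
    sigma_mm: float = 0.0
    machine: MachineConstants = field(default_factory=MachineConstants)

    def __post_init__(self) -> None:
        pairs = tuple((float(t), float(p)) for t, p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for theta, psi in pairs:
            if not -180.0 <= psi <= 180.0:
                raise ConfigurationError(f"gantry angle {psi} outside [-180, 180]")
            if not -165.0 <= theta <= 165.0:
                raise ConfigurationError(f"collimator angle {theta} outside [-165, 165]")
        if self.sigma_mm < 0:
            raise ConfigurationError("sigma must be non-negative")

    @property
    def sigma_cm(self) -> float:
        return self.sigma_mm / 10.0

    @property
    def gantry_angles(self) -> list[float]:
        """Distinct gantry angles in plan order."""
        seen: dict[float, None] = {}
        for _, psi in self.pairs:
            seen.setdefault(psi)
        return list(seen)

    @property
    def collimator_angles(self) -> list[float]:
        seen: dict[float, None] = {}
        for theta, _ in self.pairs:
            seen.setdefault(theta)
        return list(seen)

    @staticmethod
    def gantry_grid(n: int) -> np.ndarray:
        """``n`` gantry angles evenly spaced over [-180, 180] (both ends included)."""
        if n < 1:
            raise ConfigurationError("need at least one gantry angle")
        return np.linspace(-180.0, 180.0, n)

    @staticmethod
    def collimator_grid(n: int) -> np.ndarray:
        """``n`` collimator angles over the travel range [-165, 165].

        The 5-angle case uses the conventional set (-165, -90, 0, 90, 165);
        other counts are evenly spaced.
        """
        if n < 1:
            raise ConfigurationError("need at least one collimator angle")
        if n == 5:
            return np.array(FIVE_COLLIMATOR_ANGLES)
        return np.linspace(-165.0, 165.0, n)

    @classmethod
    def grid(
        cls,
        n_gantry: int,
        n_collimator: int,
        sigma_mm: float = 0.0,
        machine: MachineConstants | None = None,
    ) -> "TestPlan":
        """Full factorial plan: every collimator angle at every gantry angle."""
        gantry = cls.gantry_grid(n_gantry)
        coll = cls.collimator_grid(n_collimator)
        pairs = tuple((float(t), float(p)) for p in gantry for t in coll)
        return cls(pairs=pairs, sigma_mm=sigma_mm, machine=machine or MachineConstants())

    def __len__(self) -> int:
        return len(self.pairs)
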