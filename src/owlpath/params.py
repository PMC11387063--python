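"""Model parameter containers and their YAML serialization.

All regression coefficients act on standardized (z-scored) covariates, so
each slope is the change in the linear predictor per one standard deviation
of its covariate.  Reproduction submodels use a log link (eggs) or logit link
(hatching, fledging); survival uses a logit link.  Detection is parameterized
by recapture probability ``p`` and dead-recovery probability ``r``, each
specific to the tag group (ring-only vs VHF-transmitter birds).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from typing import Iterator

import numpy as np
import yaml

from owlpath.exceptions import ConfigurationError

SEXES = ("F", "M")
TAG_GROUPS = ("ring", "vhf")

# Covariate order of each linear predictor (first entry is the intercept).
EGG_TERMS = ("intercept", "experience", "laying_date", "prey_sm_prelay", "prey_vole_prelay")
HATCH_TERMS = (
    "intercept",
    "experience",
    "eggs",
    "laying_date",
    "cond_incubation",
    "prey_sm_incub",
    "prey_vole_incub",
)
FLEDGE_TERMS = (
    "intercept",
    "experience",
    "nestlings",
    "laying_date",
    "cond_rearing",
    "prey_sm_rear",
    "prey_vole_rear",
)
SURVIVAL_TERMS = (
    "intercept",
    "experience",
    "cond_rearing",
    "nestlings",
    "fledglings",
    "gc_baseline",
    "gc_stress",
    "spot",
    "prey_sm_incub",
    "prey_vole_incub",
    "prey_sm_winter",
    "prey_vole_winter",
)


class _CoefficientSet:
    """Mixin giving coefficient dataclasses array/dict round-trips."""

    TERMS: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, values) -> "_CoefficientSet":
        values = np.asarray(values, dtype=float)
        names = [f.name for f in fields(cls)]
        if values.shape != (len(names),):
            raise ConfigurationError(
                f"{cls.__name__}: expected {len(names)} coefficients, got shape {values.shape}"
            )
        return cls(**dict(zip(names, values.tolist())))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "_CoefficientSet":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    def validate(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"{type(self).__name__}: coefficients must be finite")


@dataclass
class EggModelCoefficients(_CoefficientSet):
    """Poisson (log link) model for the annual number of eggs."""

    intercept: float = 0.0
    b_experience: float = 0.0
    b_laying_date: float = 0.0
    b_prey_sm_prelay: float = 0.0
    b_prey_vole_prelay: float = 0.0

    TERMS = EGG_TERMS


@dataclass
class HatchModelCoefficients(_CoefficientSet):
    """Binomial (logit link) model for hatching success given eggs."""

    intercept: float = 0.0
    b_experience: float = 0.0
    b_eggs: float = 0.0
    b_laying_date: float = 0.0
    b_cond_incubation: float = 0.0
    b_prey_sm_incub: float = 0.0
    b_prey_vole_incub: float = 0.0

    TERMS = HATCH_TERMS


@dataclass
class FledgeModelCoefficients(_CoefficientSet):
    """Binomial (logit link) model for fledging success given nestlings."""

    intercept: float = 0.0
    b_experience: float = 0.0
    b_nestlings: float = 0.0
    b_laying_date: float = 0.0
    b_cond_rearing: float = 0.0
    b_prey_sm_rear: float = 0.0
    b_prey_vole_rear: float = 0.0

    TERMS = FLEDGE_TERMS


@dataclass
class SurvivalCoefficients(_CoefficientSet):
    """Logit-linear model for annual survival probability phi."""

    intercept: float = 0.0
    b_experience: float = 0.0
    b_cond_rearing: float = 0.0
    b_nestlings: float = 0.0
    b_fledglings: float = 0.0
    b_gc_baseline: float = 0.0
    b_gc_stress: float = 0.0
    b_spot: float = 0.0
    b_prey_sm_incub: float = 0.0
    b_prey_vole_incub: float = 0.0
    b_prey_sm_winter: float = 0.0
    b_prey_vole_winter: float = 0.0

    TERMS = SURVIVAL_TERMS


@dataclass
class DetectionParameters:
    """Group-specific recapture (p) and dead-recovery (r) probabilities.

    VHF-tagged birds emit a locator signal in a synchronized spring week, so
    both their live resighting and dead recovery are far more likely than for
    ring-only birds.
    """

    p_ring: float = 0.5
    p_vhf: float = 0.9
    r_ring: float = 0.15
    r_vhf: float = 0.7

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"DetectionParameters.{f.name} must lie in (0, 1), got {v}")

    def p(self, group: str) -> float:
        return self.p_ring if group == "ring" else self.p_vhf

    def r(self, group: str) -> float:
        return self.r_ring if group == "ring" else self.r_vhf

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParameters":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})


@dataclass
class ModelParameters:
    """Sex-specific coefficient sets for the four submodels plus detection."""

    egg: dict[str, EggModelCoefficients]
    hatch: dict[str, HatchModelCoefficients]
    fledge: dict[str, FledgeModelCoefficients]
    survival: dict[str, SurvivalCoefficients]
    detection: DetectionParameters

    def validate(self) -> None:
        for name in ("egg", "hatch", "fledge", "survival"):
            block = getattr(self, name)
            if set(block) != set(SEXES):
                raise ConfigurationError(f"ModelParameters.{name} must have keys {SEXES}")
            for c in block.values():
                c.validate()
        self.detection.validate()

    def submodels(self) -> Iterator[tuple[str, str, _CoefficientSet]]:
        for name in ("egg", "hatch", "fledge", "survival"):
            for sex in SEXES:
                yield name, sex, getattr(self, name)[sex]

    def to_dict(self) -> dict:
        return {
            "egg": {s: c.to_dict() for s, c in self.egg.items()},
            "hatch": {s: c.to_dict() for s, c in self.hatch.items()},
            "fledge": {s: c.to_dict() for s, c in self.fledge.items()},
            "survival": {s: c.to_dict() for s, c in self.survival.items()},
            "detection": self.detection.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            egg={s: EggModelCoefficients.from_dict(v) for s, v in d["egg"].items()},
            hatch={s: HatchModelCoefficients.from_dict(v) for s, v in d["hatch"].items()},
            fledge={s: FledgeModelCoefficients.from_dict(v) for s, v in d["fledge"].items()},
            survival={s: SurvivalCoefficients.from_dict(v) for s, v in d["survival"].items()},
            detection=DetectionParameters.from_dict(d["detection"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def zeros(cls) -> "ModelParameters":
        return cls(
            egg={s: EggModelCoefficients() for s in SEXES},
            hatch={s: HatchModelCoefficients() for s in SEXES},
            fledge={s: FledgeModelCoefficients() for s in SEXES},
            survival={s: SurvivalCoefficients() for s in SEXES},
            detection=DetectionParameters(),
        )
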