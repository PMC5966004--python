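"""Radiopharmaceutical registry: decay constants, lesion biokinetics, plans.

Clearance of a bone-seeking radiopharmaceutical from a lesion combines
radioactive decay with biological washout.  Both processes are first order,
so their decay constants add:

    lambda_eff = lambda_phys + lambda_bio,    lambda = ln(2) / T_half

equivalently  1/T_eff = 1/T_phys + 1/T_bio.  The registry couples each
radiopharmaceutical's physical half-life with its lesion-level biokinetics
(effective *or* biological half-life -- the other is derived -- and skeletal
uptake as a fraction of the injected activity) and the typical administered
activity, either absolute or per kilogram of body mass.

Half-lives are stored in days, the unit they are quoted in; the
``lambda_*_per_s`` properties expose canonical per-second rates for the
integration and extrapolation stages.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParameterError, ValidationError
from .units import LN2, rate_per_s_from_half_life_d

__all__ = [
    "RadionuclideSpec",
    "BiokineticParams",
    "TreatmentPlan",
    "RegistryEntry",
    "Registry",
    "effective_decay_constant",
    "effective_half_life",
    "biological_half_life_from_effective",
    "planned_activity",
    "load_default_registry",
]


def _check_half_life(value: float, name: str, allow_inf: bool = False) -> None:
    if value != value or value <= 0:  # NaN or non-positive
        raise ParameterError(f"{name} must be positive, got {value!r}")
    if not allow_inf and value == math.inf:
        raise ParameterError(f"{name} must be finite, got inf")


def effective_decay_constant(
    physical_half_life_d: float, biological_half_life_d: float
) -> float:
    """Effective decay constant, per day.

    Sum of the physical and biological decay constants.  The biological
    half-life may be infinite (no biological clearance), in which case the
    result equals the physical decay constant alone.
    """
    _check_half_life(physical_half_life_d, "physical_half_life_d")
    _check_half_life(biological_half_life_d, "biological_half_life_d", allow_inf=True)
    lam_phys = LN2 / physical_half_life_d
    lam_bio = 0.0 if biological_half_life_d == math.inf else LN2 / biological_half_life_d
    return lam_phys + lam_bio


def effective_half_life(
    physical_half_life_d: float, biological_half_life_d: float
) -> float:
    """Effective half-life in days: ln(2) over the summed decay constants."""
    return LN2 / effective_decay_constant(physical_half_life_d, biological_half_life_d)


def biological_half_life_from_effective(
    physical_half_life_d: float, effective_half_life_d: float
) -> float:
    """Invert the sum-of-decay-constants relation: 1/T_bio = 1/T_eff - 1/T_phys.

    Requires 0 < T_eff < T_phys; at T_eff == T_phys there is no finite
    biological half-life.
    """
    _check_half_life(physical_half_life_d, "physical_half_life_d")
    _check_half_life(effective_half_life_d, "effective_half_life_d")
    if effective_half_life_d >= physical_half_life_d:
        raise ParameterError(
            "effective half-life "
            f"({effective_half_life_d} d) must be shorter than the physical "
            f"half-life ({physical_half_life_d} d) for a finite biological half-life"
        )
    return 1.0 / (1.0 / effective_half_life_d - 1.0 / physical_half_life_d)


@dataclass(frozen=True)
class RadionuclideSpec:
    """A radionuclide and its physical half-life (days)."""

    name: str
    physical_half_life_d: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("radionuclide name must be non-empty")
        _check_half_life(self.physical_half_life_d, "physical_half_life_d")

    @property
    def lambda_phys_per_s(self) -> float:
        return rate_per_s_from_half_life_d(self.physical_half_life_d)


@dataclass(frozen=True)
class BiokineticParams:
    """Lesion-level kinetics of one radiopharmaceutical.

    Exactly one of the effective / biological half-life pair is supplied by
    the user (via :meth:`from_effective` or :meth:`from_biological`); the
    other is derived so the stored pair is always mutually consistent.
    ``bone_uptake_fraction`` is the fraction of the injected activity
    retained in the skeleton/lesions, in (0, 1].
    """

    effective_half_life_d: float
    biological_half_life_d: float  # math.inf means no biological clearance
    bone_uptake_fraction: float

    def __post_init__(self) -> None:
        _check_half_life(self.effective_half_life_d, "effective_half_life_d")
        _check_half_life(self.biological_half_life_d, "biological_half_life_d", allow_inf=True)
        u = self.bone_uptake_fraction
        if not (0.0 < u <= 1.0):
            raise ValidationError(f"bone_uptake_fraction must be in (0, 1], got {u!r}")

    @classmethod
    def from_effective(
        cls,
        physical_half_life_d: float,
        effective_half_life_d: float,
        bone_uptake_fraction: float,
    ) -> "BiokineticParams":
        _check_half_life(physical_half_life_d, "physical_half_life_d")
        _check_half_life(effective_half_life_d, "effective_half_life_d")
        if effective_half_life_d > physical_half_life_d * (1.0 + 1e-12):
            raise ValidationError(
                f"effective half-life ({effective_half_life_d} d) cannot exceed "
                f"the physical half-life ({physical_half_life_d} d)"
            )
        if math.isclose(effective_half_life_d, physical_half_life_d, rel_tol=1e-12):
            t_bio = math.inf
        else:
            t_bio = biological_half_life_from_effective(
                physical_half_life_d, effective_half_life_d
            )
        return cls(effective_half_life_d, t_bio, bone_uptake_fraction)

    @classmethod
    def from_biological(
        cls,
        physical_half_life_d: float,
        biological_half_life_d: float,
        bone_uptake_fraction: float,
    ) -> "BiokineticParams":
        t_eff = effective_half_life(physical_half_life_d, biological_half_life_d)
        return cls(t_eff, biological_half_life_d, bone_uptake_fraction)

    @property
    def lambda_eff_per_s(self) -> float:
        return rate_per_s_from_half_life_d(self.effective_half_life_d)

    @property
    def lambda_bio_per_s(self) -> float:
        return rate_per_s_from_half_life_d(self.biological_half_life_d)


@dataclass(frozen=True)
class TreatmentPlan:
    """Administered activity of a plan: absolute MBq or MBq per kg body mass."""

    radiopharmaceutical: str
    administered_MBq: float | None = None
    administered_MBq_per_kg: float | None = None

    def __post_init__(self) -> None:
        absolute, per_kg = self.administered_MBq, self.administered_MBq_per_kg
        if (absolute is None) == (per_kg is None):
            raise ValidationError(
                "exactly one of administered_MBq / administered_MBq_per_kg required"
            )
        value = absolute if absolute is not None else per_kg
        if not (value > 0 and math.isfinite(value)):
            raise ParameterError(f"administered activity must be positive, got {value!r}")

    @property
    def is_per_kg(self) -> bool:
        return self.administered_MBq_per_kg is not None


def planned_activity(plan: TreatmentPlan, patient_mass_kg: float | None = None) -> float:
    """Administered activity in MBq; per-kg plans require the patient mass."""
    if not plan.is_per_kg:
        return float(plan.administered_MBq)
    if patient_mass_kg is None:
        raise ParameterError(
            f"plan for {plan.radiopharmaceutical!r} is per-kg; patient mass required"
        )
    if not (patient_mass_kg > 0 and math.isfinite(patient_mass_kg)):
        raise ParameterError(f"patient mass must be positive, got {patient_mass_kg!r}")
    return float(plan.administered_MBq_per_kg) * float(patient_mass_kg)


@dataclass(frozen=True)
class RegistryEntry:
    """One radiopharmaceutical: nuclide physics + lesion biokinetics + plan."""

    name: str
    radionuclide: RadionuclideSpec
    kinetics: BiokineticParams
    plan: TreatmentPlan

    def __post_init__(self) -> None:
        if self.kinetics.effective_half_life_d > self.radionuclide.physical_half_life_d * (
            1.0 + 1e-9
        ):
            raise ValidationError(
                f"{self.name}: effective half-life exceeds the physical half-life"
            )

    # flat accessors, all in days / fractions
    @property
    def physical_half_life(self) -> float:
        return self.radionuclide.physical_half_life_d

    @property
    def effective_half_life(self) -> float:
        return self.kinetics.effective_half_life_d

    @property
    def biological_half_life(self) -> float:
        return self.kinetics.biological_half_life_d

    @property
    def bone_uptake_fraction(self) -> float:
        return self.kinetics.bone_uptake_fraction

    @property
    def lambda_eff_per_s(self) -> float:
        return self.kinetics.lambda_eff_per_s

    @property
    def lambda_phys_per_s(self) -> float:
        return self.radionuclide.lambda_phys_per_s

    def administered_activity(self, patient_mass_kg: float | None = None) -> float:
        return planned_activity(self.plan, patient_mass_kg)

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "radionuclide": self.radionuclide.name,
            "physical_half_life_d": self.radionuclide.physical_half_life_d,
            "effective_half_life_d": self.kinetics.effective_half_life_d,
            "bone_uptake_percent": self.kinetics.bone_uptake_fraction * 100.0,
        }
        if self.plan.is_per_kg:
            d["administered_activity_MBq_per_kg"] = self.plan.administered_MBq_per_kg
        else:
            d["administered_activity_MBq"] = self.plan.administered_MBq
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegistryEntry":
        name = d["name"]
        spec = RadionuclideSpec(d.get("radionuclide", name), d["physical_half_life_d"])
        has_eff = "effective_half_life_d" in d
        has_bio = "biological_half_life_d" in d
        if has_eff == has_bio:
            raise ValidationError(
                f"{name}: supply exactly one of effective_half_life_d / "
                "biological_half_life_d (the other is derived)"
            )
        uptake = float(d["bone_uptake_percent"]) / 100.0
        if has_eff:
            kinetics = BiokineticParams.from_effective(
                spec.physical_half_life_d, float(d["effective_half_life_d"]), uptake
            )
        else:
            kinetics = BiokineticParams.from_biological(
                spec.physical_half_life_d, float(d["biological_half_life_d"]), uptake
            )
        plan = TreatmentPlan(
            radiopharmaceutical=name,
            administered_MBq=d.get("administered_activity_MBq"),
            administered_MBq_per_kg=d.get("administered_activity_MBq_per_kg"),
        )
        return cls(name, spec, kinetics, plan)


class Registry(Mapping):
    """Ordered, name-keyed collection of :class:`RegistryEntry`."""

    def __init__(self, entries: list[RegistryEntry] | None = None) -> None:
        self._entries: dict[str, RegistryEntry] = {}
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: RegistryEntry) -> None:
        if entry.name in self._entries:
            raise ValidationError(f"duplicate registry entry {entry.name!r}")
        self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> RegistryEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def to_dict(self) -> dict:
        return {"radiopharmaceuticals": [e.to_dict() for e in self._entries.values()]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Registry":
        return cls([RegistryEntry.from_dict(e) for e in d["radiopharmaceuticals"]])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_default_registry() -> Registry:
    """Bundled registry of the seven bone-seeking radiopharmaceuticals.

    Physical and effective half-lives, skeletal uptake and typical
    administered activities are transcribed from the published treatment
    summary.  The delivered-plan entry (186Re-HEDP) needs two constants the
    summary does not print -- its lesion effective half-life and skeletal
    uptake; the bundled defaults (2.7 d, 30 %IA) are package choices and can
    be overridden by editing a saved copy of the registry.  Every pipeline
    manifest records the values actually used.
    """
    text = (resources.files("voxdose.data") / "registry.json").read_text()
    return Registry.from_dict(json.loads(text))
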