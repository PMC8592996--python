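"""Sex- and variant-specific anthropometry: parameter tables and scaling laws.

Three model variants are supported:

``male_base`` and ``female_base``
    the generic model, scaled only by stature and body mass; both share one
    PCSA table and one segment-mass table.
``female_specific``
    the base model with female muscle physiological cross-sectional areas
    (PCSAs), female segmental mass distribution, and a female BMI-based body
    fat estimate substituted in.

Muscle strength is ``PCSA x specific tension x strength scale`` where the
scale follows a length-mass-fat law: lean-mass ratio over stature ratio
relative to a configurable reference subject (exponents configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Any, Mapping

from .config import load_config

MUSCLES = (
    "multifidus",
    "erector_spinae",
    "quadratus_lumborum",
    "psoas_major",
    "internal_oblique",
    "external_oblique",
    "rectus_abdominis",
)
BACK_MUSCLES = ("multifidus", "erector_spinae", "quadratus_lumborum", "psoas_major")
OBLIQUES = ("internal_oblique", "external_oblique")

SEGMENTS = (
    "head",
    "thorax",
    "lumbar",
    "pelvis",
    "thighs",
    "shanks",
    "feet",
    "upper_arms",
    "lower_arms",
    "hands",
)

VARIANTS = ("male_base", "female_base", "female_specific")


def _variant_column(variant: str) -> str:
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {', '.join(VARIANTS)}"
        )
    return "female_specific" if variant == "female_specific" else "base"


@dataclass(frozen=True)
class SubjectProfile:
    """One participant: sex, stature (m), mass (kg), age (yr).

    ``bmi`` is derived; ``fat_fraction`` may be supplied (0-1) or left None to
    be estimated from BMI by the configured regression.
    """

    sex: str
    stature: float
    mass: float
    age: float = 30.0
    fat_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.stature > 0:
            raise ValueError("stature must be positive")
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        if self.fat_fraction is not None and not 0 <= self.fat_fraction < 1:
            raise ValueError("fat_fraction must lie in [0, 1)")

    @property
    def bmi(self) -> float:
        return self.mass / self.stature**2


@dataclass(frozen=True)
class MuscleParameterTable:
    """Per-muscle-group PCSA in cm^2 (per side unless stated otherwise)."""

    pcsa: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.pcsa) != set(MUSCLES):
            missing = set(MUSCLES) - set(self.pcsa)
            extra = set(self.pcsa) - set(MUSCLES)
            raise ValueError(
                f"PCSA table rows mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        for name, value in self.pcsa.items():
            if not value > 0:
                raise ValueError(f"PCSA of {name} must be positive, got {value}")

    def __getitem__(self, muscle: str) -> float:
        return self.pcsa[muscle]


@dataclass(frozen=True)
class SegmentMassTable:
    """Per-segment mass as a percentage of total body mass; sums to 100."""

    fraction_pct: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.fraction_pct) != set(SEGMENTS):
            missing = set(SEGMENTS) - set(self.fraction_pct)
            extra = set(self.fraction_pct) - set(SEGMENTS)
            raise ValueError(
                f"mass table rows mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        total = sum(self.fraction_pct.values())
        if abs(total - 100.0) > 0.05:
            raise ValueError(f"segment mass fractions sum to {total}, expected 100 +/- 0.05")
        for name, value in self.fraction_pct.items():
            if not value > 0:
                raise ValueError(f"mass fraction of {name} must be positive, got {value}")

    def __getitem__(self, segment: str) -> float:
        return self.fraction_pct[segment]


@dataclass(frozen=True)
class ParameterSet:
    """Everything variant-specific that personalizes the trunk model."""

    variant: str
    pcsa_table: MuscleParameterTable
    mass_table: SegmentMassTable
    specific_tension: float
    strength_scale: float = 1.0
    fat_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        if not self.specific_tension > 0:
            raise ValueError("specific_tension must be positive")


def load_pcsa_table(variant: str, config: Any = None) -> MuscleParameterTable:
    """Return the PCSA column for ``variant`` (base variants share one column)."""
    cfg = load_config(config, "parameters.yaml")
    column = _variant_column(variant)
    return MuscleParameterTable(pcsa=dict(cfg["pcsa_cm2"][column]))


def load_mass_distribution(variant: str, config: Any = None) -> SegmentMassTable:
    """Return the segment-mass-fraction column for ``variant``."""
    cfg = load_config(config, "parameters.yaml")
    column = _variant_column(variant)
    return SegmentMassTable(fraction_pct=dict(cfg["mass_fractions_pct"][column]))


def segment_masses(table: SegmentMassTable, body_mass: float) -> dict[str, float]:
    """Per-segment mass in kg: fraction/100 x body mass."""
    if body_mass < 0:
        raise ValueError("body_mass must be non-negative")
    return {seg: table[seg] / 100.0 * body_mass for seg in SEGMENTS}


def body_fat_fraction(
    bmi: float,
    coefficients: Mapping[str, float],
    bmi_window: tuple[float, float] = (15.0, 35.0),
) -> float:
    """Evaluate the configured linear BMI regression, clamped to [0, 0.75].

    A BMI outside the regression's validity window triggers a warning and a
    clamped evaluation at the window edge.
    """
    lo, hi = bmi_window
    if not lo <= bmi <= hi:
        warnings.warn(
            f"BMI {bmi:.1f} outside regression validity window [{lo}, {hi}]; clamping",
            stacklevel=2,
        )
        bmi = min(max(bmi, lo), hi)
    value = coefficients["slope"] * bmi + coefficients["intercept"]
    return min(max(value, 0.0), 0.75)


def lean_mass(subject: SubjectProfile, default_fat: float = 0.2) -> float:
    fat = subject.fat_fraction if subject.fat_fraction is not None else default_fat
    return subject.mass * (1.0 - fat)


def length_mass_fat_scale(
    subject: SubjectProfile,
    reference: SubjectProfile,
    lean_exponent: float = 1.0,
    stature_exponent: float = 1.0,
) -> float:
    """Length-mass-fat strength scale.

    scale = (lean mass ratio)^lean_exponent / (stature ratio)^stature_exponent,
    equal to 1 for the reference subject itself.
    """
    ref_lean = lean_mass(reference)
    sub_lean = lean_mass(subject)
    if ref_lean <= 0 or sub_lean <= 0:
        raise ValueError("lean mass must be positive for strength scaling")
    return (sub_lean / ref_lean) ** lean_exponent / (
        subject.stature / reference.stature
    ) ** stature_exponent


def muscle_strength(pcsa: float, specific_tension: float, scale: float) -> float:
    """Maximum force (N) = PCSA (cm^2) x specific tension (N/cm^2) x scale."""
    if pcsa < 0 or specific_tension < 0 or scale < 0:
        raise ValueError("pcsa, specific_tension and scale must be non-negative")
    return pcsa * specific_tension * scale


def make_parameter_set(
    variant: str, subject: SubjectProfile, config: Any = None
) -> ParameterSet:
    """Bundle tables and the subject's strength scale for one model variant.

    Base variants estimate body fat with the generic (male) regression;
    the female-specific variant substitutes the female regression, so that the
    fat percentage is one of the parameters the variant modifies.
    """
    cfg = load_config(config, "parameters.yaml")
    pcsa = load_pcsa_table(variant, cfg)
    mass = load_mass_distribution(variant, cfg)
    regression_sex = "female" if variant == "female_specific" else "male"
    if subject.fat_fraction is not None:
        fat = subject.fat_fraction
    else:
        fat = body_fat_fraction(
            subject.bmi,
            cfg["fat_regression"][regression_sex],
            tuple(cfg["fat_regression"]["bmi_window"]),
        )
    ref_cfg = cfg["reference_subject"]
    reference = SubjectProfile(
        sex=ref_cfg["sex"],
        stature=ref_cfg["stature"],
        mass=ref_cfg["mass"],
        age=ref_cfg["age"],
        fat_fraction=ref_cfg["fat_fraction"],
    )
    scale = length_mass_fat_scale(
        replace(subject, fat_fraction=fat),
        reference,
        lean_exponent=cfg["scaling"]["lean_exponent"],
        stature_exponent=cfg["scaling"]["stature_exponent"],
    )
    return ParameterSet(
        variant=variant,
        pcsa_table=pcsa,
        mass_table=mass,
        specific_tension=cfg["specific_tension"],
        strength_scale=scale,
        fat_fraction=fat,
    )


def oblique_pcsa_deficit_pct(config: Any = None) -> float:
    """Percent by which the base-model mean oblique PCSA falls short of the
    female-specific mean, relative to the base value."""
    base = load_pcsa_table("female_base", config)
    spec = load_pcsa_table("female_specific", config)
    base_mean = sum(base[m] for m in OBLIQUES) / len(OBLIQUES)
    spec_mean = sum(spec[m] for m in OBLIQUES) / len(OBLIQUES)
    return 100.0 * (spec_mean - base_mean) / base_mean


def back_pcsa_reduction_pct(config: Any = None) -> float:
    """Mean per-muscle percent reduction of the posterior muscle PCSAs
    (multifidus, erector spinae, quadratus lumborum) in the female-specific
    column relative to base."""
    base = load_pcsa_table("female_base", config)
    spec = load_pcsa_table("female_specific", config)
    muscles = ("multifidus", "erector_spinae", "quadratus_lumborum")
    return 100.0 * sum((base[m] - spec[m]) / base[m] for m in muscles) / len(muscles)
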