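"""Population-normalized hazard-ratio adjustment and the factored risk curve.

Published hazard ratios for AD risk factors come from heterogeneous studies
with different reference groups, so each factor's ratios are rescaled so
that the prevalence-weighted mean hazard ratio over its levels is exactly 1:

    HR_adj = HR / Σ_levels (HR_i · prevalence_i)

Selected adjusted ratios combine additively, m = Σ(HR_adj − 1) + 1, and the
genetic risk curve is multiplied by m (clipped at 1).  The additive rule is
a deliberate simplification — real risk factors confound rather than add —
and a multiplicative alternative is available behind a flag.

The registry stores only the raw hazard ratios and North-American
prevalences; adjusted values are always recomputed at full precision.  The
diet factor's published prevalences are label-corrected by default
(Mediterranean 26.9%, other 73.1%), the reading consistent with its
published adjusted values; ``strict_printed=True`` keeps the prevalences as
printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

from .errors import UnknownLevelError, ValidationError
from .risk_model import RiskCurve

__all__ = [
    "HazardLevel",
    "HazardFactor",
    "default_registry",
    "adjusted_hr",
    "select_adjusted",
    "combine_hazards",
    "factored_risk_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HazardLevel:
    """One phenotype level: label, raw hazard ratio, population prevalence."""

    label: str
    hazard_ratio: float
    prevalence: float

    def __post_init__(self) -> None:
        if not self.hazard_ratio > 0:
            raise ValidationError(
                f"hazard ratio for {self.label!r} must be positive, got {self.hazard_ratio!r}"
            )
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError(
                f"prevalence for {self.label!r} must be in [0, 1], got {self.prevalence!r}"
            )


@dataclass(frozen=True)
class HazardFactor:
    """A risk factor with mutually exclusive phenotype levels."""

    name: str
    levels: Tuple[HazardLevel, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValidationError(f"factor {self.name!r} needs at least one level")
        object.__setattr__(self, "levels", tuple(self.levels))
        total_prev = sum(lv.prevalence for lv in self.levels)
        # Published prevalences may undershoot 1 slightly (race sums to 0.98
        # as printed); they must never exceed it.
        if total_prev > 1.0 + 1e-6:
            raise ValidationError(
                f"factor {self.name!r} prevalences sum to {total_prev!r} > 1"
            )

    @property
    def normalizer(self) -> float:
        """Prevalence-weighted mean raw hazard ratio Σ(HR·prevalence)."""
        return sum(lv.hazard_ratio * lv.prevalence for lv in self.levels)

    def level(self, label: str) -> HazardLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise UnknownLevelError(
            f"unknown level {label!r} for factor {self.name!r}; "
            f"valid labels: {[lv.label for lv in self.levels]}"
        )

    def adjusted(self, label: str) -> float:
        return self.level(label).hazard_ratio / self.normalizer

    def adjusted_table(self) -> Dict[str, float]:
        norm = self.normalizer
        return {lv.label: lv.hazard_ratio / norm for lv in self.levels}


def default_registry(strict_printed: bool = False) -> Dict[str, HazardFactor]:
    """The built-in registry of published AD risk factors.

    TBI prevalences printed as "<1%" are encoded as 0.005 each with the
    No/Mild level at 0.99.  With ``strict_printed=True`` the diet prevalences
    stay as printed (Mediterranean 73.1%) instead of the label-corrected
    default.
    """
    if strict_printed:
        logger.warning(
            "strict-as-printed hazard registry: diet prevalences kept as "
            "printed (Mediterranean 73.1%), inconsistent with the published "
            "adjusted values"
        )
        diet = (
            HazardLevel("Mediterranean", 0.6, 0.731),
            HazardLevel("Other", 1.0, 0.269),
        )
    else:
        diet = (
            HazardLevel("Mediterranean", 0.6, 0.269),
            HazardLevel("Other", 1.0, 0.731),
        )
    factors = [
        HazardFactor(
            "race",
            (
                HazardLevel("White", 1.25, 0.63),
                HazardLevel("Black", 1.73, 0.14),
                HazardLevel("Hispanic", 1.29, 0.14),
                HazardLevel("Asian", 1.0, 0.06),
                HazardLevel("Aboriginal", 1.42, 0.01),
            ),
        ),
        HazardFactor(
            "t2dm",
            (
                HazardLevel("No T2DM", 1.0, 0.74),
                HazardLevel("T2DM", 1.62, 0.26),
            ),
        ),
        HazardFactor(
            "tbi",
            (
                HazardLevel("No/Mild TBI", 1.0, 0.99),
                HazardLevel("Moderate TBI", 2.3, 0.005),
                HazardLevel("Severe TBI", 4.5, 0.005),
            ),
        ),
        HazardFactor(
            "education",
            (
                HazardLevel("Secondary or greater", 1.0, 0.68),
                HazardLevel("Primary or less", 1.78, 0.32),
            ),
        ),
        HazardFactor(
            "exercise",
            (
                HazardLevel("None", 1.0, 0.257),
                HazardLevel("Some", 0.71, 0.358),
                HazardLevel("Regular", 0.63, 0.385),
            ),
        ),
        HazardFactor("diet", diet),
    ]
    return {f.name: f for f in factors}


def adjusted_hr(factor: HazardFactor, level_label: str) -> float:
    """Population-normalized hazard ratio HR / Σ(HR·prevalence) for one level."""
    return factor.adjusted(level_label)


def select_adjusted(
    registry: Mapping[str, HazardFactor], selection: Mapping[str, str]
) -> List[float]:
    """Adjusted ratios for a {factor_name: level_label} selection."""
    ratios = []
    for name, label in selection.items():
        if name not in registry:
            raise UnknownLevelError(
                f"unknown factor {name!r}; valid factors: {sorted(registry)}"
            )
        ratios.append(registry[name].adjusted(label))
    return ratios


def combine_hazards(
    selected: Iterable[float], *, multiplicative: bool = False
) -> float:
    """Combine adjusted hazard ratios into one risk multiplier.

    The default is the additive rule Σ(HR_adj − 1) + 1.  The multiplicative
    alternative ΠHR_adj is a non-default sensitivity option; neither models
    the confounding between real risk factors.  An empty selection yields
    the neutral multiplier 1.
    """
    ratios = list(selected)
    for r in ratios:
        if not r > 0:
            raise ValidationError(f"adjusted hazard ratios must be positive, got {r!r}")
    if not ratios:
        return 1.0
    if multiplicative:
        out = 1.0
        for r in ratios:
            out *= r
        return out
    return 1.0 + sum(r - 1.0 for r in ratios)


def factored_risk_curve(curve: RiskCurve, multiplier: float) -> RiskCurve:
    """Multiply a risk curve by a combined hazard multiplier, clipping at 1.

    Risks exceeding probability 1 after multiplication are clipped and a
    warning is logged naming the first clipped age.
    """
    if not multiplier > 0:
        raise ValidationError(f"hazard multiplier must be positive, got {multiplier!r}")
    risks = curve.risks * multiplier
    clipped = risks > 1.0
    if clipped.any():
        first_age = float(curve.ages[clipped.argmax()])
        logger.warning(
            "factored risk exceeds 1 from age %g; clipping to 1.0", first_age
        )
        risks = risks.clip(max=1.0)
    return RiskCurve(curve.ages, risks)
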