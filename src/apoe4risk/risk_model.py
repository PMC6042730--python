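"""Gompertz cumulative AD-risk curves and genotype-probability weighting.

Cumulative risk of AD onset by a given age is modelled per genotype as a
Gompertz sigmoid A·exp(−exp(−k·(age − x))) with asymptote A (lifetime risk),
rate k per year and location x near the mean onset age.  A subject's genetic
risk curve uses the probability-weighted average of the three parameter
triples (ΣA·P, Σk·P, Σx·P); curve mixing ΣP·curve_g is available behind a
flag for sensitivity analysis.

The sign convention is the rising form: risk increases with age towards the
asymptote A, matching the cumulative-risk interpretation (x is roughly the
age at which risk reaches A/e).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genetics import GENOTYPES, Genotype, GenotypeDistribution

__all__ = [
    "GompertzParams",
    "RiskCurve",
    "DEFAULT_GOMPERTZ_TABLE",
    "gompertz_risk",
    "genotype_weighted_params",
    "risk_curve",
    "lifetime_risk_weights",
]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters: lifetime risk A in (0, 1], rate k > 0 per year, location x in years."""

    lifetime_risk: float
    rate: float
    location: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lifetime_risk <= 1.0):
            raise ConfigurationError(
                f"lifetime risk must be in (0, 1], got {self.lifetime_risk!r}"
            )
        if not (np.isfinite(self.rate) and self.rate > 0.0):
            raise ConfigurationError(f"Gompertz rate must be positive, got {self.rate!r}")
        if not np.isfinite(self.location):
            raise ConfigurationError(f"Gompertz location must be finite, got {self.location!r}")


#: Published per-genotype fits of cumulative AD risk.
DEFAULT_GOMPERTZ_TABLE: Dict[Genotype, GompertzParams] = {
    Genotype.E4_HOMOZYGOTE: GompertzParams(0.9377, 0.137, 64.09),
    Genotype.E4_HETEROZYGOTE: GompertzParams(0.4962, 0.1295, 72.294),
    Genotype.E4_NONCARRIER: GompertzParams(0.225, 0.116, 80.92),
}


def gompertz_risk(
    age: Union[float, np.ndarray], params: GompertzParams
) -> Union[float, np.ndarray]:
    """Cumulative AD risk A·exp(−exp(−k·(age − x))) at ``age`` (scalar or array)."""
    a = np.asarray(age, dtype=float)
    with np.errstate(over="ignore"):  # far-below-location ages overflow the inner exp; the risk is 0
        out = params.lifetime_risk * np.exp(-np.exp(-params.rate * (a - params.location)))
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


@dataclass(frozen=True)
class RiskCurve:
    """Cumulative risk evaluated on a strictly increasing age grid."""

    ages: np.ndarray
    risks: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        risks = np.asarray(self.risks, dtype=float)
        if ages.ndim != 1 or ages.size == 0:
            raise ValidationError("age grid must be a non-empty 1-D array")
        if ages.size != risks.size:
            raise ValidationError("age grid and risk values differ in length")
        if np.any(np.diff(ages) <= 0):
            raise ValidationError("ages must be strictly increasing")
        if np.any(risks < -1e-12) or np.any(risks > 1.0 + 1e-12):
            raise ValidationError("risks must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "risks", risks)

    def __len__(self) -> int:
        return int(self.ages.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "risk": self.risks})


def genotype_weighted_params(
    dist: GenotypeDistribution,
    table: Dict[Genotype, GompertzParams] = DEFAULT_GOMPERTZ_TABLE,
) -> GompertzParams:
    """Probability-weighted average of the per-genotype Gompertz parameters.

    Averages the parameters, not the curves: each of A, k, x is the dot
    product of the genotype probabilities with the corresponding row of the
    parameter table.
    """
    p = dist.as_array()
    return GompertzParams(
        lifetime_risk=float(sum(p[g] * table[g].lifetime_risk for g in GENOTYPES)),
        rate=float(sum(p[g] * table[g].rate for g in GENOTYPES)),
        location=float(sum(p[g] * table[g].location for g in GENOTYPES)),
    )


def risk_curve(
    dist: GenotypeDistribution,
    ages: Sequence[float],
    table: Dict[Genotype, GompertzParams] = DEFAULT_GOMPERTZ_TABLE,
    *,
    mix_curves: bool = False,
) -> RiskCurve:
    """Genetic risk curve for a genotype distribution over an age grid.

    With ``mix_curves=False`` (default) the Gompertz parameters are
    probability-averaged first and a single curve evaluated; with
    ``mix_curves=True`` the three pure-genotype curves are evaluated and
    mixed pointwise, a variant exposed for sensitivity analysis only.
    """
    grid = np.asarray(ages, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("age grid must be a non-empty 1-D sequence")
    if mix_curves:
        p = dist.as_array()
        risks = sum(p[g] * gompertz_risk(grid, table[g]) for g in GENOTYPES)
    else:
        risks = gompertz_risk(grid, genotype_weighted_params(dist, table))
    return RiskCurve(grid, np.asarray(risks, dtype=float))


def lifetime_risk_weights(
    table: Dict[Genotype, GompertzParams] = DEFAULT_GOMPERTZ_TABLE,
) -> np.ndarray:
    """Per-genotype lifetime risks, for the likelihood-weighting variant."""
    return np.array([table[g].lifetime_risk for g in GENOTYPES], dtype=float)
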