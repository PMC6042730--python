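"""Single-individual Bayesian APOE ε4 genotype estimation from age of AD onset.

The model treats the age of onset of late-onset Alzheimer's disease as a
Gaussian whose mean depends on the APOE ε4 genotype (ε4 homozygotes tend to
convert earliest, non-carriers latest).  Combining that likelihood with
population genotype frequencies through Bayes' theorem yields a posterior
probability over the three genotype states given a single observed age of
onset.  An individual with no AD history contributes no likelihood and keeps
the prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigurationError, OnsetRangeError, ValidationError

__all__ = [
    "Genotype",
    "GENOTYPES",
    "GenotypeDistribution",
    "OnsetModel",
    "PopulationPriors",
    "DEFAULT_ONSET_MODEL",
    "DEFAULT_POPULATION_PRIORS",
    "DEFAULT_ONSET_RANGE",
    "onset_density",
    "marginal_onset_density",
    "genotype_posterior",
]

#: Ages of onset the estimator accepts by default, in years.
DEFAULT_ONSET_RANGE: Tuple[float, float] = (45.0, 95.0)

_SUM_TOL = 1e-9


class Genotype(IntEnum):
    """APOE ε4 genotype, ordered (+/+, +/-, -/-) in all vector representations."""

    E4_HOMOZYGOTE = 0
    E4_HETEROZYGOTE = 1
    E4_NONCARRIER = 2

    @property
    def label(self) -> str:
        return ("+/+", "+/-", "-/-")[self]

    @property
    def n_e4(self) -> int:
        """Number of ε4 copies carried."""
        return (2, 1, 0)[self]

    @property
    def transmission_probability(self) -> float:
        """Probability this genotype transmits an ε4 allele to a child."""
        return self.n_e4 / 2.0


GENOTYPES: Tuple[Genotype, ...] = tuple(Genotype)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probability distribution over the three APOE ε4 genotype states.

    Components are ordered (+/+, +/-, -/-), each in [0, 1], and must sum to
    one within 1e-9.  This is the currency passed between every stage of the
    pipeline: population priors, Mendelian offspring distributions and
    Bayesian posteriors are all instances of this type.
    """

    p_pp: float
    p_pm: float
    p_mm: float

    def __post_init__(self) -> None:
        comps = (self.p_pp, self.p_pm, self.p_mm)
        for c in comps:
            if not (np.isfinite(c) and -1e-12 <= c <= 1.0 + 1e-12):
                raise ValidationError(
                    f"genotype probability {c!r} outside [0, 1]"
                )
        total = sum(comps)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"genotype probabilities sum to {total!r}, expected 1 within {_SUM_TOL}"
            )

    @classmethod
    def from_array(cls, values: Sequence[float], normalize: bool = False) -> "GenotypeDistribution":
        a = np.asarray(values, dtype=float)
        if a.shape != (3,):
            raise ValidationError(f"expected 3 genotype probabilities, got shape {a.shape}")
        if normalize:
            total = a.sum()
            if total <= 0:
                raise ValidationError("cannot normalize non-positive probability vector")
            a = a / total
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.p_pp, self.p_pm, self.p_mm], dtype=float)

    def __getitem__(self, genotype: Genotype) -> float:
        return (self.p_pp, self.p_pm, self.p_mm)[Genotype(genotype)]

    @property
    def transmission_probability(self) -> float:
        """Probability a parent with this genotype distribution transmits ε4."""
        return self.p_pp + 0.5 * self.p_pm

    def almost_equal(self, other: "GenotypeDistribution", tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.as_array(), other.as_array(), atol=tol, rtol=0.0))

    def __str__(self) -> str:
        return (
            f"+/+ {self.p_pp:.3f}, +/- {self.p_pm:.3f}, -/- {self.p_mm:.3f}"
        )


@dataclass(frozen=True)
class OnsetModel:
    """Gaussian age-of-onset model: per-genotype mean and SD in years.

    Defaults are the published estimates: mean onset 68 for ε4 homozygotes,
    76 for heterozygotes, 84 for non-carriers, each with SD 8.2 years.
    """

    mean_onset_ages: Tuple[float, float, float] = (68.0, 76.0, 84.0)
    sds: Tuple[float, float, float] = (8.2, 8.2, 8.2)

    def __post_init__(self) -> None:
        if len(self.mean_onset_ages) != 3 or len(self.sds) != 3:
            raise ConfigurationError("onset model needs one mean and SD per genotype")
        for sd in self.sds:
            if not (np.isfinite(sd) and sd > 0):
                raise ConfigurationError(f"onset SD must be strictly positive, got {sd!r}")

    @property
    def means(self) -> np.ndarray:
        return np.asarray(self.mean_onset_ages, dtype=float)

    @property
    def sd_array(self) -> np.ndarray:
        return np.asarray(self.sds, dtype=float)


# The population prior is itself just a genotype distribution.
PopulationPriors = GenotypeDistribution

DEFAULT_ONSET_MODEL = OnsetModel()

#: Published North-American APOE ε4 genotype frequencies: 4.5% +/+, 9% +/-,
#: 86.5% -/-.  Note these are not at Hardy-Weinberg equilibrium for the
#: implied allele frequency of 9%.
DEFAULT_POPULATION_PRIORS = GenotypeDistribution(0.045, 0.09, 0.865)


def onset_density(
    age: float, genotype: Genotype, model: OnsetModel = DEFAULT_ONSET_MODEL
) -> float:
    """Gaussian density (per year) of AD onset at ``age`` for a genotype."""
    if not np.isfinite(age):
        raise ValidationError(f"age of onset must be finite, got {age!r}")
    g = Genotype(genotype)
    return float(stats.norm.pdf(age, loc=model.means[g], scale=model.sd_array[g]))


def _onset_densities(age: float, model: OnsetModel) -> np.ndarray:
    """Vector of the three per-genotype onset densities at ``age``."""
    return stats.norm.pdf(float(age), loc=model.means, scale=model.sd_array)


def marginal_onset_density(
    age: float,
    prior: GenotypeDistribution,
    model: OnsetModel = DEFAULT_ONSET_MODEL,
) -> float:
    """Prior-weighted mixture density of AD onset at ``age``.

    This is the normalizing constant of Bayes' theorem: the probability
    density of observing onset at ``age`` marginalized over genotype.
    """
    if not np.isfinite(age):
        raise ValidationError(f"age of onset must be finite, got {age!r}")
    return float(prior.as_array() @ _onset_densities(age, model))


def genotype_posterior(
    onset: Optional[float],
    prior: GenotypeDistribution = DEFAULT_POPULATION_PRIORS,
    model: OnsetModel = DEFAULT_ONSET_MODEL,
    *,
    weights: Optional[Sequence[float]] = None,
    onset_range: Optional[Tuple[float, float]] = DEFAULT_ONSET_RANGE,
) -> GenotypeDistribution:
    """Posterior genotype distribution given an age of AD onset.

    Parameters
    ----------
    onset
        Age of AD onset in years, or ``None`` for an individual with no AD
        history, in which case the prior is returned unchanged.
    prior
        Genotype distribution before observing the onset age.
    model
        Gaussian age-of-onset model.
    weights
        Optional per-genotype multiplicative likelihood weights.  Used by the
        lifetime-risk weighting variant, which scales each genotype's
        likelihood by its asymptotic lifetime risk; the default (``None``)
        uses the plain Gaussian likelihood.
    onset_range
        Inclusive (low, high) ages the estimator accepts, or ``None`` to
        accept any finite age.  Out-of-range onsets raise
        :class:`~apoe4risk.errors.OnsetRangeError` rather than being clamped.
    """
    if onset is None:
        return prior
    if not np.isfinite(onset):
        raise ValidationError(f"age of onset must be finite, got {onset!r}")
    if onset_range is not None:
        low, high = onset_range
        if not (low <= onset <= high):
            raise OnsetRangeError(
                f"age of onset {onset!r} outside the supported range [{low:g}, {high:g}]"
            )
    likelihood = _onset_densities(onset, model)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ConfigurationError(f"likelihood weights must be 3 non-negative finite values, got {weights!r}")
        likelihood = likelihood * w
    unnormalized = prior.as_array() * likelihood
    total = unnormalized.sum()
    if total <= 0.0 or not math.isfinite(total):
        raise ValidationError(
            "posterior is degenerate: prior support does not overlap the likelihood"
        )
    return GenotypeDistribution.from_array(unnormalized / total)
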