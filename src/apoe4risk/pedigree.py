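"""Mendelian combination and hierarchical propagation through a three-generation pedigree.

Information flows forward only, ancestors to descendants: each grandparent's
genotype posterior is computed from the population prior and their own age of
AD onset (if any); the two posteriors on each parental side are combined
through single-locus Mendelian transmission into that parent's prior; the
parent's own onset (if any) updates it; and the subject's prior is the
Mendelian combination of the two parental posteriors.  A person whose AD
status is unknown simply keeps their prior, so a missing ancestor is treated
exactly like an AD-free one: the population prior is substituted and the
combination rule is applied uniformly (no short-circuiting).

Note that the combination of two copies of the published population
frequencies is *not* numerically equal to those frequencies, because the
printed genotype frequencies are not at Hardy-Weinberg equilibrium; the
combined no-information prior for a child of two population-prior parents is
(0.0081, 0.1638, 0.8281).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Sequence, Tuple

from .errors import PedigreeStructureError, ValidationError
from .genetics import (
    DEFAULT_ONSET_MODEL,
    DEFAULT_ONSET_RANGE,
    DEFAULT_POPULATION_PRIORS,
    Genotype,
    GenotypeDistribution,
    OnsetModel,
    genotype_posterior,
)

__all__ = [
    "Role",
    "Person",
    "Pedigree",
    "mendelian_offspring_table",
    "offspring_prior",
    "estimate_pedigree",
]


class Role(str, Enum):
    """The seven fixed slots of the three-generation pedigree."""

    SUBJECT = "subject"
    FATHER = "father"
    MOTHER = "mother"
    PATERNAL_GRANDFATHER = "paternal_grandfather"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    MATERNAL_GRANDFATHER = "maternal_grandfather"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"


#: Grandparent slots feeding each parent.
PARENT_OF: Dict[Role, Tuple[Role, Role]] = {
    Role.FATHER: (Role.PATERNAL_GRANDFATHER, Role.PATERNAL_GRANDMOTHER),
    Role.MOTHER: (Role.MATERNAL_GRANDFATHER, Role.MATERNAL_GRANDMOTHER),
}


@dataclass(frozen=True)
class Person:
    """One pedigree member's AD phenotype record.

    ``onset_age`` is the age of AD onset and must be present iff ``had_ad``.
    ``age`` is the current age or age at death; it is carried for record
    keeping but plays no role in the genotype estimation.
    """

    role: Role
    had_ad: bool = False
    onset_age: Optional[float] = None
    age: Optional[float] = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.had_ad and self.onset_age is None:
            raise ValidationError(
                f"{self.role.value}: had_ad is true but onset_age is missing"
            )
        if not self.had_ad and self.onset_age is not None:
            raise ValidationError(
                f"{self.role.value}: onset_age given but had_ad is false"
            )
        if (
            self.onset_age is not None
            and self.age is not None
            and self.age < self.onset_age
        ):
            raise ValidationError(
                f"{self.role.value}: age {self.age!r} earlier than onset_age {self.onset_age!r}"
            )
        if not self.id:
            object.__setattr__(self, "id", self.role.value)


@dataclass(frozen=True)
class Pedigree:
    """Three-generation pedigree: subject, parents, four grandparents.

    Every member except the subject may be missing.  Each slot's person must
    carry the matching role.
    """

    subject: Person
    father: Optional[Person] = None
    mother: Optional[Person] = None
    paternal_grandfather: Optional[Person] = None
    paternal_grandmother: Optional[Person] = None
    maternal_grandfather: Optional[Person] = None
    maternal_grandmother: Optional[Person] = None

    def __post_init__(self) -> None:
        for role in Role:
            person = getattr(self, role.value)
            if role is Role.SUBJECT and person is None:
                raise PedigreeStructureError("subject is required")
            if person is not None and person.role is not role:
                raise PedigreeStructureError(
                    f"person with role {person.role.value!r} attached to the "
                    f"{role.value!r} slot"
                )

    def get(self, role: Role) -> Optional[Person]:
        return getattr(self, Role(role).value)

    def members(self) -> Dict[Role, Person]:
        """Present members keyed by role."""
        return {
            role: person
            for role in Role
            if (person := getattr(self, role.value)) is not None
        }


def mendelian_offspring_table(
    father_g: Genotype, mother_g: Genotype
) -> GenotypeDistribution:
    """Offspring genotype distribution for one parental genotype pair.

    Single-locus biallelic transmission: each parent passes an ε4 allele
    with probability 1, ½ or 0 for the +/+, +/- and -/- genotypes, giving
    e.g. (¼, ½, ¼) for two heterozygous parents.
    """
    tf = Genotype(father_g).transmission_probability
    tm = Genotype(mother_g).transmission_probability
    return GenotypeDistribution(
        tf * tm,
        tf * (1.0 - tm) + tm * (1.0 - tf),
        (1.0 - tf) * (1.0 - tm),
    )


def offspring_prior(
    father_dist: GenotypeDistribution, mother_dist: GenotypeDistribution
) -> GenotypeDistribution:
    """Offspring genotype distribution from two parental genotype distributions.

    Marginalizes the Mendelian transmission table over all nine parental
    genotype pairs.  Because transmission is independent per parent this
    collapses to a product of the two parental ε4-transmission probabilities
    t = P(+/+) + ½·P(+/-): the +/+ component is t_father · t_mother, the
    classic expansion used to seed each generation's prior.
    """
    for d in (father_dist, mother_dist):
        if not isinstance(d, GenotypeDistribution):
            raise ValidationError(f"expected a GenotypeDistribution, got {type(d).__name__}")
    tf = father_dist.transmission_probability
    tm = mother_dist.transmission_probability
    return GenotypeDistribution(
        tf * tm,
        tf * (1.0 - tm) + tm * (1.0 - tf),
        (1.0 - tf) * (1.0 - tm),
    )


def _person_posterior(
    person: Optional[Person],
    prior: GenotypeDistribution,
    model: OnsetModel,
    weights: Optional[Sequence[float]],
    onset_range: Optional[Tuple[float, float]],
) -> GenotypeDistribution:
    onset = person.onset_age if (person is not None and person.had_ad) else None
    return genotype_posterior(
        onset, prior, model, weights=weights, onset_range=onset_range
    )


def estimate_pedigree(
    ped: Pedigree,
    priors: GenotypeDistribution = DEFAULT_POPULATION_PRIORS,
    model: OnsetModel = DEFAULT_ONSET_MODEL,
    *,
    weights: Optional[Sequence[float]] = None,
    onset_range: Optional[Tuple[float, float]] = DEFAULT_ONSET_RANGE,
) -> Dict[Role, GenotypeDistribution]:
    """Hierarchical genotype estimation for every member of a pedigree.

    Returns the posterior genotype distribution for all seven roles.  Missing
    persons are assigned the population prior (grandparents) or the Mendelian
    combination of their own parents' posteriors (parents), exactly as if
    they were present with no AD history.
    """
    posteriors: Dict[Role, GenotypeDistribution] = {}

    for role in (
        Role.PATERNAL_GRANDFATHER,
        Role.PATERNAL_GRANDMOTHER,
        Role.MATERNAL_GRANDFATHER,
        Role.MATERNAL_GRANDMOTHER,
    ):
        posteriors[role] = _person_posterior(
            ped.get(role), priors, model, weights, onset_range
        )

    for parent_role, (gf_role, gm_role) in PARENT_OF.items():
        parent_prior = offspring_prior(posteriors[gf_role], posteriors[gm_role])
        posteriors[parent_role] = _person_posterior(
            ped.get(parent_role), parent_prior, model, weights, onset_range
        )

    subject_prior = offspring_prior(posteriors[Role.FATHER], posteriors[Role.MOTHER])
    posteriors[Role.SUBJECT] = _person_posterior(
        ped.subject, subject_prior, model, weights, onset_range
    )
    return posteriors
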