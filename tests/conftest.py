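"""Shared fixtures and independent scalar oracles.

The oracle functions here deliberately use only ``math`` and explicit
enumeration — no numpy, no scipy, and none of the package's own vector
code — so they stay independent of the implementation they check.
"""

import math

import pytest

from apoe4risk import (
    DEFAULT_ONSET_MODEL,
    DEFAULT_POPULATION_PRIORS,
    Pedigree,
    Person,
    Role,
)

MEANS = (68.0, 76.0, 84.0)
SDS = (8.2, 8.2, 8.2)
PRIORS = (0.045, 0.09, 0.865)


def gauss_pdf(x, mean, sd):
    return math.exp(-((x - mean) ** 2) / (2.0 * sd * sd)) / (sd * math.sqrt(2.0 * math.pi))


def bf_posterior(onset, prior, means=MEANS, sds=SDS, weights=None):
    """Brute-force normalized product of prior and Gaussian onset likelihood."""
    w = list(weights) if weights is not None else [1.0, 1.0, 1.0]
    unnorm = [p * gauss_pdf(onset, m, s) * wt for p, m, s, wt in zip(prior, means, sds, w)]
    total = sum(unnorm)
    return [u / total for u in unnorm]


# Offspring genotype distribution for each parental genotype pair, written
# out explicitly from Mendelian inheritance (0 = +/+, 1 = +/-, 2 = -/-).
MENDEL_PAIRS = {
    (0, 0): (1.0, 0.0, 0.0),
    (0, 1): (0.5, 0.5, 0.0),
    (0, 2): (0.0, 1.0, 0.0),
    (1, 1): (0.25, 0.5, 0.25),
    (1, 2): (0.0, 0.5, 0.5),
    (2, 2): (0.0, 0.0, 1.0),
}


def mendel_pair(fg, mg):
    return MENDEL_PAIRS[(fg, mg) if (fg, mg) in MENDEL_PAIRS else (mg, fg)]


def bf_offspring(father, mother):
    """Brute-force enumeration over all nine parental genotype pairs."""
    out = [0.0, 0.0, 0.0]
    for fg in range(3):
        for mg in range(3):
            pair = mendel_pair(fg, mg)
            weight = father[fg] * mother[mg]
            for k in range(3):
                out[k] += weight * pair[k]
    return out


@pytest.fixture
def model():
    return DEFAULT_ONSET_MODEL

@pytest.fixture
def priors():
    return DEFAULT_POPULATION_PRIORS


def make_person(role, onset=None, age=None):
    return Person(role=Role(role), had_ad=onset is not None, onset_age=onset, age=age)


@pytest.fixture
def worked_example_pedigree():
    """The packaged worked-example family: three affected across two generations."""
    return Pedigree(
        subject=make_person("subject", age=45),
        father=make_person("father", onset=64, age=75),
        mother=make_person("mother", onset=85, age=97),
        paternal_grandfather=make_person("paternal_grandfather", onset=82, age=87),
        paternal_grandmother=make_person("paternal_grandmother", age=75),
        maternal_grandfather=make_person("maternal_grandfather", age=79),
        maternal_grandmother=make_person("maternal_grandmother", onset=67, age=77),
    )
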