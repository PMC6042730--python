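"""Mendelian combination and hierarchical propagation through pedigrees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apoe4risk import (
    DEFAULT_POPULATION_PRIORS,
    Genotype,
    GenotypeDistribution,
    Pedigree,
    PedigreeStructureError,
    Person,
    Role,
    ValidationError,
    estimate_pedigree,
    genotype_posterior,
    mendelian_offspring_table,
    offspring_prior,
)

from conftest import PRIORS, bf_offspring, bf_posterior, make_person, mendel_pair


class TestMendelianTable:
    @pytest.mark.parametrize("fg", list(Genotype))
    @pytest.mark.parametrize("mg", list(Genotype))
    def test_all_nine_pairs_match_enumeration(self, fg, mg):
        got = mendelian_offspring_table(fg, mg).as_array()
        assert got == pytest.approx(mendel_pair(int(fg), int(mg)), abs=1e-15)

    def test_two_heterozygotes_give_quarter_half_quarter(self):
        got = mendelian_offspring_table(Genotype.E4_HETEROZYGOTE, Genotype.E4_HETEROZYGOTE)
        assert got.as_array() == pytest.approx([0.25, 0.5, 0.25], abs=0)

    def test_obligate_outcomes(self):
        hom = mendelian_offspring_table(Genotype.E4_HOMOZYGOTE, Genotype.E4_HOMOZYGOTE)
        assert hom.as_array() == pytest.approx([1.0, 0.0, 0.0], abs=0)
        het = mendelian_offspring_table(Genotype.E4_HOMOZYGOTE, Genotype.E4_NONCARRIER)
        assert het.as_array() == pytest.approx([0.0, 1.0, 0.0], abs=0)


class TestOffspringPrior:
    def test_hand_expanded_homozygote_component(self):
        father = GenotypeDistribution(0.01, 0.08, 0.91)
        mother = GenotypeDistribution(0.045, 0.09, 0.865)
        assert offspring_prior(father, mother).p_pp == pytest.approx(0.0045, abs=1e-12)

    def test_point_masses_reduce_to_mendelian_table(self):
        for fg in Genotype:
            for mg in Genotype:
                fd = GenotypeDistribution.from_array(np.eye(3)[fg])
                md = GenotypeDistribution.from_array(np.eye(3)[mg])
                assert offspring_prior(fd, md).almost_equal(
                    mendelian_offspring_table(fg, mg)
                )

    def test_matches_nine_pair_enumeration_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = rng.random(3) + 1e-3
            m = rng.random(3) + 1e-3
            fd = GenotypeDistribution.from_array(f / f.sum())
            md = GenotypeDistribution.from_array(m / m.sum())
            got = offspring_prior(fd, md).as_array()
            assert got == pytest.approx(bf_offspring(fd.as_array(), md.as_array()), abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        raw=st.tuples(*[st.floats(min_value=1e-3, max_value=1.0) for _ in range(6)])
    )
    def test_parental_symmetry(self, raw):
        f = raw[:3]
        m = raw[3:]
        fd = GenotypeDistribution.from_array([x / sum(f) for x in f])
        md = GenotypeDistribution.from_array([x / sum(m) for x in m])
        assert offspring_prior(fd, md).almost_equal(offspring_prior(md, fd))


class TestEstimatePedigree:
    def test_every_distribution_is_normalized(self, worked_example_pedigree):
        posts = estimate_pedigree(worked_example_pedigree)
        assert set(posts) == set(Role)
        for dist in posts.values():
            assert abs(sum(dist.as_array()) - 1.0) < 1e-9

    def test_no_ad_pedigree_matches_two_stage_combination(self):
        """With no AD anywhere the cascade is pure Mendelian combination of priors."""
        ped = Pedigree(
            subject=make_person("subject"),
            father=make_person("father"),
            mother=make_person("mother"),
            paternal_grandfather=make_person("paternal_grandfather"),
            paternal_grandmother=make_person("paternal_grandmother"),
            maternal_grandfather=make_person("maternal_grandfather"),
            maternal_grandmother=make_person("maternal_grandmother"),
        )
        posts = estimate_pedigree(ped)
        parent = bf_offspring(PRIORS, PRIORS)
        subject = bf_offspring(parent, parent)
        assert posts[Role.SUBJECT].as_array() == pytest.approx(subject, abs=1e-12)
        assert posts[Role.FATHER].as_array() == pytest.approx(parent, abs=1e-12)

    def test_subject_only_reduces_to_single_individual_update(self):
        """A lone subject's prior is the two-stage combination of the population prior."""
        ped = Pedigree(subject=make_person("subject", onset=67))
        posts = estimate_pedigree(ped)
        parent = bf_offspring(PRIORS, PRIORS)
        prior = GenotypeDistribution.from_array(bf_offspring(parent, parent))
        expected = genotype_posterior(67.0, prior)
        assert posts[Role.SUBJECT].almost_equal(expected, tol=1e-12)

    def test_missing_and_ad_free_ancestors_are_equivalent(self):
        with_gm = Pedigree(
            subject=make_person("subject", onset=70),
            father=make_person("father", onset=64),
            paternal_grandfather=make_person("paternal_grandfather", onset=82),
            paternal_grandmother=make_person("paternal_grandmother"),
        )
        without_gm = Pedigree(
            subject=make_person("subject", onset=70),
            father=make_person("father", onset=64),
            paternal_grandfather=make_person("paternal_grandfather", onset=82),
        )
        a = estimate_pedigree(with_gm)
        b = estimate_pedigree(without_gm)
        for role in Role:
            assert a[role].almost_equal(b[role], tol=1e-15)

    def test_worked_example_reproduces_published_table(self, worked_example_pedigree):
        posts = estimate_pedigree(worked_example_pedigree)
        published = {
            Role.PATERNAL_GRANDFATHER: (0.01, 0.08, 0.91),
            Role.PATERNAL_GRANDMOTHER: (0.04, 0.09, 0.87),
            Role.MATERNAL_GRANDFATHER: (0.04, 0.09, 0.87),
            Role.MATERNAL_GRANDMOTHER: (0.21, 0.26, 0.53),
            Role.FATHER: (0.03, 0.48, 0.49),
            Role.MOTHER: (0.00, 0.25, 0.75),
            Role.SUBJECT: (0.03, 0.33, 0.64),
        }
        for role, expected in published.items():
            assert posts[role].as_array() == pytest.approx(expected, abs=0.05), role

    def test_early_onset_ancestor_never_lowers_subject_homozygote_probability(self):
        rng = np.random.default_rng(11)
        ancestor_roles = [r for r in Role if r is not Role.SUBJECT]
        for _ in range(20):
            persons = {"subject": make_person(
                "subject", onset=float(rng.uniform(50, 90)) if rng.random() < 0.5 else None
            )}
            for role in ancestor_roles:
                u = rng.random()
                if u < 0.3:
                    continue  # missing
                onset = float(rng.uniform(50, 90)) if u < 0.65 else None
                persons[role.value] = make_person(role.value, onset=onset)
            ped = Pedigree(**persons)
            base = estimate_pedigree(ped)[Role.SUBJECT].p_pp
            for role in ancestor_roles:
                current = ped.get(role)
                if current is not None and current.had_ad:
                    continue
                modified = dict(persons)
                modified[role.value] = make_person(role.value, onset=50.0)
                boosted = estimate_pedigree(Pedigree(**modified))[Role.SUBJECT].p_pp
                assert boosted >= base - 1e-12, role


class TestStructuralValidation:
    def test_had_ad_requires_onset(self):
        with pytest.raises(ValidationError, match="father"):
            Person(role=Role.FATHER, had_ad=True)

    def test_age_before_onset_rejected(self):
        with pytest.raises(ValidationError):
            Person(role=Role.MOTHER, had_ad=True, onset_age=80.0, age=70.0)

    def test_person_in_wrong_slot_names_the_role(self):
        subject = Person(role=Role.SUBJECT)
        stray = Person(role=Role.MOTHER)
        with pytest.raises(PedigreeStructureError, match="father"):
            Pedigree(subject=subject, father=stray)

    def test_subject_required(self):
        with pytest.raises(TypeError):
            Pedigree()
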