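"""Seeded generative pedigree model for calibration and recovery experiments.

Founders (the four grandparents) are drawn from configurable genotype
frequencies; parents and subject inherit ε4 alleles by single-locus
Mendelian transmission; each person develops AD with a per-genotype lifetime
probability and, if affected, receives an age of onset from that genotype's
Gaussian, truncated by resampling to the estimator's valid range (or
untruncated when ``onset_truncation`` is ``None``).

Two study designs are supported:

* ``subject_only=False`` — full three-generation pedigrees with every
  member's phenotype observed.
* ``subject_only=True`` — the same generative process, but only the
  subject's phenotype is observed (the ancestors are recorded as missing).
  Marginally the subject's genotype follows the two-stage Mendelian
  combination of the founder frequencies, which is exactly the estimator's
  no-information subject prior, so with genotype-independent lifetime risk
  and untruncated onsets the estimator is the Bayes posterior of the
  generating model and must be calibrated up to Monte-Carlo error
  (see :func:`matched_singleton_config`).

Hazard-factor phenotypes are not simulated: no generative model links them
to onset, so the hazard code is tested analytically instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetics import (
    DEFAULT_ONSET_MODEL,
    DEFAULT_POPULATION_PRIORS,
    GENOTYPES,
    Genotype,
    GenotypeDistribution,
    OnsetModel,
)
from .pedigree import PARENT_OF, Pedigree, Person, Role, estimate_pedigree

__all__ = [
    "SimConfig",
    "matched_singleton_config",
    "simulate_pedigree",
    "simulate_pedigrees",
    "calibration_experiment",
    "recovery_experiment",
]

#: Published per-genotype lifetime risks (the Gompertz asymptotes).
DEFAULT_LIFETIME_RISK: Tuple[float, float, float] = (0.9377, 0.4962, 0.225)

_GRANDPARENTS = (
    Role.PATERNAL_GRANDFATHER,
    Role.PATERNAL_GRANDMOTHER,
    Role.MATERNAL_GRANDFATHER,
    Role.MATERNAL_GRANDMOTHER,
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the generative pedigree model."""

    n_pedigrees: int
    seed: int
    founder_frequencies: GenotypeDistribution = DEFAULT_POPULATION_PRIORS
    lifetime_risk: Tuple[float, float, float] = DEFAULT_LIFETIME_RISK
    onset_model: OnsetModel = DEFAULT_ONSET_MODEL
    onset_truncation: Optional[Tuple[float, float]] = (45.0, 95.0)
    subject_only: bool = False

    def __post_init__(self) -> None:
        if self.n_pedigrees < 1:
            raise ValidationError(f"n_pedigrees must be >= 1, got {self.n_pedigrees!r}")
        for r in self.lifetime_risk:
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"lifetime risk {r!r} outside [0, 1]")
        if self.onset_truncation is not None:
            low, high = self.onset_truncation
            if not low < high:
                raise ValidationError(
                    f"onset truncation bounds must be increasing, got {self.onset_truncation!r}"
                )


def matched_singleton_config(n_pedigrees: int = 10_000, seed: int = 1) -> SimConfig:
    """Config under which the estimator is exactly Bayes for the generator.

    Lifetime risk is equalized across genotypes (so AD status itself carries
    no genotype information, matching the estimator's treatment of AD-free
    individuals), onsets are untruncated Gaussians (the estimator's
    likelihood), and only the subject's phenotype is observed.
    """
    return SimConfig(
        n_pedigrees=n_pedigrees,
        seed=seed,
        lifetime_risk=(0.5, 0.5, 0.5),
        onset_truncation=None,
        subject_only=True,
    )


def _draw_genotype(rng: np.random.Generator, dist: GenotypeDistribution) -> Genotype:
    return Genotype(int(rng.choice(3, p=dist.as_array())))


def _child_genotype(
    rng: np.random.Generator, father: Genotype, mother: Genotype
) -> Genotype:
    n_e4 = int(rng.random() < father.transmission_probability) + int(
        rng.random() < mother.transmission_probability
    )
    return Genotype(2 - n_e4)


def _draw_onset(
    rng: np.random.Generator,
    genotype: Genotype,
    model: OnsetModel,
    truncation: Optional[Tuple[float, float]],
) -> float:
    mean = model.means[genotype]
    sd = model.sd_array[genotype]
    while True:
        onset = float(rng.normal(mean, sd))
        if truncation is None:
            return onset
        low, high = truncation
        if low <= onset <= high:
            return onset


def simulate_pedigree(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[Pedigree, Dict[Role, Genotype]]:
    """Simulate one pedigree and return it with the true genotypes per role."""
    truth: Dict[Role, Genotype] = {}
    for role in _GRANDPARENTS:
        truth[role] = _draw_genotype(rng, config.founder_frequencies)
    for parent_role, (gf, gm) in PARENT_OF.items():
        truth[parent_role] = _child_genotype(rng, truth[gf], truth[gm])
    truth[Role.SUBJECT] = _child_genotype(
        rng, truth[Role.FATHER], truth[Role.MOTHER]
    )

    observed = (Role.SUBJECT,) if config.subject_only else tuple(Role)
    persons: Dict[str, Person] = {}
    for role in observed:
        g = truth[role]
        had_ad = bool(rng.random() < config.lifetime_risk[g])
        onset = (
            _draw_onset(rng, g, config.onset_model, config.onset_truncation)
            if had_ad
            else None
        )
        persons[role.value] = Person(role=role, had_ad=had_ad, onset_age=onset)
    return Pedigree(**persons), truth


def simulate_pedigrees(config: SimConfig) -> List[Tuple[Pedigree, Dict[Role, Genotype]]]:
    """Simulate ``config.n_pedigrees`` pedigrees; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    return [simulate_pedigree(config, rng) for _ in range(config.n_pedigrees)]


def _subject_predictions(config: SimConfig) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 3) predicted subject posteriors and (n,) true subject genotypes."""
    onset_range = config.onset_truncation  # estimator accepts what the sim emits
    preds = np.empty((config.n_pedigrees, 3), dtype=float)
    truths = np.empty(config.n_pedigrees, dtype=int)
    for i, (ped, truth) in enumerate(simulate_pedigrees(config)):
        post = estimate_pedigree(
            ped,
            config.founder_frequencies,
            config.onset_model,
            onset_range=onset_range,
        )[Role.SUBJECT]
        preds[i] = post.as_array()
        truths[i] = int(truth[Role.SUBJECT])
    return preds, truths


def _decile_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile-based bin index per value; collapses duplicate edges."""
    edges = np.unique(np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1)))
    inner = edges[1:-1]
    if inner.size == 0:
        return np.zeros(values.size, dtype=int)
    return np.digitize(values, inner, right=True)


def calibration_experiment(config: SimConfig, n_bins: int = 10) -> pd.DataFrame:
    """Predicted-vs-empirical genotype frequency per decile of the prediction.

    For each genotype component, subjects are binned into deciles of the
    predicted probability; each occupied bin reports its count, mean
    predicted probability, empirical frequency of the true genotype and the
    calibration gap (predicted − empirical).
    """
    preds, truths = _subject_predictions(config)
    rows = []
    for g in GENOTYPES:
        p = preds[:, g]
        hit = (truths == int(g)).astype(float)
        bins = _decile_bins(p, n_bins)
        for b in np.unique(bins):
            mask = bins == b
            mean_pred = float(p[mask].mean())
            observed = float(hit[mask].mean())
            rows.append(
                {
                    "genotype": g.label,
                    "bin": int(b),
                    "n": int(mask.sum()),
                    "mean_predicted": mean_pred,
                    "observed_frequency": observed,
                    "gap": mean_pred - observed,
                }
            )
    return pd.DataFrame(rows)


def _stratum_row(
    name: str, pred_class: np.ndarray, true_class: np.ndarray
) -> Dict[str, object]:
    n = int(true_class.size)
    accuracy = float((pred_class == true_class).mean()) if n else float("nan")
    counts = np.bincount(true_class, minlength=3)
    baseline = float(counts.max() / n) if n else float("nan")
    het_true = true_class == int(Genotype.E4_HETEROZYGOTE)
    het_recall = (
        float((pred_class[het_true] == true_class[het_true]).mean())
        if het_true.any()
        else float("nan")
    )
    return {
        "stratum": name,
        "n": n,
        "accuracy": accuracy,
        "majority_baseline": baseline,
        "het_recall": het_recall,
    }


def recovery_experiment(config: SimConfig) -> pd.DataFrame:
    """Argmax-genotype recovery accuracy versus simulation truth.

    Rows stratify by the number of AD-affected relatives (non-subject
    members), plus an overall row and an early-onset row (subjects whose own
    onset precedes age 65).  Each row reports the argmax accuracy, the
    majority-class baseline of that stratum and the recall of heterozygote
    carriers.
    """
    onset_range = config.onset_truncation
    records = []
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_pedigrees):
        ped, truth = simulate_pedigree(config, rng)
        post = estimate_pedigree(
            ped,
            config.founder_frequencies,
            config.onset_model,
            onset_range=onset_range,
        )[Role.SUBJECT]
        n_affected = sum(
            1 for role, p in ped.members().items() if role is not Role.SUBJECT and p.had_ad
        )
        records.append(
            {
                "pred": int(np.argmax(post.as_array())),
                "true": int(truth[Role.SUBJECT]),
                "n_affected": n_affected,
                "subject_onset": ped.subject.onset_age,
            }
        )
    df = pd.DataFrame(records)
    rows = []
    for k in sorted(df["n_affected"].unique()):
        sub = df[df["n_affected"] == k]
        rows.append(
            _stratum_row(f"affected_relatives={k}", sub["pred"].to_numpy(), sub["true"].to_numpy())
        )
    early = df[df["subject_onset"].notna() & (df["subject_onset"] < 65.0)]
    rows.append(_stratum_row("early_onset_subject", early["pred"].to_numpy(), early["true"].to_numpy()))
    rows.append(_stratum_row("overall", df["pred"].to_numpy(), df["true"].to_numpy()))
    return pd.DataFrame(rows)
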