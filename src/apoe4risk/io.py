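"""Pedigree/constants file handling and the packaged example pedigree.

Pedigree files are JSON documents validated against a strict schema: persons
are keyed by the seven fixed roles, unknown keys are rejected, ``onset_age``
is required iff ``had_ad`` and must lie in [45, 95].  An optional ``factors``
block selects one level per hazard factor.  Schema errors are reported with
JSON-pointer-style paths.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import pandas as pd
import pydantic
from importlib import resources

from .errors import ValidationError
from .genetics import (
    Genotype,
    GenotypeDistribution,
    OnsetModel,
)
from .hazards import HazardFactor, HazardLevel, default_registry
from .pedigree import Pedigree, Person, Role
from .risk_model import GompertzParams, RiskCurve

__all__ = [
    "PersonRecord",
    "PedigreeDocument",
    "ConstantsDocument",
    "read_pedigree",
    "read_pedigree_document",
    "write_pedigree",
    "document_to_pedigree",
    "pedigree_to_document",
    "load_constants",
    "example_pedigree_document",
    "write_risk_table",
]

SCHEMA_VERSION = "1"

_ROLE_VALUES = tuple(r.value for r in Role)


class PersonRecord(pydantic.BaseModel):
    """One person's entry in a pedigree document."""

    model_config = pydantic.ConfigDict(extra="forbid")

    had_ad: bool = False
    onset_age: Optional[float] = pydantic.Field(default=None, ge=45.0, le=95.0)
    age: Optional[float] = pydantic.Field(default=None, ge=0.0, le=130.0)

    @pydantic.model_validator(mode="after")
    def _check_consistency(self) -> "PersonRecord":
        if self.had_ad and self.onset_age is None:
            raise ValueError("had_ad is true but onset_age is missing")
        if not self.had_ad and self.onset_age is not None:
            raise ValueError("onset_age given but had_ad is false")
        if self.onset_age is not None and self.age is not None and self.age < self.onset_age:
            raise ValueError("age is earlier than onset_age")
        return self


class PedigreeDocument(pydantic.BaseModel):
    """Validated on-disk form of a three-generation pedigree."""

    model_config = pydantic.ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    persons: Dict[str, PersonRecord]
    factors: Optional[Dict[str, str]] = None

    @pydantic.field_validator("persons")
    @classmethod
    def _check_roles(cls, v: Dict[str, PersonRecord]) -> Dict[str, PersonRecord]:
        unknown = sorted(set(v) - set(_ROLE_VALUES))
        if unknown:
            raise ValueError(
                f"unknown roles {unknown}; valid roles: {list(_ROLE_VALUES)}"
            )
        if Role.SUBJECT.value not in v:
            raise ValueError("subject is required")
        return v


def _format_pydantic_errors(exc: pydantic.ValidationError) -> str:
    lines = []
    for err in exc.errors():
        pointer = "/" + "/".join(str(part) for part in err["loc"])
        lines.append(f"{pointer}: {err['msg']}")
    return "; ".join(lines)


def document_to_pedigree(doc: PedigreeDocument) -> Pedigree:
    persons = {
        role: Person(
            role=Role(role),
            had_ad=rec.had_ad,
            onset_age=rec.onset_age,
            age=rec.age,
        )
        for role, rec in doc.persons.items()
    }
    return Pedigree(**persons)


def pedigree_to_document(
    ped: Pedigree, factors: Optional[Dict[str, str]] = None
) -> PedigreeDocument:
    persons = {
        role.value: PersonRecord(
            had_ad=person.had_ad, onset_age=person.onset_age, age=person.age
        )
        for role, person in ped.members().items()
    }
    return PedigreeDocument(persons=persons, factors=factors)


def _parse_document(text: str, source: str) -> PedigreeDocument:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{source}: not valid JSON ({exc})") from exc
    try:
        return PedigreeDocument.model_validate(payload)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"{source}: {_format_pydantic_errors(exc)}") from exc


def read_pedigree_document(path: Union[str, Path]) -> PedigreeDocument:
    path = Path(path)
    return _parse_document(path.read_text(), str(path))


def read_pedigree(path: Union[str, Path]) -> Pedigree:
    """Read and validate a pedigree JSON file."""
    return document_to_pedigree(read_pedigree_document(path))


def write_pedigree(
    path: Union[str, Path], ped: Pedigree, factors: Optional[Dict[str, str]] = None
) -> None:
    doc = pedigree_to_document(ped, factors)
    Path(path).write_text(
        json.dumps(doc.model_dump(exclude_none=True), indent=2, sort_keys=True) + "\n"
    )


def example_pedigree_document() -> PedigreeDocument:
    """The packaged worked-example pedigree (with its hazard-factor block)."""
    text = resources.files("apoe4risk.data").joinpath("example_pedigree.json").read_text()
    return _parse_document(text, "packaged example pedigree")


# ---------------------------------------------------------------------------
# Constants document


class OnsetModelDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    mean_onset_ages: Tuple[float, float, float] = (68.0, 76.0, 84.0)
    sds: Tuple[float, float, float] = (8.2, 8.2, 8.2)


class GompertzRow(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    lifetime_risk: float
    rate: float
    location: float


class HazardLevelDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    label: str
    hazard_ratio: float
    prevalence: float


class FeatureFlags(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    #: Weight each genotype's onset likelihood by its lifetime risk.
    lifetime_risk_weighting: bool = False
    #: Mix the three pure-genotype curves instead of averaging parameters.
    mix_curves: bool = False
    #: Keep the diet prevalences as printed instead of label-corrected.
    strict_printed_hazards: bool = False


_DEFAULT_GOMPERTZ_DOC = {
    "pp": GompertzRow(lifetime_risk=0.9377, rate=0.137, location=64.09),
    "pm": GompertzRow(lifetime_risk=0.4962, rate=0.1295, location=72.294),
    "mm": GompertzRow(lifetime_risk=0.225, rate=0.116, location=80.92),
}

_GENOTYPE_KEYS = {"pp": Genotype.E4_HOMOZYGOTE, "pm": Genotype.E4_HETEROZYGOTE, "mm": Genotype.E4_NONCARRIER}


class ConstantsDocument(pydantic.BaseModel):
    """All model constants plus feature flags, overridable from JSON."""

    model_config = pydantic.ConfigDict(extra="forbid")

    population_priors: Tuple[float, float, float] = (0.045, 0.09, 0.865)
    onset_model: OnsetModelDoc = OnsetModelDoc()
    gompertz: Dict[str, GompertzRow] = dict(_DEFAULT_GOMPERTZ_DOC)
    hazards: Optional[Dict[str, Tuple[HazardLevelDoc, ...]]] = None
    flags: FeatureFlags = FeatureFlags()

    @pydantic.field_validator("gompertz")
    @classmethod
    def _check_gompertz_keys(cls, v: Dict[str, GompertzRow]) -> Dict[str, GompertzRow]:
        if set(v) != set(_GENOTYPE_KEYS):
            raise ValueError(f"gompertz table needs exactly the keys {sorted(_GENOTYPE_KEYS)}")
        return v

    def priors(self) -> GenotypeDistribution:
        return GenotypeDistribution(*self.population_priors)

    def onset(self) -> OnsetModel:
        return OnsetModel(self.onset_model.mean_onset_ages, self.onset_model.sds)

    def gompertz_table(self) -> Dict[Genotype, GompertzParams]:
        return {
            _GENOTYPE_KEYS[key]: GompertzParams(row.lifetime_risk, row.rate, row.location)
            for key, row in self.gompertz.items()
        }

    def hazard_registry(self) -> Dict[str, HazardFactor]:
        if self.hazards is None:
            return default_registry(strict_printed=self.flags.strict_printed_hazards)
        return {
            name: HazardFactor(
                name,
                tuple(
                    HazardLevel(lv.label, lv.hazard_ratio, lv.prevalence)
                    for lv in levels
                ),
            )
            for name, levels in self.hazards.items()
        }


def load_constants(path: Optional[Union[str, Path]] = None) -> ConstantsDocument:
    """Load a constants JSON file, or the built-in defaults when ``path`` is None."""
    if path is None:
        return ConstantsDocument()
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return ConstantsDocument.model_validate(payload)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"{path}: {_format_pydantic_errors(exc)}") from exc


def write_risk_table(path: Union[str, Path], frame: pd.DataFrame) -> None:
    """Write a curve table as CSV with fixed headers and full precision."""
    frame.to_csv(path, index=False)
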