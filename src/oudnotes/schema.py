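"""Annotation schema and the class → DSM-5 criterion crosswalk.

The schema is a closed set of annotation classes (semantic labels assigned to
full sentences of a clinical note, e.g. ``opioid craving`` or ``psychiatric
condition``).  A subset of classes is *scoring*: each scoring class maps onto
one or more of the 11 DSM-5 diagnostic criteria for opioid use disorder (OUD),
or carries a category override (``OUD treatment`` forces the "severe"
classification).  The mapping is configuration, not code: it is loaded from a
YAML file so that an updated chart-review crosswalk can be dropped in without
touching the scorer.

The default crosswalk shipped with the package encodes the 27-class schema
(18 scoring, 12 with attributes) with a provisional one-criterion-per-class
mapping; it is clearly versioned as provisional in its ``version`` field.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "N_CRITERIA",
    "DSM5_CRITERIA",
    "SeverityCategory",
    "ClassCategory",
    "DSMCriterion",
    "AnnotationClass",
    "Crosswalk",
    "CrosswalkFormatError",
    "CrosswalkValidationError",
    "load_crosswalk",
    "default_crosswalk",
    "criteria_for",
    "force_severe_classes",
]

#: Number of DSM-5 diagnostic criteria for opioid use disorder.
N_CRITERIA = 11

#: Short labels for the 11 DSM-5 OUD criteria, keyed by criterion id.
DSM5_CRITERIA: dict[int, str] = {
    1: "taken in larger amounts or for longer than intended",
    2: "persistent desire or unsuccessful efforts to cut down",
    3: "great deal of time obtaining, using, or recovering",
    4: "craving",
    5: "failure to fulfil major role obligations",
    6: "continued use despite social or interpersonal problems",
    7: "important activities given up or reduced",
    8: "recurrent use in physically hazardous situations",
    9: "continued use despite physical or psychological problems",
    10: "tolerance",
    11: "withdrawal",
}


class CrosswalkFormatError(ValueError):
    """The crosswalk file could not be parsed at all (not valid YAML/shape)."""


class CrosswalkValidationError(ValueError):
    """The crosswalk parsed but violates a schema invariant."""


class SeverityCategory(str, enum.Enum):
    """DSM-5 OUD severity category derived from the criterion count."""

    none = "none"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ClassCategory(str, enum.Enum):
    """Thematic grouping of annotation classes in the schema."""

    opioid_misuse = "opioid_misuse"
    substance_use_nonopioid = "substance_use_nonopioid"
    contributing_factor = "contributing_factor"
    consequence = "consequence"
    lack_of_control = "lack_of_control"
    other = "other"


class DSMCriterion(BaseModel):
    """One of the 11 DSM-5 diagnostic criteria for OUD."""

    model_config = ConfigDict(frozen=True)

    id: int
    label: str

    @field_validator("id")
    @classmethod
    def _id_in_range(cls, v: int) -> int:
        if not 1 <= v <= N_CRITERIA:
            raise ValueError(f"criterion id {v} outside 1..{N_CRITERIA}")
        return v


def dsm5_criteria() -> list[DSMCriterion]:
    """The canonical list of the 11 DSM-5 OUD criteria."""
    return [DSMCriterion(id=i, label=lab) for i, lab in DSM5_CRITERIA.items()]


class AnnotationClass(BaseModel):
    """A sentence-level annotation class and its scoring behaviour.

    Parameters
    ----------
    name
        Unique class identifier, e.g. ``"opioid craving"``.
    category
        Thematic grouping within the schema.
    scoring
        Whether the class contributes to the severity score.  A scoring class
        must either map to at least one criterion or force a category.
    attributes
        Declared attributes and their allowed values, e.g.
        ``{"temporality": ["current", "historic"]}``.
    criteria
        DSM-5 criterion ids (1-11) endorsed when the class is annotated.
    criteria_require
        Optional attribute restriction: the criteria are endorsed only when
        each listed attribute of the annotation takes one of the allowed
        values (an annotation missing the attribute still endorses; the
        restriction narrows, it does not demand).
    force_category
        Severity category override triggered by the class regardless of the
        criterion count (e.g. documented OUD treatment ⇒ severe).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    category: ClassCategory
    scoring: bool = False
    attributes: dict[str, tuple[str, ...]] = {}
    criteria: frozenset[int] = frozenset()
    criteria_require: dict[str, tuple[str, ...]] = {}
    force_category: Optional[SeverityCategory] = None

    @field_validator("criteria")
    @classmethod
    def _criteria_in_range(cls, v: frozenset[int]) -> frozenset[int]:
        bad = sorted(c for c in v if not 1 <= c <= N_CRITERIA)
        if bad:
            raise ValueError(f"criterion ids {bad} outside 1..{N_CRITERIA}")
        return v

    @field_validator("attributes", "criteria_require")
    @classmethod
    def _value_sets_nonempty(cls, v: dict[str, tuple[str, ...]]) -> dict:
        for attr, values in v.items():
            if len(values) == 0:
                raise ValueError(f"attribute {attr!r} declares an empty value set")
        return v

    @model_validator(mode="after")
    def _scoring_consistent(self) -> "AnnotationClass":
        has_effect = bool(self.criteria) or self.force_category is not None
        if self.scoring != has_effect:
            raise ValueError(
                f"class {self.name!r}: scoring={self.scoring} inconsistent with "
                f"criteria={sorted(self.criteria)} / force_category={self.force_category}"
            )
        return self

    def endorsed_criteria(self, attributes: Mapping[str, str] | None = None) -> frozenset[int]:
        """Criteria endorsed by one annotation of this class.

        Attribute restrictions (``criteria_require``) veto endorsement when
        the annotation carries a restricted attribute with a disallowed value.
        """
        if self.criteria_require and attributes:
            for attr, allowed in self.criteria_require.items():
                if attr in attributes and attributes[attr] not in allowed:
                    return frozenset()
        return self.criteria


class Crosswalk(BaseModel):
    """A validated annotation schema plus class → criterion mapping."""

    model_config = ConfigDict(frozen=True)

    version: str = "unversioned"
    classes: tuple[AnnotationClass, ...]
    expected_counts: Optional[dict[str, int]] = None

    @model_validator(mode="after")
    def _validate(self) -> "Crosswalk":
        names = [c.name for c in self.classes]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValueError(f"duplicate class names: {dupes}")
        if self.expected_counts is not None:
            got = {
                "total_classes": len(self.classes),
                "scoring_classes": sum(c.scoring for c in self.classes),
                "attributed_classes": sum(bool(c.attributes) for c in self.classes),
            }
            for key, expected in self.expected_counts.items():
                if key not in got:
                    raise ValueError(f"unknown expected_counts key {key!r}")
                if got[key] != expected:
                    raise ValueError(
                        f"expected_counts mismatch: {key} is {got[key]}, config declares {expected}"
                    )
        return self

    # -- lookups -----------------------------------------------------------

    def __getitem__(self, name: str) -> AnnotationClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(f"unknown annotation class {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.classes)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    @property
    def scoring_classes(self) -> tuple[AnnotationClass, ...]:
        return tuple(c for c in self.classes if c.scoring)

    def covered_criteria(self) -> frozenset[int]:
        """Union of criteria reachable through any scoring class."""
        out: set[int] = set()
        for c in self.scoring_classes:
            out |= c.criteria
        return frozenset(out)

    def classes_for_criterion(self, criterion: int) -> tuple[AnnotationClass, ...]:
        return tuple(c for c in self.scoring_classes if criterion in c.criteria)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"version": self.version}
        if self.expected_counts is not None:
            out["expected_counts"] = dict(self.expected_counts)
        out["classes"] = []
        for c in self.classes:
            entry: dict = {"name": c.name, "category": c.category.value, "scoring": c.scoring}
            if c.attributes:
                entry["attributes"] = {a: list(v) for a, v in c.attributes.items()}
            if c.criteria:
                entry["criteria"] = sorted(c.criteria)
            if c.criteria_require:
                entry["criteria_require"] = {a: list(v) for a, v in c.criteria_require.items()}
            if c.force_category is not None:
                entry["force_category"] = c.force_category.value
            out["classes"].append(entry)
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")


def _crosswalk_from_dict(raw: object, source: str) -> Crosswalk:
    if not isinstance(raw, dict) or "classes" not in raw:
        raise CrosswalkFormatError(
            f"{source}: crosswalk config must be a mapping with a 'classes' list"
        )
    try:
        return Crosswalk.model_validate(raw)
    except (ValueError, TypeError) as exc:  # pydantic ValidationError is a ValueError
        raise CrosswalkValidationError(f"{source}: {exc}") from exc


def load_crosswalk(path: str | Path) -> Crosswalk:
    """Load and validate a crosswalk YAML file.

    Raises
    ------
    CrosswalkFormatError
        If the file is not parseable YAML of the expected shape.
    CrosswalkValidationError
        If an invariant fails (duplicate class, out-of-range criterion id,
        scoring class with neither criteria nor a forced category, declared
        expected counts that do not match).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise CrosswalkFormatError(f"{path}: not valid YAML: {exc}") from exc
    return _crosswalk_from_dict(raw, str(path))


def default_crosswalk() -> Crosswalk:
    """The crosswalk shipped with the package (27 classes, 18 scoring)."""
    text = resources.files("oudnotes.data").joinpath("crosswalk.yaml").read_text("utf-8")
    return _crosswalk_from_dict(yaml.safe_load(text), "oudnotes/data/crosswalk.yaml")


def criteria_for(
    classes: Iterable[str],
    crosswalk: Crosswalk,
    attributes_by_class: Mapping[str, Mapping[str, str]] | None = None,
) -> frozenset[int]:
    """Union of DSM-5 criteria endorsed by a set of annotated classes.

    ``attributes_by_class`` optionally supplies one attribute assignment per
    class, applied through any ``criteria_require`` restrictions declared in
    the crosswalk.  Unknown class names raise ``KeyError``.
    """
    out: set[int] = set()
    for name in classes:
        cls = crosswalk[name]
        attrs = attributes_by_class.get(name) if attributes_by_class else None
        out |= cls.endorsed_criteria(attrs)
    return frozenset(out)


def force_severe_classes(crosswalk: Crosswalk) -> frozenset[str]:
    """Names of classes whose presence forces the 'severe' classification."""
    return frozenset(
        c.name for c in crosswalk.classes if c.force_category is SeverityCategory.severe
    )
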