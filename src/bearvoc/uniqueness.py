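"""Presence-absence compound-uniqueness classification.

Compounds are classified within a *treatment* (a named grouping of samples
into conditions, e.g. treatment "sex" with conditions female/male) from
their raw detection pattern:

* ``unique`` — detected in 100% of samples of exactly one condition and in
  no sample of any other condition;
* ``signature_dominant`` — detected in 100% of samples of exactly one
  condition, with partial presence elsewhere;
* ``dominant`` — detected in 100% of samples of more than one condition;
* ``not_classified`` — no condition at 100% (excluded by the inclusion
  rule).

The 100% test is exact integer arithmetic (detected count equals condition
size), never floating-point equality.  Dominant takes precedence over
signature-dominant, making the categories disjoint.  Classification sees
raw detections only: pseudo-counts introduced by zero replacement never
count as presence.
"""

from __future__ import annotations

import enum
from collections.abc import Callable
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .datatypes import CompoundID, PeakTable, SampleMetadata, Sex

__all__ = [
    "Category",
    "TreatmentSpec",
    "PresenceTable",
    "UniquenessCall",
    "build_treatments",
    "presence_fractions",
    "classify_uniqueness",
    "uniqueness_report",
]


class Category(str, enum.Enum):
    UNIQUE = "unique"
    SIGNATURE_DOMINANT = "signature_dominant"
    DOMINANT = "dominant"
    NOT_CLASSIFIED = "not_classified"


@dataclass
class TreatmentSpec:
    """A named grouping design mapping samples to conditions.

    Non-individual treatments must satisfy the outlier control that every
    condition contains samples from at least two individuals
    (``require_multi_individual``); the individual treatment waives it.
    """

    name: str
    condition_of: Callable[[SampleMetadata], str]
    sample_filter: Callable[[SampleMetadata], bool] | None = None
    exclusions: tuple[str, ...] = ()
    require_multi_individual: bool = True

    def select(self, metadata: list[SampleMetadata]) -> list[SampleMetadata]:
        out = [
            m for m in metadata
            if m.individual_id not in self.exclusions
            and (self.sample_filter is None or self.sample_filter(m))
        ]
        return out

    def conditions(self, metadata: list[SampleMetadata]) -> dict[str, list[str]]:
        """Condition -> sample IDs, validating the design constraints."""
        selected = self.select(metadata)
        groups: dict[str, list[str]] = {}
        individuals: dict[str, set[str]] = {}
        for m in selected:
            cond = self.condition_of(m)
            groups.setdefault(cond, []).append(m.sample_id)
            individuals.setdefault(cond, set()).add(m.individual_id)
        if len(groups) < 2:
            raise ValueError(
                f"treatment {self.name!r} has {len(groups)} condition(s); need >= 2"
            )
        if self.require_multi_individual:
            bad = [c for c, inds in individuals.items() if len(inds) < 2]
            if bad:
                raise ValueError(
                    f"treatment {self.name!r}: condition(s) {bad} contain "
                    "samples from < 2 individuals"
                )
        return groups


def build_treatments(
    metadata: list[SampleMetadata],
    individual_exclusions: tuple[str, ...] = ("Y744",),
) -> dict[str, TreatmentSpec]:
    """The nine standard treatments plus validation against the metadata.

    sex; age class; age class within each sex; body site within each sex;
    age class x body site within each sex; and the individual treatment
    (one condition per bear, with configured exclusions such as a bear with
    an incomplete series).
    """
    def is_f(m: SampleMetadata) -> bool:
        return m.sex is Sex.F

    def is_m(m: SampleMetadata) -> bool:
        return m.sex is Sex.M

    specs = {
        "sex": TreatmentSpec("sex", lambda m: m.sex.value),
        "age_class": TreatmentSpec("age_class", lambda m: m.age_class.value),
        "female_age_class": TreatmentSpec(
            "female_age_class", lambda m: m.age_class.value, is_f),
        "male_age_class": TreatmentSpec(
            "male_age_class", lambda m: m.age_class.value, is_m),
        "female_body_site": TreatmentSpec(
            "female_body_site", lambda m: m.body_site.value, is_f),
        "male_body_site": TreatmentSpec(
            "male_body_site", lambda m: m.body_site.value, is_m),
        "female_age_site": TreatmentSpec(
            "female_age_site",
            lambda m: f"{m.age_class.value}; {m.body_site.value}", is_f),
        "male_age_site": TreatmentSpec(
            "male_age_site",
            lambda m: f"{m.age_class.value}; {m.body_site.value}", is_m),
        "individual": TreatmentSpec(
            "individual", lambda m: m.individual_id,
            exclusions=individual_exclusions, require_multi_individual=False),
    }
    for spec in specs.values():
        spec.conditions(metadata)  # raises on invalid designs
    return specs


@dataclass
class PresenceTable:
    """Exact per-condition detection counts for one treatment."""

    treatment: str
    compounds: list[CompoundID]
    conditions: list[str]
    counts: np.ndarray  # n_compounds x n_conditions, integer detections
    sizes: np.ndarray  # samples per condition

    def fraction(self, compound_idx: int, condition: str) -> Fraction:
        j = self.conditions.index(condition)
        return Fraction(int(self.counts[compound_idx, j]), int(self.sizes[j]))

    def fractions_of(self, compound_idx: int) -> dict[str, Fraction]:
        return {c: self.fraction(compound_idx, c) for c in self.conditions}


def presence_fractions(
    detection: PeakTable | np.ndarray,
    treatment: TreatmentSpec,
    metadata: list[SampleMetadata],
    sample_ids: list[str] | None = None,
    compounds: list[CompoundID] | None = None,
) -> PresenceTable:
    """Detection counts per condition from the raw presence pattern.

    ``detection`` is a peak table (positive entries define presence — use
    a pre-zero-replacement stage) or a boolean compounds x samples matrix
    with ``sample_ids``/``compounds`` given.
    """
    if isinstance(detection, PeakTable):
        sample_ids = list(detection.samples)
        compounds = list(detection.compounds)
        detection = detection.values > 0
    if sample_ids is None or compounds is None:
        raise ValueError("sample_ids and compounds required with a bare matrix")
    det = np.asarray(detection, dtype=bool)
    col = {s: i for i, s in enumerate(sample_ids)}
    groups = treatment.conditions(metadata)
    conditions = sorted(groups)
    counts = np.zeros((det.shape[0], len(conditions)), dtype=int)
    sizes = np.zeros(len(conditions), dtype=int)
    for j, cond in enumerate(conditions):
        members = [col[s] for s in groups[cond] if s in col]
        if not members:
            raise ValueError(f"condition {cond!r} has no samples in the table")
        counts[:, j] = det[:, members].sum(axis=1)
        sizes[j] = len(members)
    return PresenceTable(treatment.name, compounds, conditions, counts, sizes)


@dataclass
class UniquenessCall:
    compound: CompoundID
    treatment: str
    category: Category
    anchor_conditions: list[str]
    presence_fraction: dict[str, Fraction] = field(default_factory=dict)


def classify_uniqueness(presence: PresenceTable) -> list[UniquenessCall]:
    """Classify every compound of a presence table into the four categories."""
    calls: list[UniquenessCall] = []
    for i, compound in enumerate(presence.compounds):
        counts = presence.counts[i]
        anchors = [c for j, c in enumerate(presence.conditions)
                   if counts[j] == presence.sizes[j]]
        detected_elsewhere = any(
            counts[j] > 0
            for j, c in enumerate(presence.conditions)
            if c not in anchors
        )
        if not anchors:
            category = Category.NOT_CLASSIFIED
        elif len(anchors) >= 2:
            category = Category.DOMINANT
        elif detected_elsewhere:
            category = Category.SIGNATURE_DOMINANT
        else:
            category = Category.UNIQUE
        calls.append(
            UniquenessCall(
                compound=compound,
                treatment=presence.treatment,
                category=category,
                anchor_conditions=anchors,
                presence_fraction=presence.fractions_of(i),
            )
        )
    return calls


def uniqueness_report(
    calls: list[UniquenessCall], treatment: TreatmentSpec | str
) -> pd.DataFrame:
    """Category totals and per-condition anchor counts for one treatment.

    One row per (category, condition) plus a total row per category; the
    per-category totals over classified compounds partition the classified
    set.
    """
    name = treatment.name if isinstance(treatment, TreatmentSpec) else str(treatment)
    conditions = sorted({c for call in calls for c in call.presence_fraction})
    rows = []
    for cat in (Category.UNIQUE, Category.SIGNATURE_DOMINANT, Category.DOMINANT):
        in_cat = [c for c in calls if c.category is cat]
        row = {"treatment": name, "category": cat.value, "n_compounds": len(in_cat)}
        for cond in conditions:
            row[f"anchored_{cond}"] = sum(
                1 for c in in_cat if cond in c.anchor_conditions
            )
        rows.append(row)
    n_not = sum(1 for c in calls if c.category is Category.NOT_CLASSIFIED)
    rows.append({"treatment": name, "category": Category.NOT_CLASSIFIED.value,
                 "n_compounds": n_not})
    return pd.DataFrame(rows).fillna(0)
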