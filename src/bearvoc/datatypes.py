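"""Core domain types for aligned GC-MS peak-table analysis.

The central object is the :class:`PeakTable`, a compounds x samples matrix of
non-negative peak abundances carrying a processing-stage tag, together with
per-sample biological metadata (:class:`SampleMetadata`).  Compounds are
identified by ``mass@retention-time`` labels as produced by peak-alignment
software; a few may additionally carry a putative library name.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "Sex",
    "AgeClass",
    "BodySite",
    "CompoundID",
    "PeakTable",
    "SampleMetadata",
    "Dataset",
    "derive_age_class",
    "validate_dataset",
    "metadata_frame",
]

AGE_CLASS_BOUNDARY_YEARS = 10


class Stage(str, enum.Enum):
    """Processing stage of a peak table."""

    RAW = "raw"
    ZERO_REPLACED = "zero_replaced"
    RELATIVE = "relative"
    TRANSFORMED = "transformed"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class AgeClass(str, enum.Enum):
    YOUNG = "young"
    MATURE = "mature"


class BodySite(str, enum.Enum):
    CHEEK = "cheek"
    FLANK = "flank"
    HUMP = "hump"
    PEDES = "pedes"


_LABEL_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*@\s*([0-9]+(?:\.[0-9]+)?)\s*$")


@dataclass(frozen=True)
class CompoundID:
    """A compound label of the form ``<nominal mass>@<retention minutes>``.

    The label is treated as an opaque identifier throughout the pipeline;
    mass and retention time are parsed for validation only, never for
    matching or merging.
    """

    label: str
    putative_name: str | None = None

    def __post_init__(self) -> None:
        m = _LABEL_RE.match(self.label)
        if m is None:
            raise ValueError(
                f"compound label {self.label!r} does not parse as "
                "'<mass>@<retention time>'"
            )
        if float(m.group(2)) < 0:
            raise ValueError(f"negative retention time in {self.label!r}")

    @property
    def mass(self) -> float:
        return float(_LABEL_RE.match(self.label).group(1))

    @property
    def retention_time(self) -> float:
        return float(_LABEL_RE.match(self.label).group(2))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class PeakTable:
    """Compounds x samples abundance matrix with a processing-stage tag.

    ``values[i, j]`` is the abundance of ``compounds[i]`` in ``samples[j]``.
    Raw tables may contain exact zeros (non-detections); a ``relative`` table
    has columns summing to one; zero replacement guarantees strictly positive
    entries.
    """

    compounds: list[CompoundID]
    samples: list[str]
    values: np.ndarray
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compounds), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at compound {self.compounds[i].label!r}, "
                f"sample {self.samples[j]!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite abundance value")
        _check_unique([c.label for c in self.compounds], "compound")
        _check_unique(self.samples, "sample")
        if self.stage is Stage.ZERO_REPLACED and np.any(self.values == 0):
            raise ValueError("zero_replaced table contains zeros")
        if self.stage is Stage.RELATIVE:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative table has columns not summing to 1")

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def compound_labels(self) -> list[str]:
        return [c.label for c in self.compounds]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample_id)]

    def with_values(self, values: np.ndarray, stage: Stage) -> "PeakTable":
        return PeakTable(list(self.compounds), list(self.samples), values, stage)

    def select_compounds(self, keep: np.ndarray) -> "PeakTable":
        """Subset rows by a boolean or index array, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return PeakTable(
            [self.compounds[i] for i in idx],
            list(self.samples),
            self.values[idx, :],
            self.stage,
        )

    def select_samples(self, sample_ids: list[str]) -> "PeakTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return PeakTable(
            list(self.compounds), list(sample_ids), self.values[:, idx], self.stage
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_labels(), columns=self.samples
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return (
            self.compound_labels() == other.compound_labels()
            and self.samples == other.samples
            and self.stage == other.stage
            and np.array_equal(self.values, other.values)
        )


def derive_age_class(age_years: int) -> AgeClass:
    """Classify age in years: young below 10 years, mature at 10 or above."""
    if age_years < 1:
        raise ValueError(f"age_years must be >= 1, got {age_years}")
    return AgeClass.YOUNG if age_years < AGE_CLASS_BOUNDARY_YEARS else AgeClass.MATURE


@dataclass(frozen=True)
class SampleMetadata:
    """Biological attributes of one sample (one swab of one body site)."""

    sample_id: str
    individual_id: str
    sex: Sex
    age_years: int
    body_site: BodySite
    replicate: int = 1
    age_class: AgeClass | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        derived = derive_age_class(self.age_years)
        if self.age_class is None:
            object.__setattr__(self, "age_class", derived)
        elif self.age_class is not derived:
            raise ValueError(
                f"sample {self.sample_id!r}: age_class {self.age_class.value!r} "
                f"inconsistent with age {self.age_years} "
                f"(young < {AGE_CLASS_BOUNDARY_YEARS}, mature >= {AGE_CLASS_BOUNDARY_YEARS})"
            )

    @property
    def age_sex_class(self) -> str:
        return f"{self.age_class.value}_{self.sex.value}"


def metadata_frame(metadata: list[SampleMetadata]) -> pd.DataFrame:
    """Tabulate metadata records, indexed by sample ID."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "individual_id": [m.individual_id for m in metadata],
            "sex": [m.sex.value for m in metadata],
            "age_years": [m.age_years for m in metadata],
            "age_class": [m.age_class.value for m in metadata],
            "body_site": [m.body_site.value for m in metadata],
            "replicate": [m.replicate for m in metadata],
        }
    )
    df["age_sex_class"] = df["age_class"] + "_" + df["sex"]
    return df.set_index("sample_id", drop=False)


@dataclass
class Dataset:
    """A peak table together with metadata covering exactly its samples."""

    table: PeakTable
    metadata: list[SampleMetadata]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        meta_ids = [m.sample_id for m in self.metadata]
        _check_unique(meta_ids, "metadata sample")
        missing = [s for s in self.table.samples if s not in set(meta_ids)]
        extra = [s for s in meta_ids if s not in set(self.table.samples)]
        if missing or extra:
            raise ValueError(
                "table/metadata sample mismatch: "
                f"missing metadata for {missing}; metadata without columns {extra}"
            )
        keys = {(m.individual_id, m.body_site, m.replicate) for m in self.metadata}
        if len(keys) != len(self.metadata):
            raise ValueError("(individual, body_site, replicate) not unique")
        excluded = {s for s, _ in self.exclusions}
        present = excluded & set(self.table.samples)
        if present:
            raise ValueError(f"excluded samples still present in table: {sorted(present)}")
        # canonical order: metadata follows the table's sample order
        by_id = {m.sample_id: m for m in self.metadata}
        self.metadata = [by_id[s] for s in self.table.samples]

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    def meta_frame(self) -> pd.DataFrame:
        return metadata_frame(self.metadata)

    def drop_samples(self, sample_ids: list[str], reason: str) -> "Dataset":
        drop = set(sample_ids)
        unknown = drop - set(self.table.samples)
        if unknown:
            raise ValueError(f"cannot exclude unknown samples: {sorted(unknown)}")
        keep = [s for s in self.table.samples if s not in drop]
        return Dataset(
            self.table.select_samples(keep),
            [m for m in self.metadata if m.sample_id not in drop],
            self.exclusions + [(s, reason) for s in sample_ids],
        )

    def select_individuals(self, individual_ids: list[str]) -> "Dataset":
        keep_set = set(individual_ids)
        keep = [m.sample_id for m in self.metadata if m.individual_id in keep_set]
        return Dataset(
            self.table.select_samples(keep),
            [m for m in self.metadata if m.individual_id in keep_set],
            list(self.exclusions),
        )


def validate_dataset(
    table: PeakTable,
    metadata: list[SampleMetadata],
    exclusions: list[tuple[str, str]] | None = None,
) -> Dataset:
    """Pair a peak table with metadata, asserting one-to-one sample coverage."""
    return Dataset(table, metadata, list(exclusions or []))
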