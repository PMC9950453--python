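"""Filtering and normalization chain from raw peak table to analysis matrices.

Canonical order: raw -> incidence filter -> replicate rule -> half-minimum
zero replacement -> relative abundance (total-sum scaling) -> square-root
transform.  Each step checks the stage tag of its input, so the chain cannot
be run out of order.  Presence/absence analyses (Jaccard, uniqueness) use the
detection pattern *before* zero replacement: a pseudo-count is a numerical
device, not a detection.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

from .datatypes import Dataset, PeakTable, SampleMetadata, Stage

__all__ = [
    "ReplicateRule",
    "PreprocessParams",
    "incidence_threshold",
    "filter_by_incidence",
    "apply_replicate_rule",
    "replace_zeros",
    "to_relative_abundance",
    "sqrt_transform",
    "count_compounds_per_sample",
    "run_preprocess",
]

log = logging.getLogger(__name__)


class ReplicateRule(str, enum.Enum):
    BOTH_REPLICATES = "both_replicates"
    EITHER_REPLICATE = "either_replicate"
    IGNORE_REPLICATES = "ignore_replicates"


@dataclass
class PreprocessParams:
    """Tunable preprocessing thresholds.

    Defaults follow the analysis conventions of small-n wildlife VOC
    studies: compounds must occur in at least 5% of samples; a compound
    counts as present within a replicate pair only if detected in both
    members; compound-per-sample counts use a strict >0.50% relative
    abundance rule.
    """

    incidence_fraction: float = 0.05
    replicate_rule: ReplicateRule = ReplicateRule.BOTH_REPLICATES
    abundance_floor_for_presence: float = 0.0
    count_threshold_fraction: float = 0.005
    half_minimum_scope: str = "global"  # or "per_compound"

    def __post_init__(self) -> None:
        if not (0.0 < self.incidence_fraction <= 1.0):
            raise ValueError("incidence_fraction must be in (0, 1]")
        if self.abundance_floor_for_presence < 0:
            raise ValueError("abundance_floor_for_presence must be >= 0")
        if self.half_minimum_scope not in ("global", "per_compound"):
            raise ValueError("half_minimum_scope must be 'global' or 'per_compound'")
        self.replicate_rule = ReplicateRule(self.replicate_rule)


def incidence_threshold(n_samples: int, fraction: float = 0.05) -> int:
    """Minimum number of samples a compound must occur in: ceil(f * n), >= 1.

    incidence_threshold(77, 0.05) == 4, the usual 5%-of-samples rule.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    return max(1, math.ceil(fraction * n_samples))


def _presence(table: PeakTable, floor: float = 0.0) -> np.ndarray:
    return table.values > floor


def filter_by_incidence(
    table: PeakTable, min_samples: int, abundance_floor: float = 0.0
) -> PeakTable:
    """Retain compounds detected in at least ``min_samples`` samples."""
    if table.stage is not Stage.RAW:
        raise ValueError("incidence filter expects a raw-stage table")
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples {min_samples} exceeds sample count {table.n_samples}"
        )
    incidence = _presence(table, abundance_floor).sum(axis=1)
    kept = table.select_compounds(incidence >= min_samples)
    log.info(
        "incidence filter (>= %d samples): %d -> %d compounds",
        min_samples, table.n_compounds, kept.n_compounds,
    )
    return kept


def _replicate_pairs(
    metadata: list[SampleMetadata],
) -> list[tuple[str, ...]]:
    """Group sample IDs by (individual, body site); singletons allowed."""
    groups: dict[tuple[str, str], list[str]] = {}
    for m in metadata:
        groups.setdefault((m.individual_id, m.body_site.value), []).append(m.sample_id)
    for key, members in groups.items():
        if len(members) > 2:
            raise ValueError(f"replicate group {key} has {len(members)} > 2 members")
    return [tuple(v) for v in groups.values()]


def apply_replicate_rule(
    table: PeakTable,
    metadata: list[SampleMetadata],
    rule: ReplicateRule | str = ReplicateRule.BOTH_REPLICATES,
    abundance_floor: float = 0.0,
) -> PeakTable:
    """Enforce the both-replicates detection criterion.

    Under ``both_replicates`` a compound's abundance within a replicate pair
    is zeroed unless it is detected in both members; singleton "pairs" are
    left as-is.  All samples remain separate columns.  The other rules leave
    the table unchanged.
    """
    rule = ReplicateRule(rule)
    if rule is not ReplicateRule.BOTH_REPLICATES:
        return table.with_values(table.values.copy(), table.stage)
    col = {s: i for i, s in enumerate(table.samples)}
    values = table.values.copy()
    present = values > abundance_floor
    n_zeroed = 0
    for pair in _replicate_pairs(metadata):
        if len(pair) != 2:
            continue
        i, j = col[pair[0]], col[pair[1]]
        keep = present[:, i] & present[:, j]
        n_zeroed += int((~keep & (present[:, i] | present[:, j])).sum())
        values[~keep, i] = 0.0
        values[~keep, j] = 0.0
    log.info("replicate rule both_replicates: zeroed %d singleton detections", n_zeroed)
    return table.with_values(values, table.stage)


def replace_zeros(table: PeakTable, scope: str = "global") -> PeakTable:
    """Replace zeros with half the minimum positive abundance.

    ``scope='global'`` (default) uses one constant — half the smallest
    positive entry of the whole table; ``scope='per_compound'`` uses half
    each compound's own minimum positive value (rows that are entirely zero
    fall back to the global constant).
    """
    if table.stage is not Stage.RAW:
        raise ValueError("zero replacement expects a raw-stage table")
    values = table.values.copy()
    positive = values > 0
    if not positive.any():
        raise ValueError("cannot replace zeros in an all-zero table")
    global_half = 0.5 * values[positive].min()
    if scope == "global":
        values[~positive] = global_half
        log.info("zero replacement: global pseudo-count %.6g", global_half)
    elif scope == "per_compound":
        for i in range(values.shape[0]):
            row_pos = positive[i]
            fill = 0.5 * values[i, row_pos].min() if row_pos.any() else global_half
            values[i, ~row_pos] = fill
    else:
        raise ValueError(f"unknown half-minimum scope {scope!r}")
    return table.with_values(values, Stage.ZERO_REPLACED)


def to_relative_abundance(table: PeakTable) -> PeakTable:
    """Total-sum scaling: divide each sample by its total abundance."""
    if table.stage is not Stage.ZERO_REPLACED:
        raise ValueError("relative-abundance scaling expects a zero_replaced table")
    sums = table.values.sum(axis=0)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"zero-sum sample column: {table.samples[bad[0]]!r}")
    return table.with_values(table.values / sums, Stage.RELATIVE)


def sqrt_transform(table: PeakTable) -> PeakTable:
    """Entrywise square root of relative abundances (variance stabilizing)."""
    if table.stage is not Stage.RELATIVE:
        raise ValueError("square-root transform expects a relative-stage table")
    return table.with_values(np.sqrt(table.values), Stage.TRANSFORMED)


def count_compounds_per_sample(
    table: PeakTable, threshold_fraction: float = 0.005
) -> dict[str, int]:
    """Per sample, count compounds strictly above a relative-abundance cut.

    The conventional figure-level summary counts compounds contributing
    more than 0.50% of a sample's profile; the inequality is strict, so a
    compound at exactly the threshold is not counted.
    """
    if table.stage is not Stage.RELATIVE:
        raise ValueError("compound counting expects a relative-stage table")
    if threshold_fraction >= 1.0:
        raise ValueError("threshold_fraction must be < 1")
    counts = (table.values > threshold_fraction).sum(axis=0)
    return {s: int(c) for s, c in zip(table.samples, counts)}


@dataclass
class PreprocessResult:
    """All intermediate stages of the canonical chain."""

    raw: PeakTable
    filtered: PeakTable
    detection: np.ndarray  # presence pattern after the replicate rule
    zero_replaced: PeakTable
    relative: PeakTable
    transformed: PeakTable
    pseudo_count: float
    min_samples: int


def run_preprocess(dataset: Dataset, params: PreprocessParams | None = None) -> PreprocessResult:
    """Run the canonical chain on a dataset, recording every stage.

    The returned ``detection`` matrix (compounds x samples, boolean) is the
    presence pattern after the replicate rule but before zero replacement —
    the pattern Jaccard and uniqueness analyses operate on.
    """
    params = params or PreprocessParams()
    raw = dataset.table
    min_samples = incidence_threshold(raw.n_samples, params.incidence_fraction)
    filtered = filter_by_incidence(raw, min_samples, params.abundance_floor_for_presence)
    ruled = apply_replicate_rule(
        filtered, dataset.metadata, params.replicate_rule,
        params.abundance_floor_for_presence,
    )
    detection = ruled.values > params.abundance_floor_for_presence
    zero_replaced = replace_zeros(ruled, params.half_minimum_scope)
    pseudo = 0.5 * ruled.values[ruled.values > 0].min()
    relative = to_relative_abundance(zero_replaced)
    transformed = sqrt_transform(relative)
    return PreprocessResult(
        raw=raw,
        filtered=filtered,
        detection=detection,
        zero_replaced=zero_replaced,
        relative=relative,
        transformed=transformed,
        pseudo_count=pseudo,
        min_samples=min_samples,
    )
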