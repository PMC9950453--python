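"""Pairwise sample dissimilarities: Bray-Curtis and Jaccard.

Bray-Curtis operates on (transformed) relative abundances,
d(i,j) = sum_k |x_ki - x_kj| / sum_k (x_ki + x_kj); Jaccard operates on
detected-compound sets, d = 1 - |A n B| / |A u B|.  The classical set form
of Jaccard equals 2b/(1+b) where b is the binary Bray-Curtis (Sorensen)
dissimilarity — an identity the test suite checks exactly, since the two
are often confused.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import PeakTable, Stage

__all__ = ["Metric", "DissimilarityMatrix", "bray_curtis", "jaccard"]


class Metric(str, enum.Enum):
    BRAY_CURTIS = "bray_curtis"
    JACCARD = "jaccard"


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray
    metric: Metric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("dissimilarity matrix has nonzero diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("dissimilarity entries outside [0, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def between(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def reorder(self, sample_ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimilarityMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)], self.metric
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, path: str | Path, metric: Metric | str) -> "DissimilarityMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls([str(s) for s in df.columns], df.to_numpy(), Metric(metric))


def bray_curtis(table: PeakTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    Expects the transformed (or relative) stage so that the distances being
    decomposed downstream (SIMPER) match the distances being tested.
    """
    if table.stage not in (Stage.TRANSFORMED, Stage.RELATIVE):
        raise ValueError("Bray-Curtis expects a relative or transformed table")
    X = table.values
    col_sums = X.sum(axis=0)
    # denominator s_i + s_j; numerator via pairwise L1
    diff = np.abs(X[:, :, None] - X[:, None, :]).sum(axis=0)
    denom = col_sums[:, None] + col_sums[None, :]
    zero_pair = denom == 0
    if np.any(zero_pair & ~np.eye(len(table.samples), dtype=bool)):
        raise ValueError("Bray-Curtis undefined: two all-zero sample columns")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pair, 0.0, diff / np.where(zero_pair, 1.0, denom))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(table.samples), d, Metric.BRAY_CURTIS)


def jaccard(
    detection: np.ndarray | PeakTable, sample_ids: list[str] | None = None
) -> DissimilarityMatrix:
    """Jaccard dissimilarity on detected-compound sets.

    ``detection`` is a boolean compounds x samples matrix (raw detections,
    i.e. the pre-zero-replacement pattern) or a peak table whose positive
    entries define presence.  A sample with no detections is at distance 1
    from any non-empty sample; two empty samples are rejected.
    """
    if isinstance(detection, PeakTable):
        if sample_ids is None:
            sample_ids = list(detection.samples)
        detection = detection.values > 0
    if sample_ids is None:
        raise ValueError("sample_ids required when detection is a bare matrix")
    B = np.asarray(detection, dtype=bool).astype(float)
    inter = B.T @ B
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    both_empty = union == 0
    if np.any(both_empty & ~np.eye(len(sample_ids), dtype=bool)):
        raise ValueError("Jaccard undefined: two samples with no detections")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(both_empty, 0.0, 1.0 - inter / np.where(both_empty, 1.0, union))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(sample_ids), d, Metric.JACCARD)
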