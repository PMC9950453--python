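"""Non-metric multidimensional scaling with Kruskal stress-1.

The embedding is found by majorization (SMACOF) on ranks, best of several
random restarts plus one metric (principal-coordinates) start.  Stress-1 is
computed against the monotone (isotonic, primary tie treatment) regression
of the embedded distances on the input dissimilarity order:

    stress1 = sqrt( sum (dhat_ij - theta_ij)^2 / sum dhat_ij^2 )

Two goodness-of-fit flavours are reported because both circulate in the
literature: the non-metric R^2 = 1 - stress1^2 and the linear R^2 (squared
correlation between embedded distances and the monotone fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist
from scipy.stats import chi2
from sklearn.manifold import smacof

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "NMDSResult",
    "nmds",
    "nmds_scan",
    "goodness_of_fit",
    "monotone_fit",
    "EllipseParams",
    "group_ellipses",
]


def monotone_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit of y against the order of x.

    Primary tie treatment: tied x values are sorted by y first, so the
    monotone fit is free to leave tied blocks unequal (ties may be broken
    to reduce stress).  Returns fitted values in the original order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.lexsort((y, x))
    fitted_sorted = isotonic_regression(y[order]).x
    fitted = np.empty_like(y)
    fitted[order] = fitted_sorted
    return fitted


@dataclass
class NMDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # n x k, centered at the origin
    stress: float  # Kruskal stress-1
    nonmetric_r2: float
    linear_r2: float
    k: int
    n_restarts: int
    converged: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"NMDS{i + 1}" for i in range(self.k)],
        )


def _stress1(coords: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """(stress-1, linear R^2) of a configuration against dissimilarities d."""
    dhat = pdist(coords)
    denom = float(np.sum(dhat ** 2))
    if denom == 0:
        return (0.0, 1.0) if np.allclose(d, 0) else (1.0, 0.0)
    theta = monotone_fit(d, dhat)
    s2 = float(np.sum((dhat - theta) ** 2)) / denom
    if np.std(theta) == 0 or np.std(dhat) == 0:
        linear = 1.0 if s2 < 1e-12 else 0.0
    else:
        linear = float(np.corrcoef(dhat, theta)[0, 1] ** 2)
    return float(np.sqrt(max(s2, 0.0))), linear


def _pcoa_coords(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * C @ (D ** 2) @ C
    w, V = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1][:k]
    coords = V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    return coords


def nmds(
    dmatrix: DissimilarityMatrix,
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    extra_inits: list[np.ndarray] | None = None,
) -> NMDSResult:
    """Best-of-restarts non-metric MDS minimizing Kruskal stress-1.

    One start is the metric (PCoA) configuration; ``n_restarts`` further
    starts are random.  Deterministic given the seed.  Non-convergence of
    the majorization loop is flagged but the best configuration found is
    still returned.
    """
    n = dmatrix.n
    if k >= n:
        # n points always embed exactly in n-1 dimensions, so k <= n-1
        raise ValueError(f"k={k} requires at least {k + 1} samples, have {n}")
    D = dmatrix.values
    d_flat = D[np.triu_indices(n, 1)]
    inits: list[np.ndarray | None] = [_pcoa_coords(D, k)]
    if extra_inits:
        inits.extend(np.asarray(e, dtype=float) for e in extra_inits)
    inits.extend([None] * n_restarts)

    best: tuple[float, float, np.ndarray, bool] | None = None
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for init in inits:
            rs = int(rng.integers(0, 2 ** 31 - 1))
            coords, _, n_iter = smacof(
                D,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                random_state=rs,
                normalized_stress=True,
                return_n_iter=True,
            )
            stress, linear = _stress1(coords, d_flat)
            converged = n_iter < max_iter
            if best is None or stress < best[0]:
                best = (stress, linear, coords, converged)

    stress, linear, coords, converged = best
    coords = coords - coords.mean(axis=0)
    if not converged:
        warnings.warn("nMDS majorization did not converge; best solution returned")
    return NMDSResult(
        sample_ids=list(dmatrix.sample_ids),
        coordinates=coords,
        stress=stress,
        nonmetric_r2=1.0 - stress ** 2,
        linear_r2=linear,
        k=k,
        n_restarts=n_restarts,
        converged=converged,
    )


def nmds_scan(
    dmatrix: DissimilarityMatrix,
    k_values: list[int],
    n_restarts: int = 20,
    seed: int = 0,
    **kwargs,
) -> dict[int, NMDSResult]:
    """nMDS over increasing dimensions, for choosing k by stress.

    Each dimension additionally starts from the previous best configuration
    padded with a zero axis, which guarantees weakly decreasing stress in k.
    """
    results: dict[int, NMDSResult] = {}
    prev: NMDSResult | None = None
    for k in sorted(k_values):
        extra = []
        if prev is not None and prev.k < k:
            pad = np.zeros((dmatrix.n, k - prev.k))
            extra.append(np.hstack([prev.coordinates, pad]))
        results[k] = nmds(
            dmatrix, k=k, n_restarts=n_restarts, seed=seed,
            extra_inits=extra, **kwargs,
        )
        prev = results[k]
    return results


def goodness_of_fit(
    result: NMDSResult, dmatrix: DissimilarityMatrix
) -> tuple[float, float]:
    """(non-metric R^2, linear R^2) recomputed from a configuration."""
    n = dmatrix.n
    d_flat = dmatrix.values[np.triu_indices(n, 1)]
    stress, linear = _stress1(result.coordinates, d_flat)
    return 1.0 - stress ** 2, linear


@dataclass
class EllipseParams:
    """Covariance confidence ellipse on the first two ordination axes."""

    group: str
    center: tuple[float, float]
    width: float  # full axis length along the major eigenvector
    height: float
    angle_deg: float
    n: int
    degenerate: bool


def group_ellipses(
    coordinates: np.ndarray | pd.DataFrame,
    grouping: dict[str, str] | pd.Series,
    confidence: float = 0.99,
    sample_ids: list[str] | None = None,
) -> dict[str, EllipseParams]:
    """Per-group confidence ellipses (chi-square quantile, 2 df).

    Groups with fewer than 3 samples are skipped with a warning; a group
    whose 2-D covariance is singular (e.g. duplicated points) is returned
    flagged as degenerate.
    """
    if isinstance(coordinates, pd.DataFrame):
        sample_ids = list(coordinates.index)
        coordinates = coordinates.to_numpy()
    if sample_ids is None:
        raise ValueError("sample_ids required with bare coordinate arrays")
    grouping = pd.Series(grouping)
    labels = grouping.loc[sample_ids].to_numpy()
    scale = chi2.ppf(confidence, df=2)
    out: dict[str, EllipseParams] = {}
    for g in pd.unique(labels):
        pts = coordinates[labels == g][:, :2]
        if len(pts) < 3:
            warnings.warn(f"group {g!r} has < 3 samples; ellipse skipped")
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        w, V = np.linalg.eigh(cov)
        degenerate = bool(w.min() <= 1e-12)
        w = np.clip(w, 0.0, None)
        angle = float(np.degrees(np.arctan2(V[1, 1], V[0, 1])))
        out[str(g)] = EllipseParams(
            group=str(g),
            center=(float(center[0]), float(center[1])),
            width=float(2.0 * np.sqrt(scale * w[1])),
            height=float(2.0 * np.sqrt(scale * w[0])),
            angle_deg=angle,
            n=len(pts),
            degenerate=degenerate,
        )
    return out
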