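"""Distance-based inference: sequential-term PERMANOVA and dispersion.

The PERMANOVA here follows the classical partitioning of a dissimilarity
matrix: Gower-center the squared dissimilarities, project onto a sequence of
dummy-coded model matrices, and attribute to each term the increment in
explained sum of squares (sequential, order-dependent SS — the behaviour of
``adonis``-style software).  Nested factors (individual within sex, body
site within individual) are encoded by entering the nested factor's full
level set after its nesting factors; the sequential increment then carries
the nested degrees of freedom.  P-values come from free whole-row label
permutation with the add-one estimator, so p is never 0 and never below
1/(n_permutations + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Dataset, SampleMetadata, metadata_frame
from .dissimilarity import DissimilarityMatrix

__all__ = [
    "Term",
    "ModelDesign",
    "DESIGN_PRESETS",
    "PermanovaTable",
    "DispersionResult",
    "gower_center",
    "permanova",
    "adjust_fdr",
    "fdr_across",
    "dispersion",
    "balance_by_subsampling",
]

log = logging.getLogger(__name__)

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class Term:
    """One model term: a (possibly crossed/nested) combination of factors.

    ``columns`` are metadata columns whose value combinations define the
    term's cells.  Nesting needs no special syntax: coding every cell of
    ``individual_id`` after ``sex`` yields exactly the ID-within-sex
    sequential increment.
    """

    name: str
    columns: tuple[str, ...]

    def cells(self, meta: pd.DataFrame) -> pd.Series:
        combined = meta[self.columns[0]].astype(str)
        for c in self.columns[1:]:
            combined = combined + "/" + meta[c].astype(str)
        return combined


@dataclass(frozen=True)
class ModelDesign:
    """Ordered sequence of terms; order determines the sequential SS."""

    name: str
    terms: tuple[Term, ...]


def _T(name: str, *cols: str) -> Term:
    return Term(name, cols)


#: The study's model presets.  ``full`` is the headline design
#: (age + sex + age*sex + ID(sex) + body site(ID(sex))); the single-factor
#: presets are the initial groupings; ``site_in_individual`` and
#: ``individual_only`` serve the per-age-sex-class reruns.
DESIGN_PRESETS: dict[str, ModelDesign] = {
    "age": ModelDesign("age", (_T("age", "age_class"),)),
    "sex": ModelDesign("sex", (_T("sex", "sex"),)),
    "age_sex": ModelDesign(
        "age_sex",
        (_T("age", "age_class"), _T("sex", "sex"), _T("age*sex", "age_class", "sex")),
    ),
    "individual": ModelDesign(
        "individual", (_T("sex", "sex"), _T("ID(sex)", "individual_id"))
    ),
    "body_site": ModelDesign(
        "body_site",
        (
            _T("sex", "sex"),
            _T("ID(sex)", "individual_id"),
            _T("site(ID(sex))", "individual_id", "body_site"),
        ),
    ),
    "full": ModelDesign(
        "full",
        (
            _T("age", "age_class"),
            _T("sex", "sex"),
            _T("age*sex", "age_class", "sex"),
            _T("ID(sex)", "individual_id"),
            _T("site(ID(sex))", "individual_id", "body_site"),
        ),
    ),
    "individual_only": ModelDesign(
        "individual_only", (_T("ID", "individual_id"),)
    ),
    "site_in_individual": ModelDesign(
        "site_in_individual",
        (_T("ID", "individual_id"), _T("site(ID)", "individual_id", "body_site")),
    ),
}


@dataclass
class PermanovaTable:
    """Per-term df, SS, pseudo-F and permutation p, plus residual/total rows."""

    design: str
    metric: str
    table: pd.DataFrame  # index: term names + "Residual" + "Total"
    n_permutations: int
    seed: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p_values(self) -> pd.Series:
        return self.table["p_perm"].dropna()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"PERMANOVA [{self.design}, {self.metric}]\n{self.table}"


def gower_center(dmatrix: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 C d^2 C.

    trace(G) equals the total sum of squares (1/n) sum_{i<j} d_ij^2.
    """
    D = dmatrix.values if isinstance(dmatrix, DissimilarityMatrix) else np.asarray(dmatrix)
    n = D.shape[0]
    A = -0.5 * D ** 2
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return C @ A @ C


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > _RANK_TOL * s[0]).sum()) if s.size and s[0] > 0 else 0
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def _build_projectors(
    design: ModelDesign, meta: pd.DataFrame
) -> tuple[list[np.ndarray], list[int], np.ndarray, int]:
    """Sequential difference projectors, dfs, residual projector, residual df."""
    n = len(meta)
    X = np.ones((n, 1))
    H_prev, r_prev = _hat(X)
    deltas: list[np.ndarray] = []
    dfs: list[int] = []
    for term in design.terms:
        cells = term.cells(meta)
        if cells.nunique() < 2:
            raise ValueError(f"term {term.name!r} has a single level")
        dummies = pd.get_dummies(cells).to_numpy(dtype=float)
        X = np.hstack([X, dummies])
        H, r = _hat(X)
        df = r - r_prev
        if df < 1:
            raise ValueError(
                f"term {term.name!r} adds no degrees of freedom after "
                "the preceding terms"
            )
        deltas.append(H - H_prev)
        dfs.append(df)
        H_prev, r_prev = H, r
    df_res = n - r_prev
    if df_res < 1:
        raise ValueError("saturated design: residual degrees of freedom = 0")
    residual = np.eye(n) - H_prev
    return deltas, dfs, residual, df_res


def permanova(
    dmatrix: DissimilarityMatrix,
    design: ModelDesign | str,
    metadata: list[SampleMetadata],
    n_permutations: int = 10_000,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaTable:
    """Sequential-SS PERMANOVA with permutation p-values.

    ``strata`` optionally names a metadata column within whose levels rows
    are permuted (default: free permutation).  P-values use the add-one
    estimator with inclusive tie counting (permuted F >= observed counts as
    extreme).  BH-adjusted p-values across the table's own terms are filled
    in; use :func:`fdr_across` to adjust over a wider family.
    """
    if isinstance(design, str):
        design = DESIGN_PRESETS[design]
    if dmatrix.n < 4:
        raise ValueError("PERMANOVA requires at least 4 samples")
    meta = metadata_frame(metadata).loc[dmatrix.sample_ids]
    deltas, dfs, residual, df_res = _build_projectors(design, meta)
    G = gower_center(dmatrix)
    total_ss = float(np.trace(G))
    K = len(deltas)
    Dstack = np.stack(deltas)
    ss_obs = np.einsum("kij,ij->k", Dstack, G)
    ss_res = float(np.sum(residual * G))
    F_obs = (ss_obs / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    n = dmatrix.n
    counts = np.zeros(K, dtype=np.int64)
    if strata is not None:
        groups = [np.flatnonzero(meta[strata].values == g)
                  for g in pd.unique(meta[strata].values)]
    chunk = max(1, min(256, n_permutations))
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        if strata is None:
            idx = np.argsort(rng.random((c, n)), axis=1)
        else:
            idx = np.tile(np.arange(n), (c, 1))
            for g in groups:
                sub = np.argsort(rng.random((c, len(g))), axis=1)
                idx[:, g] = g[sub]
        Gp = G[idx[:, :, None], idx[:, None, :]]
        ss_p = np.einsum("kij,cij->kc", Dstack, Gp)
        ss_res_p = total_ss - ss_p.sum(axis=0)
        F_p = (ss_p / np.array(dfs)[:, None]) / (ss_res_p / df_res)
        counts += (F_p >= F_obs[:, None] - 1e-12).sum(axis=1)
        done += c
    p_perm = (1.0 + counts) / (1.0 + n_permutations)

    names = [t.name for t in design.terms]
    table = pd.DataFrame(
        {
            "df": dfs + [df_res, n - 1],
            "SS": list(ss_obs) + [ss_res, total_ss],
            "pseudo_F": list(F_obs) + [np.nan, np.nan],
            "p_perm": list(p_perm) + [np.nan, np.nan],
        },
        index=names + ["Residual", "Total"],
    )
    table["p_adj_fdr"] = np.nan
    table.loc[names, "p_adj_fdr"] = adjust_fdr(list(p_perm))
    return PermanovaTable(design.name, str(dmatrix.metric.value), table,
                          n_permutations, seed)


def adjust_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p, method="fdr_bh")[1])


def fdr_across(tables: list[PermanovaTable]) -> None:
    """Re-adjust p-values with BH over the pooled family of several tables.

    Mirrors reporting conventions where one results table carries all terms
    of all distance metrics; modifies the tables in place.
    """
    keys, pooled = [], []
    for t in tables:
        for name, p in t.p_values().items():
            keys.append((t, name))
            pooled.append(p)
    adjusted = adjust_fdr(pooled)
    for (t, name), q in zip(keys, adjusted):
        t.table.loc[name, "p_adj_fdr"] = q


@dataclass
class DispersionResult:
    """Distance-to-centroid dispersion comparison across groups."""

    distances: pd.Series  # per-sample distance to its group centroid
    group_means: pd.Series
    F: float
    p: float
    excluded_groups: list[str] = field(default_factory=list)


def dispersion(
    dmatrix: DissimilarityMatrix, grouping: dict[str, str] | pd.Series
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Samples are embedded by principal-coordinates decomposition of the
    Gower-centered matrix; negative-eigenvalue axes contribute negatively
    to squared centroid distances (the standard correction), with small
    negatives clamped to zero.  Group sizes of 1 are excluded with a
    warning; a one-way F-test compares the centroid distances.
    """
    grouping = pd.Series(grouping)
    labels = grouping.loc[dmatrix.sample_ids].to_numpy()
    G = gower_center(dmatrix)
    w, V = np.linalg.eigh(G)
    pos, neg = w > 1e-10, w < -1e-10
    Xp = V[:, pos] * np.sqrt(w[pos])
    Xn = V[:, neg] * np.sqrt(-w[neg])

    sizes = pd.Series(labels).value_counts()
    excluded = [g for g in sizes.index if sizes[g] < 2]
    if excluded:
        warnings.warn(f"dispersion: excluding singleton groups {excluded}")
    keep_groups = [g for g in sizes.index if sizes[g] >= 2]
    if len(keep_groups) < 2:
        raise ValueError("dispersion requires >= 2 groups with >= 2 samples")

    dist = {}
    for g in keep_groups:
        mask = labels == g
        cp = Xp[mask].mean(axis=0)
        cn = Xn[mask].mean(axis=0)
        d2 = ((Xp[mask] - cp) ** 2).sum(axis=1) - ((Xn[mask] - cn) ** 2).sum(axis=1)
        d = np.sqrt(np.clip(d2, 0.0, None))
        for sid, val in zip(np.array(dmatrix.sample_ids)[mask], d):
            dist[sid] = float(val)
    distances = pd.Series(dist, name="centroid_distance")
    by_group = [distances[np.array(dmatrix.sample_ids)[labels == g]].to_numpy()
                for g in keep_groups]
    F, p = stats.f_oneway(*by_group)
    means = pd.Series({g: float(np.mean(v)) for g, v in zip(keep_groups, by_group)})
    return DispersionResult(distances, means, float(F), float(p), excluded)


def balance_by_subsampling(
    dataset: Dataset,
    class_to_reduce: str,
    n_individuals: int,
    seed: int = 0,
    keep_individuals: list[str] | None = None,
) -> Dataset:
    """Randomly subsample one age-sex class down to ``n_individuals`` bears.

    ``class_to_reduce`` is an age-sex class label such as ``"young_M"``.
    All samples of the chosen individuals are retained, as are all samples
    outside the class.  Deterministic given the seed; ``keep_individuals``
    pins the retained bears explicitly (e.g. to reproduce a published
    subsample) instead of drawing them.
    """
    meta = dataset.meta_frame()
    in_class = meta.loc[meta["age_sex_class"] == class_to_reduce, "individual_id"]
    individuals = sorted(in_class.unique())
    if not individuals:
        raise ValueError(f"no individuals in class {class_to_reduce!r}")
    if n_individuals >= len(individuals):
        return dataset
    if keep_individuals is not None:
        unknown = set(keep_individuals) - set(individuals)
        if unknown or len(keep_individuals) != n_individuals:
            raise ValueError(
                f"keep_individuals must name {n_individuals} bears of "
                f"{class_to_reduce!r}; got {keep_individuals}"
            )
        chosen = sorted(keep_individuals)
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(individuals, size=n_individuals, replace=False))
    keep = sorted(set(meta["individual_id"]) - set(individuals) | set(chosen))
    log.info("balanced subsample of %s: kept %s", class_to_reduce, chosen)
    return dataset.select_individuals(keep)
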