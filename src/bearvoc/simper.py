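"""SIMPER decomposition and univariate follow-up tests.

SIMPER attributes the average between-group Bray-Curtis dissimilarity to
individual compounds: for each between-group sample pair the per-compound
share is |x_ki - x_kj| / sum_m (x_mi + x_mj), averaged over all pairs.  The
shares sum exactly to the mean between-group dissimilarity, which the test
suite checks to 1e-10.  Compounds contributing at least 2.0% are screened
as "of interest" and followed up with per-compound ANOVA (sequential SS,
matching the multivariate module's term convention), Tukey HSD, or
Bonferroni-corrected pairwise contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import CompoundID, PeakTable, SampleMetadata, Stage, metadata_frame
from .multivariate import ModelDesign, Term

__all__ = [
    "SimperRow",
    "simper",
    "simper_all_pairs",
    "screen_contributors",
    "UnivariateRow",
    "compound_anova",
    "pairwise_bonferroni",
    "CompoundCountResult",
    "compound_count_anova",
]


@dataclass
class SimperRow:
    compound: CompoundID
    group_pair: tuple[str, str]
    mean_contribution: float
    percent_contribution: float
    cumulative_percent: float = float("nan")


def simper(
    table: PeakTable,
    grouping: dict[str, str] | pd.Series,
    group_pair: tuple[str, str],
) -> list[SimperRow]:
    """Per-compound contributions to the mean between-group dissimilarity.

    Runs on the same transformed relative-abundance matrix as Bray-Curtis,
    so the contributions decompose exactly the distances being analysed.
    Rows are returned sorted by decreasing contribution with cumulative
    percentages filled in.
    """
    if table.stage not in (Stage.TRANSFORMED, Stage.RELATIVE):
        raise ValueError("SIMPER expects a relative or transformed table")
    grouping = pd.Series(grouping)
    labels = grouping.loc[table.samples].to_numpy()
    a, b = group_pair
    idx_a = np.flatnonzero(labels == a)
    idx_b = np.flatnonzero(labels == b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"empty group in pair {group_pair}")
    X = table.values
    contrib = np.zeros(table.n_compounds)
    n_pairs = 0
    for i in idx_a:
        for j in idx_b:
            denom = X[:, i].sum() + X[:, j].sum()
            if denom == 0:
                raise ValueError("pair of all-zero samples in SIMPER")
            contrib += np.abs(X[:, i] - X[:, j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    if total == 0:
        raise ValueError("zero average dissimilarity between groups "
                         f"{group_pair}: contributions undefined")
    percent = 100.0 * contrib / total
    order = np.argsort(-contrib, kind="stable")
    rows = []
    cum = 0.0
    for k in order:
        cum += percent[k]
        rows.append(
            SimperRow(
                compound=table.compounds[k],
                group_pair=(a, b),
                mean_contribution=float(contrib[k]),
                percent_contribution=float(percent[k]),
                cumulative_percent=float(cum),
            )
        )
    return rows


def simper_all_pairs(
    table: PeakTable, grouping: dict[str, str] | pd.Series
) -> dict[tuple[str, str], list[SimperRow]]:
    """SIMPER for every unordered pair of groups (pooled-list provenance)."""
    grouping = pd.Series(grouping)
    groups = sorted(pd.unique(grouping.loc[table.samples]))
    return {
        (a, b): simper(table, grouping, (a, b))
        for a, b in itertools.combinations(groups, 2)
    }


def screen_contributors(
    rows: list[SimperRow], cutoff_percent: float = 2.0
) -> list[CompoundID]:
    """Compounds contributing >= cutoff percent, sorted descending (boundary
    inclusive)."""
    passing = [r for r in rows if r.percent_contribution >= cutoff_percent]
    passing.sort(key=lambda r: -r.percent_contribution)
    return [r.compound for r in passing]


@dataclass
class UnivariateRow:
    compound: CompoundID
    anova: pd.DataFrame
    F: float
    p: float
    focal_term: str
    simper_percent: float = float("nan")
    pairwise: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)


def _term_frame(
    design: ModelDesign, meta: pd.DataFrame, y: np.ndarray
) -> tuple[pd.DataFrame, str]:
    data = pd.DataFrame({"y": y}, index=meta.index)
    parts = []
    for i, term in enumerate(design.terms):
        col = f"t{i}"
        data[col] = term.cells(meta).values
        parts.append(f"C({col})")
    return data, "y ~ " + " + ".join(parts)


def compound_anova(
    table: PeakTable,
    metadata: list[SampleMetadata],
    compound: CompoundID | str,
    design: ModelDesign,
    focal_term: str | None = None,
    tukey_on: str | None = None,
    bonferroni_on: str | None = None,
) -> UnivariateRow:
    """Linear-model ANOVA of one compound's (transformed) relative abundance.

    Sequential (type I) sums of squares over the design terms; the reported
    F/p belong to ``focal_term`` (default: the last term).  ``tukey_on`` /
    ``bonferroni_on`` name a metadata column (or term) for pairwise
    follow-up contrasts.
    """
    label = compound.label if isinstance(compound, CompoundID) else compound
    try:
        k = table.compound_labels().index(label)
    except ValueError:
        raise ValueError(f"compound {label!r} not in table") from None
    meta = metadata_frame(metadata).loc[table.samples]
    y = table.values[k, :]
    if np.ptp(y) == 0:
        raise ValueError(f"compound {label!r} has zero variance")
    data, formula = _term_frame(design, meta, y)
    model = smf.ols(formula, data=data).fit()
    if model.df_resid < 1:
        raise ValueError("saturated univariate design")
    anova = sm.stats.anova_lm(model, typ=1)
    anova.index = [t.name for t in design.terms] + ["Residual"]
    focal = focal_term or design.terms[-1].name
    if focal not in anova.index:
        raise ValueError(f"unknown focal term {focal!r}")

    pairwise: list[tuple[tuple[str, str], float, float]] = []
    if tukey_on is not None:
        groups = _resolve_labels(tukey_on, design, meta)
        res = pairwise_tukeyhsd(y, groups)
        for (g1, g2), p in zip(
            itertools.combinations(res.groupsunique, 2), res.pvalues
        ):
            pairwise.append(((str(g1), str(g2)), float(p), float(p)))
    if bonferroni_on is not None:
        pairwise.extend(pairwise_bonferroni(y, _resolve_labels(bonferroni_on, design, meta)))

    return UnivariateRow(
        compound=table.compounds[k],
        anova=anova,
        F=float(anova.loc[focal, "F"]),
        p=float(anova.loc[focal, "PR(>F)"]),
        focal_term=focal,
        pairwise=pairwise,
    )


def _resolve_labels(name: str, design: ModelDesign, meta: pd.DataFrame) -> np.ndarray:
    if name in meta.columns:
        return meta[name].to_numpy()
    for term in design.terms:
        if term.name == name:
            return term.cells(meta).to_numpy()
    raise ValueError(f"cannot resolve grouping {name!r}")


def pairwise_bonferroni(
    values: np.ndarray, labels: np.ndarray
) -> list[tuple[tuple[str, str], float, float]]:
    """All pairwise equal-variance t-tests with Bonferroni-adjusted p."""
    groups = sorted(pd.unique(labels))
    pairs = list(itertools.combinations(groups, 2))
    out = []
    m = len(pairs)
    for g1, g2 in pairs:
        _, p = stats.ttest_ind(values[labels == g1], values[labels == g2])
        out.append(((str(g1), str(g2)), float(p), float(min(1.0, p * m))))
    return out


@dataclass
class CompoundCountResult:
    anova: pd.DataFrame
    tukey: pd.DataFrame
    group_stats: pd.DataFrame  # mean, sd, n per age-sex class


def compound_count_anova(
    counts: dict[str, int],
    metadata: list[SampleMetadata],
) -> CompoundCountResult:
    """Factorial ANOVA of per-sample compound counts on age, sex, age x sex.

    Follows up with Tukey HSD over the four age-sex class means and reports
    per-class mean +/- SD.
    """
    meta = metadata_frame(metadata)
    missing = [s for s in counts if s not in meta.index]
    if missing:
        raise ValueError(f"counts for unknown samples: {missing}")
    data = meta.loc[list(counts)].copy()
    data["count"] = [counts[s] for s in data.index]
    classes = data["age_sex_class"].unique()
    if data.groupby("age_sex_class").size().min() < 1 or len(classes) < 2:
        raise ValueError("need >= 2 non-empty age-sex classes")
    model = smf.ols("count ~ C(age_class) * C(sex)", data=data).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        anova = sm.stats.anova_lm(model, typ=1)
    anova.index = ["age", "sex", "age*sex", "Residual"]
    # a term explaining zero variance has F = 0 even when the residual
    # mean square is also numerically zero (degenerate all-equal counts)
    total_ss = float(anova["sum_sq"].sum())
    zero_ss = anova["sum_sq"] <= 1e-12 * max(total_ss, 1.0)
    terms = anova.index != "Residual"
    anova.loc[zero_ss & terms, "F"] = 0.0
    anova.loc[zero_ss & terms, "PR(>F)"] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pairwise_tukeyhsd(data["count"].to_numpy(),
                                data["age_sex_class"].to_numpy())
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    group_stats = (
        data.groupby("age_sex_class")["count"]
        .agg(mean="mean", sd="std", n="size")
        .sort_index()
    )
    return CompoundCountResult(anova=anova, tukey=tukey, group_stats=group_stats)
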