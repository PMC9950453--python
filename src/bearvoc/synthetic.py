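"""Seeded generator of synthetic cutaneous-VOC peak tables.

Emulates the sampling design of a 12-bear field study: four body sites per
bear, paired replicate swabs for most bears, zero-inflated right-skewed peak
abundances, and plantable compound effects at the age-sex-class, individual
and body-site level.  Zeros arise from two mechanisms — true absence (a
compound's incidence) and detection-limit censoring — mirroring the
ambiguity of non-detections in real GC-MS peak tables.

The default design reproduces the study's bookkeeping exactly: 12 bears,
sample counts 8/8/4/8/8/4/4/2/8/8/8/8 (78 swabs), including the one bear
with an incomplete two-sample series, so that unbalanced-class and
exclusion code paths are exercised by every test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AgeClass,
    BodySite,
    CompoundID,
    Dataset,
    PeakTable,
    SampleMetadata,
    Sex,
    Stage,
    derive_age_class,
)

__all__ = [
    "BearDesign",
    "Effect",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "null_dataset",
    "table1_design",
    "simulate_study_dataset",
    "FAILED_SAMPLE_ID",
]

ALL_SITES = (BodySite.CHEEK, BodySite.FLANK, BodySite.HUMP, BodySite.PEDES)

#: the synthetic counterpart of the one field sample whose raw file failed
#: to convert (a pede replicate), dropped to reach the analysed n = 77.
FAILED_SAMPLE_ID = "Y862_pedes_2"


@dataclass(frozen=True)
class BearDesign:
    """One individual's sampling plan: replicates per body site."""

    individual_id: str
    sex: Sex
    age_years: int
    samples_per_site: int = 2
    sites: tuple[BodySite, ...] = ALL_SITES

    def sample_plan(self) -> list[tuple[BodySite, int]]:
        return [(site, r + 1) for site in self.sites
                for r in range(self.samples_per_site)]


def table1_design() -> list[BearDesign]:
    """The default 12-bear design (sample counts sum to 78).

    The two-sample bear contributed one cheek and one flank swab — the only
    allocation consistent with the study's per-site male sample counts.
    """
    return [
        BearDesign("Y861", Sex.F, 14, 2),
        BearDesign("Y866", Sex.F, 19, 2),
        BearDesign("Y865", Sex.F, 6, 1),
        BearDesign("Y867", Sex.F, 4, 2),
        BearDesign("Y742", Sex.M, 19, 2),
        BearDesign("Y868", Sex.M, 15, 1),
        BearDesign("Y743", Sex.M, 4, 1),
        BearDesign("Y744", Sex.M, 3, 1, (BodySite.CHEEK, BodySite.FLANK)),
        BearDesign("Y860", Sex.M, 4, 2),
        BearDesign("Y862", Sex.M, 4, 2),
        BearDesign("Y863", Sex.M, 3, 2),
        BearDesign("Y864", Sex.M, 3, 2),
    ]


@dataclass(frozen=True)
class Effect:
    """Multiplicative effect on a compound's detection odds and mean abundance.

    ``incidence_odds`` multiplies the odds p/(1-p); 0 forces absence and
    ``inf`` forces presence, which lets tests plant exactly-unique and
    signature-dominant compounds.
    """

    incidence_odds: float = 1.0
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.incidence_odds < 0 or self.abundance < 0:
            raise ValueError("effect multipliers must be non-negative")


@dataclass
class SimulationConfig:
    """Generative model parameters.

    Baseline per-compound incidence is Beta-distributed (right-skewed: most
    compounds are rare, a few are near-ubiquitous).  Detection is
    hierarchical: each bear carries a compound *repertoire* (one Bernoulli
    draw per compound per bear), and every swab of that bear then detects a
    repertoire compound with probability ``replicate_correlation`` — which
    therefore equals P(detected in one replicate | detected in its pair)
    while the marginal incidence stays at the baseline.  Because the
    repertoire is shared by all of a bear's swabs, body sites are
    exchangeable within a bear unless a ``site_effect`` is planted, while
    individuals genuinely differ (real individual-identity signal).

    Detected abundances are log-normal in arbitrary instrument counts; the
    detection limit matches the deconvolution area floor of the instrument
    workflow the design emulates (5000 counts).  Effects are keyed by
    age-sex class (e.g. ``"mature_M"``), individual ID, or body-site name,
    each mapping compound index -> :class:`Effect`.
    """

    n_compounds: int = 254
    design: list[BearDesign] = field(default_factory=table1_design)
    body_sites: tuple[BodySite, ...] = ALL_SITES
    incidence_alpha: float = 1.2
    incidence_beta: float = 3.0
    incidence_override: float | None = None  # fixed incidence for all compounds
    abundance_location: float = 12.0
    abundance_scale: float = 1.0
    class_effect: dict[str, dict[int, Effect]] = field(default_factory=dict)
    individual_effect: dict[str, dict[int, Effect]] = field(default_factory=dict)
    site_effect: dict[str, dict[int, Effect]] = field(default_factory=dict)
    replicate_correlation: float = 1.0
    detection_limit: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.replicate_correlation <= 1.0):
            raise ValueError("replicate_correlation must be in [0, 1]")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        for name, effects in [
            ("class_effect", self.class_effect),
            ("individual_effect", self.individual_effect),
            ("site_effect", self.site_effect),
        ]:
            for key, mapping in effects.items():
                for idx in mapping:
                    if not (0 <= idx < self.n_compounds):
                        raise ValueError(
                            f"{name}[{key!r}] references unknown compound "
                            f"index {idx} (pool size {self.n_compounds})"
                        )


@dataclass
class GroundTruth:
    """Planted generative parameters, for recovery tests."""

    compound_labels: list[str]
    baseline_incidence: np.ndarray
    abundance_mu: np.ndarray
    class_markers: dict[str, list[int]]
    individual_markers: dict[str, list[int]]
    site_markers: dict[str, list[int]]
    config: SimulationConfig

    def incidence_for(
        self,
        compound: int,
        age_class: AgeClass,
        sex: Sex,
        individual_id: str,
        site: BodySite,
    ) -> float:
        """Effect-adjusted detection probability for one compound/sample."""
        p = float(self.baseline_incidence[compound])
        odds_mult = 1.0
        cls = f"{age_class.value}_{sex.value}"
        for effects, key in [
            (self.config.class_effect, cls),
            (self.config.individual_effect, individual_id),
            (self.config.site_effect, site.value),
        ]:
            eff = effects.get(key, {}).get(compound)
            if eff is not None:
                odds_mult *= eff.incidence_odds
        return _apply_odds(p, odds_mult)


def _apply_odds(p: float, mult: float) -> float:
    if mult == 1.0:
        return p
    if mult == 0.0:
        return 0.0
    if math.isinf(mult):
        return 1.0
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    odds = mult * p / (1.0 - p)
    return odds / (1.0 + odds)


def _synthetic_compound_labels(n: int, rng: np.random.Generator) -> list[str]:
    """Plausible-looking mass@retention labels, unique by construction."""
    labels: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        mass = rng.integers(50, 300)
        rt = rng.uniform(1.0, 32.0)
        label = f"{mass}.0@{rt:.2f}"
        if label not in labels:
            labels.add(label)
            out.append(label)
    return out


def _repertoire_prob(p_target: np.ndarray, r: float) -> np.ndarray:
    """Bear-level presence probability giving marginal detection p_target.

    Marginal detection is pi * r, so pi = p_target / r, capped at 1 (the
    cap only binds for compounds with target incidence above r).
    """
    if r <= 0.0:
        return np.zeros_like(p_target)
    return np.minimum(1.0, np.asarray(p_target, dtype=float) / r)


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one synthetic dataset plus its generative ground truth.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical serialized dataset.
    """
    rng = np.random.default_rng(config.seed)
    labels = _synthetic_compound_labels(config.n_compounds, rng)
    if config.incidence_override is not None:
        p0 = np.full(config.n_compounds, float(config.incidence_override))
    else:
        p0 = rng.beta(config.incidence_alpha, config.incidence_beta,
                      config.n_compounds)
    mu = rng.normal(config.abundance_location, 0.75 * config.abundance_scale,
                    config.n_compounds)

    r = config.replicate_correlation
    metadata: list[SampleMetadata] = []
    columns: list[np.ndarray] = []
    for bear in config.design:
        age_class = derive_age_class(bear.age_years)
        cls = f"{age_class.value}_{bear.sex.value}"

        # bear-level target incidence (class and individual effects)
        bear_odds = np.ones(config.n_compounds)
        bear_abund = np.ones(config.n_compounds)
        for effects, key in [
            (config.class_effect, cls),
            (config.individual_effect, bear.individual_id),
        ]:
            for j, eff in effects.get(key, {}).items():
                bear_odds[j] *= eff.incidence_odds
                bear_abund[j] *= eff.abundance
        p_bear = np.array(
            [_apply_odds(float(p0[j]), float(bear_odds[j]))
             for j in range(config.n_compounds)]
        )
        # the bear's compound repertoire: one draw per bear, shared by all
        # of its swabs, so body sites are exchangeable within a bear
        repertoire = rng.random(config.n_compounds) < _repertoire_prob(p_bear, r)

        for site in bear.sites:
            n_reps = bear.samples_per_site
            present = repertoire
            abund_mult = bear_abund.copy()
            site_eff = config.site_effect.get(site.value, {})
            if site_eff:
                # site-marker compounds get site-specific presence
                present = present.copy()
                for j, eff in site_eff.items():
                    p_site = _apply_odds(float(p_bear[j]), eff.incidence_odds)
                    present[j] = rng.random() < _repertoire_prob(
                        np.array([p_site]), r)[0]
                    abund_mult[j] *= eff.abundance

            # per-swab detection: reliability r given repertoire presence
            if r >= 1.0:
                det = np.repeat(present[:, None], n_reps, axis=1)
            else:
                det = present[:, None] & (
                    rng.random((config.n_compounds, n_reps)) < r
                )

            raw = rng.lognormal(
                mu[:, None], config.abundance_scale, (config.n_compounds, n_reps)
            ) * abund_mult[:, None]
            raw = np.where(det, raw, 0.0)
            raw = np.where(raw >= config.detection_limit, raw, 0.0)

            for rep in range(n_reps):
                sid = f"{bear.individual_id}_{site.value}_{rep + 1}"
                metadata.append(
                    SampleMetadata(
                        sample_id=sid,
                        individual_id=bear.individual_id,
                        sex=bear.sex,
                        age_years=bear.age_years,
                        body_site=site,
                        replicate=rep + 1,
                    )
                )
                columns.append(raw[:, rep])

    table = PeakTable(
        [CompoundID(lab) for lab in labels],
        [m.sample_id for m in metadata],
        np.column_stack(columns),
        Stage.RAW,
    )
    truth = GroundTruth(
        compound_labels=labels,
        baseline_incidence=p0,
        abundance_mu=mu,
        class_markers={k: sorted(v) for k, v in config.class_effect.items()},
        individual_markers={k: sorted(v) for k, v in config.individual_effect.items()},
        site_markers={k: sorted(v) for k, v in config.site_effect.items()},
        config=config,
    )
    return Dataset(table, metadata), truth


def simulate_study_dataset(
    seed: int = 0, exclude_failed_sample: bool = True, **config_kwargs
) -> tuple[Dataset, GroundTruth]:
    """Default-design dataset, optionally minus the failed pede sample (n=77)."""
    dataset, truth = simulate_dataset(SimulationConfig(seed=seed, **config_kwargs))
    if exclude_failed_sample:
        dataset = dataset.drop_samples([FAILED_SAMPLE_ID], "failed file conversion")
    return dataset, truth


def null_dataset(n_samples: int, n_compounds: int, seed: int) -> Dataset:
    """Exchangeable samples with balanced random labels (type-I-error harness).

    Every abundance is drawn i.i.d. (Bernoulli(0.5) detection, log-normal
    counts), so any attached grouping is independent of the data by
    construction.  Samples are paired into pseudo-individuals with balanced
    random sex and age labels.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)
    labels = _synthetic_compound_labels(n_compounds, rng)
    det = rng.random((n_compounds, n_samples)) < 0.5
    values = np.where(det, rng.lognormal(10.0, 1.0, (n_compounds, n_samples)), 0.0)

    n_ind = (n_samples + 1) // 2
    sexes = rng.permutation((["F", "M"] * ((n_ind + 1) // 2))[:n_ind])
    ages = rng.permutation(([4, 15] * ((n_ind + 1) // 2))[:n_ind])
    metadata = []
    for i in range(n_samples):
        ind = i // 2
        metadata.append(
            SampleMetadata(
                sample_id=f"s{i + 1}",
                individual_id=f"ind{ind + 1}",
                sex=Sex(sexes[ind]),
                age_years=int(ages[ind]),
                body_site=ALL_SITES[i % 2],
                replicate=1,
            )
        )
    table = PeakTable(
        [CompoundID(lab) for lab in labels],
        [m.sample_id for m in metadata],
        values,
        Stage.RAW,
    )
    return Dataset(table, metadata)
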