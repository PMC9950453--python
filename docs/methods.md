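# Methods

This note documents the statistical procedures implemented in `bearvoc`,
the conventions chosen where several defensible readings exist, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Preprocessing chain

The canonical order is fixed and enforced through stage tags on the peak
table (`raw → zero_replaced → relative → transformed`); each step refuses
input at the wrong stage.

1. **Incidence filter.** A compound is retained if detected (abundance
   above the presence floor, default 0) in at least `⌈f·n⌉` samples,
   default f = 0.05 — with 77 samples this is 4. The threshold is never 0.
2. **Replicate rule.** Replicate swab pairs are identified by
   (individual, body site). Under the default `both_replicates` rule a
   compound's detections within a pair are zeroed unless present in both
   members; bears sampled once per site are left untouched, and all samples
   remain separate columns in every analysis. The numeric thresholds behind
   "present" are configurable because no universal convention exists; the
   default is any positive abundance.
3. **Zero replacement.** Remaining zeros become half the minimum positive
   entry of the filtered table — one global constant, computed *after*
   filtering so that discarded compounds cannot set the pseudo-count. A
   `per_compound` option (half each compound's own minimum) is provided
   since both conventions circulate in compositional workflows.
4. **Relative abundance.** Total-sum scaling; each sample column sums to 1
   within 1e−9.
5. **Square-root transform**, the usual variance stabilization for
   right-skewed relative abundances.

Presence/absence analyses (Jaccard, uniqueness classification) always use
the detection pattern *before* zero replacement: a pseudo-count is a
numerical device, never a detection. Per-sample compound counts use a
strict `> 0.50%` relative-abundance rule (a compound at exactly the
threshold does not count).

## Distances

Bray–Curtis is computed on the transformed relative abundances so that the
SIMPER decomposition (below) reconstructs exactly the distances analysed.
Jaccard uses the classical set form `1 − |A∩B|/|A∪B|`; it equals
`2b/(1+b)` for the binary Bray–Curtis b, an identity the test suite checks
exactly because the two are routinely confused. A sample with no
detections sits at distance 1 from every non-empty sample (the limit of
the set formula); two empty samples are rejected.

## PERMANOVA

The distance matrix D is Gower-centered, `G = −½·C·D²·C`, whose trace is
the total sum of squares. Model terms enter sequentially: each term's
cells are dummy-coded in full and appended to the cumulative model matrix;
the term's SS is `trace((H_k − H_{k−1})·G)` with H the orthogonal
projector, and its df is the rank increment. Nesting needs no special
machinery — coding every individual after sex yields the ID-within-sex
increment, and every (individual, site) cell after that yields
site-within-individual. On the balanced 8-bear subset of the default
design this reproduces the expected df ladder (1, 1, 1, 4, 24, residual
20 of 51).

P-values come from free (unrestricted) whole-row permutation: the
permuted statistic is `trace(ΔH·PGPᵀ)`, vectorized over permutation
batches. The estimator is add-one, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`,
with inclusive tie counting — p is never 0 and never below
`1/(n_perm+1)`. Within-stratum permutation is available as an option but
is not the default, since the emulated analysis used free permutations.
FDR adjustment is Benjamini–Hochberg; the family is the set of p-values
reported in one results table (all terms of all distance metrics run
together), mirroring the usual presentation.

The dispersion check embeds the samples by principal coordinates
(negative-eigenvalue axes subtract from squared centroid distances, with
small negatives clamped at zero), computes each sample's distance to its
group centroid, and compares groups by a one-way F-test. Singleton groups
are excluded with a warning.

Balanced subsampling keeps all samples of `n` randomly chosen individuals
of an over-represented age-sex class; `keep_individuals` pins a published
subset (e.g. the two young males whose retention yields 8 bears and 52
samples in the default design).

**Caveat — free permutations and replicate inclusion.** Including
replicate swabs as samples means the permutation units are swabs, not
bears. When individuals genuinely differ (as they do in the default
synthetic world and in real skin-VOC data), class-level terms (age, sex,
age×sex) inherit bear-level clustering and their permutation p-values are
anti-conservative relative to a bear-level analysis. This is a property of
the emulated analysis design itself, preserved deliberately; the nested
body-site term, by contrast, is tested within the structure that the
preceding ID term absorbs and behaves conservatively-to-nominal (its
rejection rate at α = 0.05 sits inside the 95% binomial band over 100
simulated null-site datasets).

## Non-metric MDS

Kruskal stress-1,
`stress = √( Σ(d̂ᵢⱼ − θᵢⱼ)² / Σ d̂ᵢⱼ² )`,
where d̂ are configuration distances and θ is the least-squares monotone
(isotonic) fit of d̂ against the input dissimilarity order. Ties use the
primary treatment: tied dissimilarities are pre-sorted by d̂, so the
monotone fit may split tied blocks. Optimization is by non-metric SMACOF
majorization from the best of 20 random starts plus one metric (principal
coordinates) start; `nmds_scan` additionally seeds each dimension with the
previous dimension's solution padded by a zero axis, which guarantees
weakly decreasing stress in k. Convergence tolerance is 1e−7 on the
majorization stress; non-convergence is flagged and the best configuration
is still returned.

Two goodness-of-fit flavours are reported because both appear in the
literature and published (stress, R²) pairs are not always mutually
consistent with either: the non-metric R² = 1 − stress² and the linear R²
(squared correlation of d̂ with θ). Group ellipses are covariance ellipses
on the first two axes scaled by the χ²(2 df) quantile at the requested
confidence (default 99%); groups under 3 samples are skipped, singular
covariances are flagged degenerate.

## SIMPER and univariate follow-up

For a pair of groups, compound k's contribution in a between-group sample
pair (i, j) is `|x_ki − x_kj| / Σ_m(x_mi + x_mj)`; averaging over all
between-group pairs gives contributions that sum exactly to the mean
between-group Bray–Curtis dissimilarity (tested to 1e−10). Percentages
are contributions over their sum × 100. The screen keeps compounds
contributing at least 2.0% (boundary inclusive). For designs with more
than two conditions SIMPER runs per condition pair; a compound is "of
interest" if it passes the cutoff in any pair, and the union is reported
with per-pair provenance — the pooling rule is a package convention, since
pooled published lists rarely state one.

Screened compounds are followed up with a sequential (type-I) linear-model
ANOVA of the transformed relative abundance on the same design terms as
the multivariate model, with Tukey HSD for omnibus follow-ups or
Bonferroni-corrected pairwise t-tests for figure-style contrasts.
Per-sample compound counts get a factorial age × sex ANOVA plus Tukey HSD
over the four age-sex classes, reported as mean ± SD per class.
Significance is α = 0.05 throughout.

## Uniqueness classification

Within a treatment (a named partition of samples into conditions), a
condition is an *anchor* for a compound iff the detected count equals the
condition size — an integer comparison, never floating point. Categories:

* no anchor → `not_classified` (excluded by the inclusion rule);
* ≥2 anchors → `dominant`;
* exactly one anchor, any detection elsewhere → `signature_dominant`;
* exactly one anchor, zero detections elsewhere → `unique`.

Dominant is tested before signature-dominant so the categories are
disjoint (a compound at 100% in two conditions also satisfies the literal
signature wording). Every non-individual treatment must have each
condition drawing on ≥2 individuals — the outlier control — and the
individual treatment waives it; individuals with incomplete series are
excluded from the individual treatment by configuration. The incidence
filter is *not* applied before classification by default (it belongs to
the distance-based analyses); this is configurable.

## Synthetic data: the stated world

The generator reproduces the bookkeeping of a 12-bear field design
exactly: per-bear sample counts 8/8/4/8/8/4/4/2/8/8/8/8 (78 swabs; four
body sites; paired replicates where counts allow), including one bear with
only a cheek and a flank swab — the only allocation consistent with the
published per-site totals — and a standard exclusion of one failed pede
file bringing the analysed set to 77.

Detection is hierarchical:

* per-compound baseline incidence `p ~ Beta(1.2, 3.0)` — right-skewed,
  most compounds rare, a few near-ubiquitous;
* each bear draws a compound *repertoire* (Bernoulli with probability
  `p/r` capped at 1), shared by all of its swabs;
* each swab detects a repertoire compound with reliability
  `r = replicate_correlation` (default 1.0), which makes
  `P(detected in one replicate | detected in its pair) = r` exactly while
  preserving the marginal incidence at p.

Detected abundances are log-normal: per-compound location
`μ_j ~ N(12, 0.75)` in log instrument counts (median ≈ 1.6·10⁵, the scale
of routine GC–MS peak areas) with scale σ = 1, censored to zero below the
detection limit (default 5000 counts, the deconvolution area floor of the
emulated instrument workflow — rarely binding at these abundances). Zeros
therefore arise from two mechanisms, true absence and censoring. Effects
are multiplicative on incidence odds (0 forces absence, ∞ forces
presence — used to plant exactly-unique and signature compounds) and on
abundance means, keyed by age-sex class, individual, or body site; site
effects default to empty.

Two defaults deserve explanation. With *any* per-swab detection noise
(r < 1) or frequent censoring, the both-replicates filter manufactures
identical post-filter supports within each replicate pair, which makes the
body-site-within-individual term structurally significant even with no
site effect — an artifact of the filter, not biology. The defaults
(r = 1, abundance location 12) describe a world of highly reliable
replicate swabs and well-quantified peaks in which the body-site term is
genuinely null, matching the design intent; lower r or location values
remain available for sensitivity analysis, and the filter's inflation
mechanism is itself worth knowing about when interpreting real data.

What a green test on this world does **not** establish: the generator has
no chromatographic artifacts (retention drift, co-elution), no
compositional correlation between compounds, no abundance dependence
between replicates beyond shared detection, and identical abundance
distributions across body sites; real data violate all of these to some
degree. `null_dataset` is flatter still — i.i.d. detections with balanced
random labels — and is used only for type-I-error calibration.

## Numerical conventions

* Rank decisions in projector construction use an SVD threshold of 1e−8
  relative to the largest singular value.
* Permutation batches of ≤256 keep the vectorized `trace(ΔH·PGPᵀ)`
  computation within tens of megabytes at n ≈ 80.
* Dissimilarity matrices are symmetrized and clipped to [0, 1] after
  validating symmetry to 1e−12; diagonals are forced to zero.
* Degenerate compound-count ANOVAs (all counts equal) report F = 0, p = 1
  for zero-SS terms rather than NaN.
* The 100% presence test is exact integer arithmetic.

## Known limitations

* Sequential (type-I) SS only; no type-II/III, no distance-based
  redundancy analysis, no variance components.
* Free permutation is the only default scheme; restricted schemes for
  nested terms exist as an option but exchangeability under nesting is the
  user's responsibility.
* The SIMPER pooling rule across multi-level designs is a convention (any
  pair ≥ cutoff).
* nMDS optimizes the majorization stress and evaluates stress-1 at the
  solution; for pathological tie structures a dedicated stress-1 optimizer
  could do marginally better.
* No raw GC–MS handling: the pipeline starts at an aligned peak table.
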