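# Methods

## Data model

The unit of analysis is the **use report**: one informant citing one
plant species for one use category, optionally annotated with plant
part (closed vocabulary: leaf, root, bark, stem, flower, seed, fruit,
latex, whole-aerial, or unknown), preparation and administration. A
`Survey` is a *deduplicated* collection of reports together with the
informant universe (size `N`) and the use-category universe (size
`NC`). Duplicate (informant, species, category) triples collapse to one
report with a logged warning — the classical indices are defined over
distinct triples, and deduplication makes the reading unambiguous.

`N` and `NC` are inferred from the data by default and can be fixed
explicitly. `NC` is deliberately never hard-coded anywhere: field
studies disagree internally about their own category counts often
enough that it must stay an input. Species identity is the
whitespace-normalized name string; WFO identifiers are carried as
opaque strings without online resolution.

## Sample-size design

`required_sample_size` evaluates the finite-population formula
`n = N_T / (1 + N_T·e_p²)` and rounds **up**. Rounding up is the
conservative sampling convention (rounding down would undershoot the
nominal precision) and reproduces the canonical worked value
(227 households at 5 % precision → 145). The "95 % confidence"
conventionally attached to this formula is narrative: the expression
contains no normal quantile, and the implementation computes exactly
the expression. `e_p = 0` is accepted only as a census flag and returns
`N_T`.

## Indices

With `FC_s` = distinct citing informants, `NU_s` = distinct cited
categories, and `R_s` = total deduplicated reports for species *s*:

* `UV_s = R_s / N` (summed per informant), `CII_s = R_s / N` (summed
  per category). **Under this data model UV and CII coincide**; they
  are computed through independent summation orders, asserted equal in
  the tests, and both emitted because the two columns have distinct
  lineages in the literature and readers expect both.
* `RFC_s = FC_s / N` is kept as an exact rational until formatting.
* `RI_s = (RFC-term + NU_s/NU_max)/2`. Two conventions exist for the
  RFC term: `raw_rfc` (the default) uses `RFC_s` unscaled; `normalized`
  uses `RFC_s/RFC_max`. Published tables are rarely explicit about the
  choice, and neither convention can be verified against a published RI
  column without the raw per-informant data, so the convention is a
  visible parameter and the output flags which was used. The default
  was chosen because reference rankings in the field's tables are more
  consistent with the unscaled term (a normalized term forces the
  top-cited species to RI ≥ 0.5 + RNU/2, which published tables
  contradict).
* `CVI_s = (NU_s/NC)·(FC_s/N)·CII_s ≤ CII_s ≤ NC` by construction.

Ranks (per RFC, RI, CII, CVI) are computed on unformatted values,
descending, with **competition ranking** (ties share the minimum rank);
display order is by descending RI with ties broken alphabetically.

Formatting: published index tables in this field typically **truncate**
toward zero rather than round (e.g. 68/145 = 0.46896 printed as 0.468).
`truncate_decimal` implements truncation via `decimal` arithmetic to
avoid float-representation surprises; `RoundingPolicy` binds either
truncation or round-half-up, per report. Regression-style tables
(coefficients, odds ratios) conventionally round instead; the logit
summary is left unformatted and the caller chooses.

## Reference citation dataset

`data/reference_citations.csv` is a digitization of the per-species
citation counts (and, for completeness, the printed index and rank
columns) of a published 51-species, 145-informant survey. Only the
citation and RFC columns are recomputable from each other; RI, CII, CVI
and the ranks depend on undeposited informant-level data and are
carried as reported values only. Three printed rows were internally
inconsistent (a citation count contradicting its own RFC and rank, and
two rows with a digit migrating between the identifier and the count);
they were reconciled in favour of the RFC/rank-consistent reading, and
one genuine erratum (two species sharing one WFO id) is kept verbatim.

## Capability perception

Statements are tallied, not respondents: one respondent may contribute
several instances. The default capability label set (affiliation,
bodily health, bodily integrity, emotions, life, senses/imagination/
thought, control over one's environment, plus a "practical reasons"
bucket for cost/speed/ease statements) is an **editorial
reconstruction** of the subset-of-Nussbaum-plus-bucket pattern common
in this literature; it is configuration-driven and should be replaced
by the project's actual coding frame. Validation rejects labels outside
the configured set, listing the allowed ones.

## Preference model

Binary logit fitted by Fisher scoring / IRLS. Defaults: at most 50
iterations, convergence when the largest absolute coefficient change
falls below 1e-8, step-halving (up to 30 halvings) so the
log-likelihood never decreases — the trajectory is recorded on the fit
object and asserted monotone in the tests. Standard errors come from
the inverse Fisher information at the optimum; z = estimate/SE;
two-sided p from the standard normal; odds ratio = exp(estimate);
significance stars at 0.001/0.01/0.05/0.1.

Degenerate inputs: a single-class outcome raises a separation error
up front; coefficients exceeding sup-norm 1e3, or IRLS weights
collapsing to a perfect 0/1 fit, raise a separation error during
iteration (complete/quasi-complete separation); a singular information
matrix for structural reasons raises an error naming the covariate
loading heaviest on the null space.

VIF screening regresses each covariate on all the others plus an
intercept; `VIF = 1/(1−R²)`, exact collinearity and constant columns
surfacing as infinite VIF. Covariates above the threshold (default 5)
are removed one at a time from the largest, recomputing after each
removal — removing one member of a correlated pair typically rescues
the other.

The Kolmogorov–Smirnov distributional check delegates to
`scipy.stats.ks_1samp` behind a thin domain-checked surface. A `log1p`
transform for right-skewed continuous covariates is provided but **off
by default**; the binary outcome is never transformed.

## Synthetic data

The survey generator assigns each species rank `r` a citation
probability `p_r = p₁·r^(−s)` (clipped to [1e-4, 1]) and lets every
informant cite each species independently — so distinct-informant
citation counts arise directly, without deduplication bias. Defaults
are calibrated to the packaged reference dataset at construction time:
`p₁ = 70/145 ≈ 0.483` (the observed top share) and `s ≈ 0.649`, the
free least-squares log–log slope over all 51 ranks. This calibration
reproduces the observed citation span (≈5–70 of 145) at the cost of
understating mid-rank shares — the real rank-frequency curve is not a
clean power law — so synthetic citation distributions are somewhat more
skewed than the reference. Versatility is popularity-linked: a species'
category pool is `1 + Binomial(NC−1, versatility·p_r/p₁)` and each
citing informant reports `1 + Binomial(pool−1, 0.3)` categories from
it. Plant parts are drawn from a leaf-dominated mix (leaf 0.40, bark
0.15, root 0.14, fruit 0.13, ...) typical of South Asian medicinal
floras.

The covariate generator draws independent covariates matching the
reference population's published summary moments (age 56.23 ± 15.42
clipped to 18–90; non-agroforestry income 64.59 ± 24.61 USD/month;
agroforestry income 36.6 ± 17.45; binary shares: male 42.75 %, loan
62.29 %, social-forestry 13.79 %, knowledge 57.42 %, beliefs 71.63 %,
ethnic-community membership 72.42 %), except one configurable positive
link raising the knowledge probability for ethnic-community members —
a deliberately synthetic correlation, clearly parameterized, not an
inferred one. Clip bounds for rows whose published min/max were not
cleanly legible were set at field-plausible values. Outcomes are
Bernoulli draws from the logistic law at a configurable true
coefficient vector; the default uses the field-scale coefficients of
the reference analysis' significant terms (agroforestry income
+0.1515, other income −0.1251, knowledge +1.3290, ethnicity +0.1132,
beliefs +0.0183) with intercept 1.675 chosen so classes are roughly
balanced at the covariate means.

The perception generator is exact by construction: it emits precisely
the requested enabler/barrier counts per capability, shuffled
deterministically and attributed round-robin to a respondent pool
(default 25 per group, matching the usual perception-survey arm size).

**What passing tests on synthetic data do and do not show.** They show
the implementations are mutually consistent, match independent oracles
(brute-force enumeration for the index table; closed-form and
statsmodels fits for the logit), and recover known generating
parameters at realistic sample sizes. They do not validate the
generators as models of any real community: real surveys have informant
heterogeneity, correlated covariates beyond the single modelled link,
non-power-law citation curves and coding noise that the generators
deliberately omit.

## Problem sizes in the tests

The brute-force oracle comparison runs on surveys of ≤5 informants ×
≤4 species × ≤3 categories (exhaustible by enumeration); the
full-pipeline smoke test runs 100 seeds at 30 informants × 12 species;
parameter recovery uses 200 replicates of n = 5000 respondents,
checking each true coefficient lies within 3 estimated standard errors
in ≥95 % of replicates, per coefficient. These sizes were chosen as the
smallest at which each property is meaningful.

## Known limitations

* Indices are computed on deduplicated reports; studies that count
  repeated mentions of the same triple would need a multiset variant.
* The RI convention ambiguity is surfaced, not resolved; published RI
  columns cannot be reproduced from citation counts alone.
* The logit is plain maximum likelihood: no survey weights, no
  mixed effects, no ordinal outcome, no small-sample (Firth)
  correction — separated data error out rather than being penalized.
* The capability label set ships as a documented reconstruction, not a
  canonical vocabulary.
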