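# ethnosurvey

Quantitative analysis of ethnobotanical field surveys: who cites which
medicinal plant for what, how culturally important each species is, and
what drives respondents to prefer herbal over allopathic (modern
pharmaceutical) treatment.

The package is aimed at ethnopharmacology and ethnobotany researchers
who collect informant interview data in communities that rely on
medicinal plants, and at methodologists who want the standard survey
indices and models as tested, scriptable building blocks rather than
spreadsheet formulas.

## What it computes

**Survey design.** For a finite frame of `N_T` households and precision
`e_p`, the required sample size is

    n = ceil( N_T / (1 + N_T · e_p²) )

**Ethnobotanical indices.** From a deduplicated table of use reports
(one informant × one species × one use category), with `N` informants,
`NC` use categories, `FC_s` distinct citing informants and `NU_s`
distinct cited categories for species *s*:

| index | definition |
|---|---|
| use value | `UV_s = Σ_i U_i / N` (U_i = informant i's reports for s) |
| relative frequency of citation | `RFC_s = FC_s / N` |
| relative importance | `RI_s = (RFC-term + NU_s/NU_max) / 2` |
| cultural importance | `CII_s = Σ_categories Σ_informants UR / N` |
| cultural value | `CVI_s = (NU_s/NC) · (FC_s/N) · CII_s` |

The RFC term of RI is either the raw `RFC_s` (default) or
`RFC_s / RFC_max` ("normalized"); both conventions circulate in the
literature, so the choice is an explicit parameter. Species are ranked
(descending, competition ranking) on each of RFC, RI, CII and CVI.
Published tables usually *truncate* index values at three decimals;
`truncate_decimal` and `RoundingPolicy` reproduce that formatting.

**Capability perception tallies.** Coded interview statements —
(respondent group, medicine evaluated, Nussbaum central capability,
enabler/barrier valence) — are tallied into capability × valence count
matrices per (user group, medicine) cell.

**Preference model.** A binary logit of herbal-vs-allopathy preference
(`1` = prefers herbal), fitted by iteratively reweighted least squares
with step-halving, after variance-inflation-factor screening
(`VIF_j = 1/(1−R²_j)`, covariates with VIF > 5 removed largest-first).
The report table carries estimates, standard errors, Wald z, two-sided
p with significance stars, and odds ratios `exp(β)`. Separated data
raise an explicit error instead of returning diverging coefficients.

**Synthetic data.** Seeded generators produce use-report surveys with a
Zipf-like citation rank law (calibrated to a packaged 51-species
reference citation dataset from a published field survey of 145
informants), respondent covariate tables matching that study
population's summary moments with a latent-logit outcome, and
perception statements that reproduce target tallies exactly — so the
whole pipeline runs and is testable without any raw field data.

## Worked example

```python
import ethnosurvey as es

# sample size for a 227-household frame at 5 % precision
es.required_sample_size(es.SamplingFrame(227, 0.05))   # -> 145

# synthetic survey -> index table
survey = es.generate_survey(es.SurveySimConfig(seed=7))
rows = es.compute_index_table(survey)
frame = es.index_table_to_frame(rows, es.RoundingPolicy("truncate", 3))
print(frame[["species_id", "fc", "nu", "rfc_fmt", "ri_fmt"]].head())
```

prints

```
         species_id  fc  nu  rfc_fmt  ri_fmt
  Terminalia arjuna  67   8    0.462   0.731
    Swertia chirata  49   4    0.337   0.418
        Cassia tora  20   4    0.137   0.318
Asparagus racemosus   7   4    0.048   0.274
 Ocimum tenuiflorum  22   3    0.151   0.263
```

i.e. under this seed 67 of 145 informants cited *Terminalia arjuna*
across 8 use categories, giving the top relative frequency of citation
(0.462 after 3-decimal truncation) and the top relative-importance
rank. Fitting the preference model on a synthetic respondent table:

```python
config = es.CovariateSimConfig(n=5000, seed=7)
table = es.generate_preference_frame(config).drop(columns="respondent")
fit = es.fit_logit(table, outcome="prefers_herbal")
print(fit.summary_frame().round(4))
```

recovers the generator's coefficients, e.g. knowledge of medicinal
plants `estimate 1.3052, odds ratio 3.69` against a true value of
1.3290: respondents with such knowledge have ~3.7× the odds of
preferring herbal treatment.

The same stages are available from the shell:

```sh
ethnosurvey sample-size --population 227 --precision 0.05
ethnosurvey simulate survey --seed 7 --out sim/
ethnosurvey indices --input sim/use_reports.csv --out table.csv
ethnosurvey logit --input prefs.csv --outcome prefers_herbal --out table3.csv
ethnosurvey run --config run.yaml
```

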