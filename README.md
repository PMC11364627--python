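# resptypes

Response-type fingerprinting of Likert questionnaires.

`resptypes` analyses multi-group rating surveys — the motivating application
is an international survey in which university students rated, on a 1–5
Likert scale, how strongly eight candidate drivers contribute to global
biodiversity loss (five established *main* drivers: habitat loss,
overexploitation, pollution, climate change, invasive species; three
*minor* distractor drivers with negligible real impact). Instead of
modelling a "typical questionnaire per country", the method clusters all
questionnaires into **response types** and then describes each country by
its **fingerprint** — the vector of proportions of each response type among
its respondents. This removes the country as a latent confounder of the
item ratings and turns country comparison into geometry on the probability
simplex.

## Method

For each questionnaire with main-item ratings *x*₁…*x*₅ and minor-item
ratings *y*₁…*y*₃:

1. **Imputation** — missing items are filled with the unweighted mean of the
   same item over the *k* = 8 nearest questionnaires, where the distance
   between two questionnaires is the Euclidean distance over the items both
   observe, rescaled by √(8 / #co-observed).
2. **Feature engineering** — the minor items are replaced by the
   discrimination score *D* = mean(*x*) − mean(*y*) ∈ [−4, 4], giving a
   6-dimensional feature vector (*x*₁…*x*₅, *D*). High *D* means the
   respondent separates real drivers from plausible-sounding distractors.
3. **Jitter** — i.i.d. Gaussian noise, mean 0 and variance 0.001, breaks
   exact duplicates ahead of hierarchical clustering (summaries are always
   computed on un-jittered features).
4. **Ward clustering** — agglomeration minimising the increase in total
   within-cluster sum of squares; the number of types *k* is chosen with
   the **gap statistic**: gapₖ = (1/B) Σ_b log Wₖ(ref_b) − log Wₖ(data)
   with B uniform reference datasets over the observed feature ranges, the
   one-standard-error rule, and the full curve returned for elbow
   inspection.
5. **Fingerprints** — country *c*'s fingerprint entry *i* is the proportion
   of its questionnaires in cluster *i*. Countries are compared by
   Euclidean fingerprint distance and summarised by a Ward dendrogram
   (Newick export).
6. **Index screen** — each fingerprint component is rank-correlated
   (Spearman) with external country indices (CO₂ emissions, EPI, GBI,
   number of invasive species, LPI); a cell is flagged *moderate* when
   |r| > 0.3 and *significant* when p ≤ 0.05.

A synthetic-data module generates questionnaire populations with exactly
this structure — a finite mixture of the eight published response-type
profiles, each item drawn from a Gaussian discretised onto the 1–5 grid and
moment-matched to the profile's printed mean ± SD, MCAR missingness, and
country indices constructed to a target rank correlation with a fingerprint
component — so every stage is testable at desk scale with known truth.

## Worked example

Simulate three countries mixing three well-separated reference profiles
(types 3, 6 and 7: "everything is minor", "textbook answer", "invasive
species dismissed"), then fit:

```python
import numpy as np
import resptypes as rt

profiles = rt.load_fixture("table2").loc[[3, 6, 7]]
config = rt.GeneratorConfig(
    profiles=profiles,
    country_fingerprints={
        "GER": np.array([0.5, 0.3, 0.2]),
        "POL": np.array([0.2, 0.5, 0.3]),
        "BRA": np.array([0.3, 0.2, 0.5]),
    },
    n_per_country={"GER": 150, "POL": 150, "BRA": 150},
    missing_rate=0.02,
    seed=7,
)
matrix, truth = rt.sample_questionnaires(config)

model = rt.ResponseTypeModel(matrix, min_country_n=25, seed=42)
result = model.fit(k=3)
print(result.summary())
```

```
Response-type clustering
============================================================
respondents: 450    countries: 3 (3 fingerprinted)
response types (k): 3   [fixed]

        climate_change exploitation invasive_species habitat_loss    pollution discrimination  size
type_id
1          4.84 ± 0.54  4.94 ± 0.24      4.34 ± 0.63  4.97 ± 0.18  4.76 ± 0.43    2.33 ± 0.49   148
2          4.78 ± 0.45  4.72 ± 0.48      1.40 ± 0.52  4.89 ± 0.33  4.20 ± 1.19    1.12 ± 0.69   159
3          2.52 ± 1.29  2.75 ± 1.14      2.39 ± 1.15  2.61 ± 1.24  2.72 ± 1.27   -0.37 ± 0.80   143
```

Fitted type 1 is the sharply discriminating "textbook" profile (all main
drivers ≈ 4.8–5.0, *D* ≈ 2.3), type 2 dismisses invasive species (1.40
versus ≥ 4.2 for the other main drivers), type 3 rates everything low with
*D* ≈ −0.4 — i.e. the three generating profiles, recovered with their
printed means to within sampling error. Downstream:

```python
print(result.fingerprints.round(3))        # country × type proportions
#              1      2      3
# country
# BRA      0.200  0.527  0.273
# GER      0.267  0.207  0.527
# POL      0.520  0.327  0.153

mapping, dists = result.match_to(profiles.assign(size=1))
# {1: 6, 2: 7, 3: 3}  — optimal assignment to the reference numbering

print(result.country_tree().to_newick())
# (GER:0.2275,(BRA:0.1980,POL:0.1980):0.0295);
```

The fingerprints reproduce the configured mixing proportions (POL is
type-6 dominated, BRA type-7 dominated, GER type-3 dominated), and the
dendrogram joins the two countries whose fingerprints are closest.
`result.correlate(index_table)` then screens components against a
country-index table, and `result.plot_gap()` / `result.plot_country_tree()`
draw the scree plot and dendrogram.

The same pipeline is available from the shell:

```sh
resptypes simulate --outdir sim --n 4000 --seed 1
resptypes run-all --responses sim/responses.csv --outdir out --seed 1
```

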