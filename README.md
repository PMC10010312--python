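# immunocentroid

Pretreatment tumor immunogenomic analysis of immunotherapy response for
bulk RNA-seq cohorts — the kind of retrospective analysis run on small
(~35-patient) high-dose IL2 or anti-PD-(L)1 renal-cell-carcinoma cohorts.
The package is aimed at computational biologists who need the full chain
— expression preprocessing, immune signature scoring, a cross-validated
nearest-centroid response classifier, a centroid subtype classifier, and
survival/response association statistics — as tested, reusable library
code, exercised end-to-end on synthetic cohorts with planted ground truth.

## What it computes

**Preprocessing.** Counts are filtered (≥ 10 reads in ≥ 5 samples by
default), then normalized in three fixed steps: `v = log2(1 + x)`;
per-sample upper-quartile scaling (each sample divided by its 75th
percentile of positive `v`, rescaled to the cohort mean quartile); and
per-gene median centering, so every gene's across-sample median is 0.

**Signature scores.** A signature score is the unweighted mean of the
normalized expression of the set's genes,

&nbsp;&nbsp;&nbsp;&nbsp;score(S, j) = (1/|S|) Σ<sub>g∈S</sub> x<sub>gj</sub>,

compared between responders (CR/PR) and non-responders (SD/PD) with the
two-sided Wilcoxon rank-sum test (exact for small untied groups) and a
pooled-variance t statistic. Overrepresentation of a query gene list in
annotated sets uses the hypergeometric upper tail with Benjamini–Hochberg
adjustment.

**Nearest-centroid response classifier.** From label-free candidates
(gene median ≥ 25th percentile of medians, variance ≥ 70th percentile of
variances), each leave-one-out fold ranks genes by the two-class t
statistic and keeps the top m/2 up- and m/2 down-regulated candidates;
class centroids c<sub>k</sub> and pooled within-class SDs s<sub>g</sub>
are fitted on the training fold and the held-out sample is assigned by
minimal standardized distance

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>k</sub>(x) = Σ<sub>g</sub> ((x<sub>g</sub> − c<sub>kg</sub>) / (s<sub>g</sub> + s<sub>0</sub>))².

The gene count m maximizes LOOCV accuracy (ties to the smallest m) and
the final model is refitted on all samples. A fixed-gene-list centroid
classifier (e.g. the 34-gene ccA/ccB renal subtype panel) with a
stratified 2/3–1/3 split is also provided.

**Outcomes.** ORR, disease-control and clinical-benefit rates;
Kaplan–Meier curves with medians; two-group log-rank; Cox proportional
hazards (Efron ties); Fisher exact, Kruskal–Wallis and multivariable
logistic association.

**Synthetic cohorts.** `simulate_cohort` draws negative-binomial counts
(var = μ + αμ², log-normal gene means) with planted gene programs whose
means are multiplied by 2^effect in responders, realistic CR:PR / SD:PD
splits, and exponential (optionally Weibull) survival whose hazard depends
on an immune-high flag. `simulate_contrasting_cohorts` produces an
IL2-like and an anti-PD-1-like cohort in which the myeloid program's
responder association flips sign while the effector program stays positive
in both.

## Worked example

```python
import immunocentroid as ic

cfg = ic.SimConfig(
    seed=0,
    program_specs=[("response_up", 20, 1.0), ("response_down", 20, -1.0)],
)
counts, clinical, truth = ic.simulate_cohort(cfg)
filtered, report = ic.filter_min_expression(counts)
norm = ic.normalize(filtered)

res = ic.NearestCentroidResponse.from_clinical(norm, clinical).fit()
print(res.summary())

rates = ic.response_rates(clinical)
print(f"ORR {rates.orr_percent}%  disease control "
      f"{rates.disease_control_percent}%  clinical benefit "
      f"{rates.clinical_benefit_percent}%")
```

prints

```
Nearest-centroid classifier
==============================================
classes:          CR/PR vs SD/PD
selected genes:   14
distance:         standardized (s0 = 0)
LOOCV accuracy:   1.000 at m = 14
top genes (|centroid difference|):
  G00254        +1.476
  G00679        -1.379
  ...

ORR 37%  disease control 54%  clinical benefit 43%
```

The classifier reaches perfect leave-one-out accuracy on this cohort with
a 14-gene model (its cross-validation trace over the 4–100 gene grid is in
`res.cv_trace`); the selected genes split between programs elevated
(positive centroid difference) and depleted in responders. The response
rates recompute the cohort's clinical table: 13 of 35 evaluable patients
with CR/PR gives a 37% objective response rate, adding the 6 SD patients
gives 54% disease control, and the 15 patients whose response or stable
disease lasted ≥ 6 months give 43% clinical benefit.

The same stages run from the shell:

```bash
immunocentroid simulate --seed 7 --outdir runs/sim
immunocentroid preprocess --counts runs/sim/counts.tsv --out runs/norm.tsv
immunocentroid train-response --norm runs/norm.tsv \
    --clinical runs/sim/clinical.csv --out runs/model.json
immunocentroid run --config run.yaml --seed 7   # full pipeline + manifest
```

## Layout

- `immunocentroid.simulate` — synthetic cohort generator with planted truth
- `immunocentroid.preprocess` — count filtering and normalization
- `immunocentroid.signatures` — signature scoring, group statistics, ORA
- `immunocentroid.centroid` — nearest-centroid classifiers (library
  functions plus the `NearestCentroidResponse` / `SubtypeCentroid`
  model classes)
- `immunocentroid.outcomes` — response rates and survival/association stats
- `immunocentroid.pipeline` / `immunocentroid.cli` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
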