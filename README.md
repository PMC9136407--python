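# assocmap

Multi-model association mapping for microbiome (and other compositional
or tabular) feature data.

A recurring problem in case/control microbiome studies: which metadata
variables belong in the linear model? Age, diet, delivery mode, probiotic
use and the disease itself are all correlated with one another and with
the community composition, so analysts routinely fit *several* candidate
models — a base model plus variants with additional covariates — and then
struggle to compare the results. An association that is "significant" in
one model and gone in the next is usually telling you something about
confounding, not about noise.

`assocmap` makes that workflow programmatic. It takes one merged table
(sample ID + metadata columns + feature abundance columns), a variable
schema, and a list of candidate model definitions, and produces aligned,
comparable results for all of them:

1. **Preprocessing** — total-sum scaling per sample, removal of features
   with post-TSS total < 1e-4, and the arcsine square-root transform
   y = arcsin(√x) (optional per model).
2. **Per-feature models** — for every feature and model, a multivariate
   linear model with treatment-coded fixed effects and optional random
   intercepts for grouping variables (e.g. subject ID in longitudinal
   cohorts): OLS with Wald t-tests, or REML mixed models with
   normal-approximation Wald tests.
3. **FDR** — one Benjamini–Hochberg family per model run across all
   features × terms; q < 0.2 is the default significance call.
4. **Comparison** — features significant in ≥ 1 model become rows of a
   model-blocked q-value matrix (the "birds-eye" heatmap), with
   non-significant entries retained so shifts are visible.
5. **Detail views** — per-association box/scatter plots with q-value
   brackets, and stratified (faceted) views that swap model q-values for
   within-panel two-sided Welch t-tests on all plotted samples.

A seeded synthetic-cohort generator (`assocmap.synth`) provides the
self-contained test bed: longitudinal cohorts with planted AST-scale
effects and a configurable disease↔probiotics confounding channel.

## Worked example: watching a confounded association shift

Generate a confounded cohort — 160 subjects × 6 visits, 50 taxa plus an
`unassigned` remainder, one taxon carrying a true +0.3 probiotic effect
(AST scale), probiotic use given to 60% of diseased but only 10% of
healthy subjects:

```sh
assocmap synth --scenario confounder --seed 7 --out cohort.tsv --truth truth.tsv
```

```
expectation: {'feature': 'g__taxon_00', 'confounded_variable': 'disease',
 'true_variable': 'probiotics_use', ...}
table: cohort.tsv (960 samples x 51 features)
```

Declare the variables (`schema.yaml`) and three nested models
(`models.yaml` — a model without `fixed:` inherits the previous one):

```yaml
# schema.yaml                       # models.yaml
sample_id: sample_id                # - name: basic
random: [subject_id]                #   fixed: [disease, delivery_mode, visit_age_mo]
fixed:                              #   random: [subject_id]
  disease: categorical              # - name: basic_diet
  probiotics_use: categorical       #   add_fixed: [diet]
  delivery_mode: categorical        # - name: basic_diet_pro
  diet: categorical                 #   add_fixed: [probiotics_use]
  visit_age_mo: continuous
reference:
  disease: control
  probiotics_use: Pro-
```

```sh
assocmap run --input cohort.tsv --schema schema.yaml --models models.yaml --out out
```

The comparison table (`out/comparison.tsv`) for the planted taxon:

```
model           feature      variable        level    q            significant
basic           g__taxon_00  disease         case     1.79e-08     1
basic_diet      g__taxon_00  disease         case     2.98e-08     1
basic_diet_pro  g__taxon_00  disease         case     5.76e-01     0
basic_diet_pro  g__taxon_00  probiotics_use  Pro+     0.0          1
```

Read bottom-up: in the two models that do not know about probiotics, the
taxon looks strongly disease-associated (q ≈ 2e-8) — because probiotic
use is concentrated in the diseased group. The moment probiotic use
enters the model it claims the association (q ≈ 0, coefficient ≈ 0.29 vs
the planted 0.3) and the disease q collapses to 0.58: the disease
"association" was the confounder's shadow. `out/heatmap.png` shows the
same story as the model-blocked heatmap, and

```sh
assocmap detail --input cohort.tsv --schema schema.yaml --models models.yaml \
    --model basic_diet_pro --feature g__taxon_00 --variable disease \
    --facet probiotics_use --out detail.png
```

renders the stratified box plot: within Pro+ and Pro− panels separately,
case and control distributions coincide (Welch t-test p-values replace
the model q-values on faceted plots).

## Library surface

Every CLI step is a plain function: `read_merged_table` /
`partition_columns`, `build_schema`, `prepare_features`, `run_model`,
`compare_models` / `filter_matrix`, `association_detail` / `facet_ttest` /
`render_detail`, `generate_cohort` / `confounder_scenario`, `run_pipeline`
and `export_report`. See `docs/methods.md` for the statistical model,
generator design, and numerical conventions.

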