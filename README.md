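# ethnosurvey

Quantitative analysis of comparative ethnobotanical surveys.

Ethnobotanical field campaigns produce *use reports*: one informant
attributing one use (food, medicinal, construction, ...) to one plant
species, often with the plant's provenance (home garden vs wild-collected).
This package turns a three-table survey — use reports, informants with
region/community/elevation/gender/age covariates, and a species inventory —
into the standard quantitative outputs of the field:

* **Consensus and importance indices.** Per use category, the informant
  consensus factor F<sub>IC</sub> = (N<sub>ur</sub> − N<sub>t</sub>) /
  (N<sub>ur</sub> − 1), where N<sub>ur</sub> counts use reports and
  N<sub>t</sub> distinct taxa. Per species: cultural importance
  CI = Σ<sub>u</sub> n<sub>s,u</sub>/n<sub>s</sub> (fraction of the
  species' reporting informants naming each category, summed over
  categories), use diversity UD = −Σ<sub>u</sub> p<sub>u</sub> ln
  p<sub>u</sub> (Shannon entropy of the species' reports over categories,
  in nats), and use value UV = reports / informants-asked. All are
  computed per region and pooled, with 95th-percentile ranking tables.
* **Informant ordination.** Bray–Curtis dissimilarities among informants in
  *plant-space* (which species they report) or *use-space* (which
  species-use pairs), embedded by non-metric multidimensional scaling
  (SMACOF with isotonic regression, Kruskal stress-1, classical-scaling
  first start plus random restarts). Informant covariates are fitted post
  hoc: continuous variables as vectors (OLS r²), categorical ones as
  factors (between/total sum of squares), with significance from
  whole-vector permutations and the add-one convention
  p = (1 + #{permuted ≥ observed}) / (1 + n_perm) — floor 0.001 at 999
  permutations.
* **Regional comparison.** Exact three-set Venn partitions of species and
  use inventories across the survey regions, consensus-vs-report-count
  summaries per category (optionally split by provenance), and
  species-level origin classes (exclusively wild / garden only / both).
* **Provenance trend.** A report-level logistic regression
  logit P(garden) = β₀ + β₁·metric, fitted by iteratively reweighted least
  squares, quantifying whether garden origin becomes likelier as species
  importance rises, with equal-count bins for plotting.
* **Synthetic surveys.** A seeded generator reproducing the statistical
  structure such analyses assume — three regions (34/63/74 informants),
  a 480-species pool with a large shared core, elevation-structured
  inventories, and a plantable garden–importance coupling — with a truth
  manifest, so the whole pipeline is testable against known ground truth.

## Worked example

```python
from ethnosurvey import (GeneratorConfig, generate_survey, category_summary,
                         compute_metrics_table, build_incidence_matrix,
                         bray_curtis, nmds_embed, envfit_vector)
from ethnosurvey.trend import trend_report

dataset, truth = generate_survey(GeneratorConfig(seed=42))

print(category_summary(dataset, "TK").sort_values("nur", ascending=False)
      .head(3)[["use_category", "nur", "nt", "fic"]].to_string(index=False))

inc = build_incidence_matrix(dataset, "plant_space").drop_zero_rows()
ordn = nmds_embed(bray_curtis(inc), k=2, n_restarts=20, seed=7)
elev = dataset.informants.set_index("informant_id")["elevation_m"]
fit = envfit_vector(ordn, elev, n_perm=999, seed=11, name="elevation_m")
print(f"stress = {ordn.stress:.3f}; elevation fit: r2 = {fit.r2:.3f}, p = {fit.p:.3f}")

for f in trend_report(dataset)[0]:
    print(f"{f.metric}: slope = {f.slope:.2f} (SE {f.slope_se:.2f}) -> {f.verdict}")
```

prints

```
  use_category  nur  nt      fic
          food 1079 288 0.733766
     medicinal  778 254 0.674389
utensils_tools  451 189 0.582222
stress = 0.182; elevation fit: r2 = 0.921, p = 0.001
uv: slope = 2.80 (SE 0.14) -> increasing
ci: slope = -0.06 (SE 0.16) -> flat
ud: slope = 1.10 (SE 0.11) -> increasing
```

Food carries both the most reports and the highest consensus in every
region; community elevation strongly structures which plants informants
report (the permutation p sits at its 0.001 floor); and the chance that a
report is garden-origin rises steeply with the species' use value — the
planted coupling (β₁ = 3 on UV) recovered within two standard errors —
while cultural importance shows no trend. (Use diversity co-varies with UV
in the generator, so its marginal slope is also positive; see
`docs/methods.md`.)

The same analyses run from the shell:

```sh
ethnosurvey all --seed 42 --out run/       # simulate + full pipeline
ethnosurvey simulate --seed 1 --out survey/
ethnosurvey validate survey/reports.csv survey/informants.csv survey/species.csv
```

Every run writes a `run_manifest.json` with the configuration, per-stage
seeds and a SHA-256 hash of each output file; identical config and seed
reproduce every output bit for bit.

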