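# carlit

Ecological-status assessment of rocky-shore water bodies from cartographic
macroalgal surveys, in the spirit of the CARLIT method and the EU Water
Framework Directive (WFD):

- **catalog** — community sensitivity levels (1–20) and geomorphology-specific
  reference quality values (EQi), shipped as editable CSV data files; compound
  labels (`Cor+Mgal`) are scored by the co-dominance averaging rule.
- **scoring** — per-sector quality ratios (SL/EQi), length-weighted water-body
  EQR (capped at 1), WFD status classes (bad/poor/moderate/good/high with
  bands 0.25 / 0.40 / 0.60 / 0.75, boundaries belonging to the lower class),
  community-dominance profiles and intra-seasonal consistency reports.
- **pressure** — Land Uses Simplified Index: LUSI = (Urb+Ind+Agr+FW) × coast
  factor; MA-LUSI-WB values pass through untouched.
- **varcomp** — REML fitting of the crossed random-effects model
  `EQR ~ mu + (1|Surveyor) + (1|WB) + (1|Year) + per-WB slope within Year`
  (diagonal slope covariance), P_samp variance fractions, conditional
  residuals-vs-fitted diagnostics, and AIC model comparison.
- **synthetic** — seeded generators for survey cartographies (community mix
  conditioned on a latent quality level) and EQR panels drawn from the
  random-effects structure, so every stage is testable offline.
- **io / cli** — CSV readers/writers with row-level validation, optional
  GeoJSON export, and a `carlit` command line.

## CLI

```sh
# score a survey CSV (Site, Morphology, NatArt, Length, Community)
carlit score --survey survey.csv -o out/           # writes eqr.csv, dominance.csv
carlit score --survey survey.csv --sl my_sl.csv --ref my_eqi.csv --no-cap -o out/

# classify an EQR table (Site, EQR)
carlit classify --eqr-table eqr.csv

# LUSI from pressure components (WB, Urb, Ind, Agr, FW, Coast[, MA-LUSI-WB])
carlit lusi --pressures pressures.csv

# variance components of an EQR panel (WB, Year, Surveyor, EQR)
carlit varcomp --panel panel.csv --structure wb,year,surveyor,wb_slopes

# synthetic data (JSON scenario optional; all fields have defaults)
carlit simulate survey --seed 3 -o survey.csv
carlit simulate panel --config scenario.json --seed 3 -o panel.csv

# full pipeline from a JSON config
carlit run --config run.json
```

`run.json` keys (all paths optional — present stages run): `output_dir`,
`survey`, `sensitivity_table`, `reference_table`, `pressures`, `panel`,
`cap` (bool, default true), `cap_sectors` (bool), `boundaries` (list of 4),
`structure` (term list string), `seed`, `geojson` (bool).

Simulation scenario JSON mirrors `SurveyScenario` / `PanelScenario` fields,
e.g. `{"wb_count": 2, "quality": [0.8, 0.4], "grs_mix": {"Low coast|Natural": 1.0}}`
for surveys and `{"n_wb": 50, "n_year": 10, "var_wb": 0.03, "var_residual": 0.004}`
for panels.

## Python API

```python
import carlit

catalog = carlit.default_catalog()
refs = carlit.default_references()

carlit.sensitivity_level("Cor+Mgal", catalog)      # 7.0 (co-dominance average)
carlit.reference_eq("Low coast", "Natural", refs)  # 16.6

sectors = carlit.simulate_survey(carlit.SurveyScenario(quality=0.7, seed=1), catalog)
result = carlit.waterbody_eqr(sectors, catalog, refs)
result.eqr, result.es_class

panel = carlit.simulate_eqr_panel(carlit.PanelScenario(n_wb=7, n_year=4, var_wb=0.03))
components = carlit.fit_reml(panel)
carlit.variance_fractions(components, rounded=True)   # P_samp percentages
```

## Notes

- REML estimates are optimized on the log-variance scale (L-BFGS-B, analytic
  gradients, 3 multi-starts, gradient-verified restarts); estimates below
  1e-10 × var(response) are truncated to exact zeros so boundary solutions
  are reported as 0.
- The per-WB slope-within-year term uses a diagonal covariance (one variance
  per water body); an unstructured covariance is not identifiable at typical
  panel sizes, and a warning is emitted whenever the parameter count is large
  relative to the number of observations.
- AIC comparison is computed on REML fits (identical fixed part across
  candidates); see `compare_models` docstring for the caveat.
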