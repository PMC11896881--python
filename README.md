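# thermomorph

Analysis pipeline for thermal physiology and thermal preferences of
colour-polymorphic grasshoppers, together with a synthetic-data generator
that emulates the full measurement design, so every stage is testable
end-to-end without external data.

The pipeline takes four kinds of raw inputs —

1. **heat-up traces**: internal thorax temperature every 5 s and external
   temperature every 20 s for ~13 min per individual,
2. **thermal-gradient tracks**: runway position every 10 min for 1 h, plus a
   five-point temperature calibration per runway,
3. **reflectance spectra**: 300–1000 nm, ten replicates per individual
   (five dorsal + five lateral),
4. an **individual metadata table** (species, sex, colour morph, body mass)

— and produces, for each of the six species × sex subsets:

* artefact-corrected mean spectra and mean-brightness summaries,
* heat-up speed (20–240 s) and equilibrium temperature (660–760 s) per
  channel,
* preferred temperatures (mean substrate temperature, minutes 30–60),
* morph-constrained bootstrap confidence intervals (1000 iterations,
  percentile method) for green−brown contrasts and brightness/mass
  Spearman correlations, both for summary statistics and as time-resolved
  curves with coherent confidence bands,
* an assumption-checked classical test table (t / Welch / Mann-Whitney /
  one-way ANOVA / Kruskal-Wallis with pairwise follow-ups, Pearson /
  Spearman), with an optional log-transform branch for heteroscedastic
  data.

## Layout

| module | role |
| --- | --- |
| `thermomorph.config` | `SimConfig` / `AnalysisConfig` / `PipelineConfig`, YAML round-trip |
| `thermomorph.synthetic` | cohort generator (Newton heating backbone, gradient tracks, spectra) |
| `thermomorph.spectra` | artefact correction, replicate aggregation, mean brightness |
| `thermomorph.gradient` | cubic runway calibration, position→temperature, preferred temperature |
| `thermomorph.physiology` | trace truncation, heat-up speed, equilibrium temperature |
| `thermomorph.inference` | morph-constrained bootstrap, percentile CIs, difference/correlation curves |
| `thermomorph.hypotests` | assumption checks and classical test selection |
| `thermomorph.pipeline` / `thermomorph.cli` | orchestration, tidy CSV outputs, CLI |
| `thermomorph.io` / `thermomorph.validate` | CSV schemas, input validation report |

## CLI

```bash
# generate a synthetic cohort and write the input CSVs
thermomorph simulate --seed 1 --out data/

# validate input files
thermomorph validate --data data/

# individual stages
thermomorph process-spectra --spectra data/spectra.csv --out brightness.csv
thermomorph calibrate-gradient --calibrations data/calibrations.csv --out fits.csv
thermomorph summarise-physiology --traces data/traces.csv --out physiology.csv
thermomorph bootstrap --data data/ --seed 1 -B 1000 --out results/
thermomorph tests --data data/ --out tests.csv

# everything at once (synthetic mode; add --data to run from files)
thermomorph run-all --seed 1 --out results/
```

All knobs (sample counts, mass/brightness distributions, heating-model
constants, windows, bootstrap size, CI level) live in a YAML config
mirroring `PipelineConfig`; pass it with `--config`.

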