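# mbmeta

Estimation-statistics pipeline for published *Drosophila* T-maze
short-term olfactory memory experiments: per-experiment effect sizes with
delta-method standard errors, DerSimonian–Laird random-effects
meta-analysis with driver/genotype subgroups and heterogeneity (I²),
hierarchical precision-weighted meta-regression with study clustering and
shared-control block covariance, driver cell-count regression, and
per-cell lobe-category models — plus a synthetic-data generator with
ground truth for parameter-recovery studies.

## Package layout

| module              | contents |
|---------------------|----------|
| `mbmeta.corpus`     | `ExperimentRecord`/`Dataset` model, CSV I/O, validation, the packaged review-table transcription (`table1_fixture()`), lobe-category and shared-control bookkeeping |
| `mbmeta.effects`    | raw-ΔPI and percentage-change effect sizes (delta-method SE), learning/rescue/heat-adjusted scale conversions |
| `mbmeta.meta`       | DL τ², random-effects pooling, subgroup analysis with between-group Q/I², Welch t-test, forest tables |
| `mbmeta.regression` | weighted GLMM (study clusters τ², shared-control ρ, precision weights), generalised R², residual driver effects, cell-count regression, per-cell models |
| `mbmeta.simulate`   | iteration-level synthetic corpora with truth sidecars; model-matched effect generator for estimator checks |
| `mbmeta.cli` / `mbmeta.plots` | command-line entry points and SVG figure rendering |

The packaged review table (`src/mbmeta/data/table1.csv`) transcribes the
published experiment characteristics — iteration counts and moderators
only; it carries **no PI values** (the printed table reports none), so
pooling commands need a corpus CSV with the `pi_*` columns filled.
The column contract is documented in `src/mbmeta/data/schema.json`.

## CLI

```sh
mbmeta counts                      # accounting totals for the packaged table
mbmeta simulate --out sim --seed 7 # synthetic corpus + truth.json
mbmeta effects  --input sim/synthetic.csv --out out/effects
mbmeta meta     --input sim/synthetic.csv --out out/meta --analysis-set rut
mbmeta regress  --input sim/synthetic.csv --cell-counts cells.csv --out out/reg
mbmeta report   --input sim/synthetic.csv --cell-counts cells.csv --out out
```

`cells.csv` is a two-column `driver,cell_count` table. Every command
writes a `manifest.json` (inputs, config hash, seed, version); reruns
with identical manifests produce identical outputs.

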