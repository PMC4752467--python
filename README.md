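# fingerqc

Quality-consistency evaluation of multi-batch chromatographic fingerprints:
similarity scoring and grading of common-peak area vectors, marker-compound
quantitation, DPPH antioxidant metrics (off-line IC50 and on-line
negative-peak activity fingerprints), and PLS/OPLS fingerprint–activity
regression, plus a seeded synthetic-data generator with known ground truth.

## What it computes

For each batch fingerprint `x` against the all-batch mean reference `y`:

- **S_F** — cosine similarity of the area vectors; **S_F′** — cosine of the
  peak-wise ratio vector against all-ones (equal peak weighting);
  **S_m = (S_F + S_F′)/2** — macro qualitative similarity.
- **C** — projection content similarity (%); **P** — total-content ratio
  corrected by S_F (%); **P_m = (C + P)/2** — macro quantitative similarity.
- **α = |1 − P/C|** — leveling coefficient, sensitive to sample/reference
  disproportion.
- An 8-grade quality classification (1 best): each of (S_m, P_m, α) is
  graded against nested bands and the final grade is the worst of the three.
- Multi-wavelength integration: root-mean-square of the per-channel values.

Supporting modules: retention-time clustering of per-batch peak tables into
aligned fingerprint matrices (`io_model`), calibration-curve quantitation
with percent-content normalization (`marker_quant`), DPPH inhibition / IC50
and reaction-coil activity-peak association (`antioxidant`), NIPALS PLS,
orthogonal-filtered PLS, PCA outlier screening and jack-knife intervals
(`chemometrics`), and the generator (`synthetic`).

The package bundles a published 23-batch reference dataset
(`fingerqc.datasets`): marker contents with IC50 values and the
per-wavelength similarity/grade table, used by the tests and the acceptance
report.

## CLI

```sh
fingerqc simulate --seed 1 --out data/           # synthetic dataset + ground truth
fingerqc sqfm --matrix data/matrix_260nm.csv --out sqfm.csv
fingerqc quantify --contents data/contents.csv --out markers.csv
fingerqc dpph --offline data/dpph.csv --out ic50.csv
fingerqc model --matrix matrix_260nm.csv --response ic50.csv --method opls --out model.json
fingerqc run --config run.yaml                   # full pipeline bundle
```

Exit codes: 0 success, 2 validation error, 3 computation error.

A minimal `run.yaml`:

```yaml
peak_tables: data/peak_tables.csv
contents: data/contents.csv
dpph: data/dpph.csv
out_dir: report/
rt_tolerance: 0.2
model_method: pls
model_components: 2
cv_folds: 7
seed: 1
```

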