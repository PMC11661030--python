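# genotoxpca

Principal-component scoring of genotoxic hepatocarcinogens from a
four-gene rat-liver expression panel.

## Background

Short-term rat-liver studies can flag genotoxic hepatocarcinogens (GTHCs)
well before a two-year bioassay. Four p53-pathway marker genes — **Bax**,
**Btg2**, **Ccng1** and **Cdkn1a** — respond coordinately to genotoxic
carcinogens but stay flat under non-genotoxic hepatocarcinogens (NGTHCs)
and non-genotoxic non-hepatocarcinogens (NGTNHCs). Projecting
control-normalized log2 expression ratios of the four markers onto the
first principal component of their correlation matrix collapses that
coordinated induction into a single score: strongly negative PC1 means a
genotoxic-like signature.

This package implements that workflow end to end:

* **Preprocessing** — per-animal log2 ratios against concurrent vehicle
  controls, averaged over the three rats of each dose group
  (`genotoxpca.preprocess`).
* **Correlation-matrix PCA** with deterministic sign orientation, as a
  scikit-learn transformer (`StandardizedPCA`).
* **A published fixed-coefficient model** (loadings, marker means and
  standard deviations, and a fixed decision value of −0.507) for scoring
  new compounds without refitting (`published_model`, `score_compound`).
* **Cutoff derivation and zone classification** — the midpoint between
  the highest GTHC score and the lowest non-genotoxic score splits the
  PC1 axis; three zones (GTHC / intermediate / non-genotoxic) are
  assigned per dose point (`GenotoxZoneClassifier`).
* **Evaluation** — separation and accuracy reports, and an augmentation
  workflow quantifying how much adding new dose points moves existing
  scores (`separation_accuracy`, `augment_and_rescore`).
* **A synthetic-study generator** reproducing the reference designs
  (69 dose points at 24 h, 63 at 29 days including intermediates) with a
  known additive ground truth, for testing and power exploration
  (`generate_study`).
* **A command-line interface** (`genotoxpca`) covering each stage plus a
  one-shot `run` pipeline.

## Worked example

Score a single compound profile (mean log2 ratios at one dose) with the
published fixed-coefficient model:

```python
import genotoxpca as g

profile = {"Bax": 1.20, "Btg2": 1.85, "Ccng1": 0.95, "Cdkn1a": 2.10}
res = g.score_compound(profile)
print(f"PC1 = {res.pc1:.3f}, PC2 = {res.pc2:.3f}")
print("below published cutoff:", res.pc1 <= g.PUBLISHED_CUTOFF)
```

```
PC1 = -2.176, PC2 = -0.100
below published cutoff: True
```

Run the full workflow on a synthetic study with the reference 24-hour
design (23 chemicals × 3 doses = 69 dose points):

```python
cfg = g.paper24h_config(seed=0)
table, truth = g.generate_study(cfg)
mat = g.expression_to_ratios(table, panel=g.builtin_panel("FOUR"))
labels = g.labels_for_rows(mat.rows)

model = g.StandardizedPCA(orient="labels").fit(mat.data, y=labels)
scores = model.score_frame(mat.data)
report = g.separation_accuracy(scores, labels)
print(f"dose points: {report.n_points}")
print(f"separable: {report.separable}, accuracy: {report.accuracy:.3f}")
print(f"derived cutoff: {g.zone_boundaries(scores, labels).cutoff:.3f}")
```

```
dose points: 69
separable: True, accuracy: 1.000
derived cutoff: -0.292
```

The fitted PC1 loadings on this synthetic study are nearly symmetric
across the four markers (−0.501, −0.499, −0.499, −0.501 for Bax, Btg2,
Ccng1, Cdkn1a), matching the coordinated-induction structure that the
generator encodes.

The same pipeline from the command line:

```bash
genotoxpca run --out demo --seed 0
head -4 demo/report.txt
```

```
labeled points: 69 (15 GTHC, 54 NGTHC+NGTNHC; 0 intermediate excluded)
PC1 extremes: GTHC max -1.054, non-genotoxic min 0.469
derived cutoff (midpoint): -0.292
separable: True
```

`demo/` also contains `ratios.tsv`, `scores.tsv` (with zone
assignments), `loadings.tsv`, `labels.tsv` and a provenance
`manifest.json`.

## A note on the two cutoffs

The package deliberately keeps two decision values apart:

* `derive_cutoff` computes the **midpoint rule** from data: halfway
  between the highest GTHC PC1 score and the lowest non-genotoxic PC1
  score.
* `PUBLISHED_CUTOFF = -0.507` is the **fixed published decision value**
  for use with the fixed-coefficient model.

Applying the midpoint rule to the published extreme scores (−1.168 and
−0.778) gives −0.973, not −0.507; the two constants are therefore never
conflated, and which one is in use is always explicit (see
`docs/methods.md`).

## Reproduction

All quantitative claims in this README are recomputed by the test suite
and the acceptance script:

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script is fully deterministic given `--seed` and writes a
JSON report of the package's headline quantities: published-model
geometry checks, reference design counts, eigendecomposition agreement
with an independent SVD route, synthetic separation accuracy, the
null-effect separability rate, closed-form error recovery, and
augmentation stability.

One test is expected to fail:
`tests/test_acceptance.py::TestReferenceScoreReproduction` documents
that the original per-dose-point ratio matrices needed to reproduce the
published PC1 values are not recoverable from the article text and are
not distributed here; the test fails rather than silently skipping.

## Layout

```
src/genotoxpca/
  types.py        enums, dose-point ids, validated table containers
  reference.py    built-in gene panels, chemical annotations, study designs
  io.py           TSV readers/writers (long expression + wide ratio layouts)
  preprocess.py   log2 ratios vs concurrent controls, replicate averaging
  pca.py          StandardizedPCA (correlation-matrix PCA, oriented signs)
  scorer.py       published model, cutoff derivation, GenotoxZoneClassifier
  evaluation.py   separation reports, augment-and-rescore
  simulate.py     synthetic-study generator and parameter recovery
  pipeline.py     one-shot run orchestration with provenance manifest
  cli.py          click-based command line
docs/methods.md   model equations, conventions, numerical choices, limitations
scripts/acceptance.py   deterministic headline-quantity report
```
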