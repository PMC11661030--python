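# Methods

This note defines the statistical models implemented in `genotoxpca`,
the conventions they rely on, and their limitations. Every numeric
claim here is recomputed by the test suite or by
`scripts/acceptance.py`; nothing below rests on unverified output.

## 1. Preprocessing: control-normalized log2 ratios

Input is a long-format table of per-animal expression values
(`chemical, dose, time, replicate, gene, value`), on either the linear
or log2 scale (linear values are log2-transformed first; the transform
is idempotent on already-log2 data by declaration, not detection — the
caller states the scale).

For each treated animal, the ratio against the *concurrent* control
group of the same chemical and time point is

```
r(animal, gene) = log2 x(animal, gene) − mean_c log2 x(c, gene)
```

where the mean runs over the control animals. The dose-group value is
the average of the per-animal ratios over the replicates (an
average-of-ratios, not a ratio-of-averages). With `n_t` treated and
`n_c` control animals and i.i.d. Gaussian log-scale noise of standard
deviation σ, the dose-group estimate has standard error

```
σ · sqrt(1/n_t + 1/n_c)        (= σ·sqrt(2/3) at n_t = n_c = 3)
```

because the control-mean subtraction contributes its own sampling
error. `theoretical_cell_rmse` implements this closed form, and the
Monte-Carlo recovery tests check the simulated RMSE against it (not
against the naive σ/√n, which ignores the control term).

Rows of the resulting matrix are dose points, labeled with compact ids
such as `DEN24hL` (chemical abbreviation, time point, dose letter);
columns are genes in panel order.

## 2. Correlation-matrix PCA

`StandardizedPCA` standardizes each gene column to zero mean and unit
variance (sample standard deviation, `ddof=1`), forms the correlation
matrix `C = ZᵀZ/(n−1)`, and eigendecomposes it with `numpy.linalg.eigh`.
Eigenvalues are sorted descending with a stable sort; components are
the corresponding eigenvectors. A constant column makes
standardization undefined and raises `DegenerateInputError` naming the
gene.

Eigenvector signs are arbitrary, so the fitted model applies a
deterministic orientation:

* canonical form first: each component's first nonzero coordinate is
  made positive;
* `orient="labels"` then flips PC1 so that the mean PC1 score of
  GTHC-labeled rows is negative (genotoxic = negative by convention),
  and on the four-gene panel flips PC2 so the Cdkn1a loading is
  negative, matching the published sign convention;
* `orient="loading-sum"` flips PC1 so its loading sum is negative
  (usable without labels, since marker induction loads all four genes
  with a common sign);
* `orient="none"` keeps the canonical form (used when comparing
  against an external decomposition).

The acceptance script cross-checks eigenvalues and loadings against an
independent SVD of the standardized matrix; agreement is at the
10⁻¹⁴ level, and the eigenvalue sum equals the number of genes (trace
of a correlation matrix).

## 3. The published fixed-coefficient model

For scoring new compounds without refitting, the package ships a
frozen model (`published_model()`, stored in
`src/genotoxpca/data/published_model.tsv`):

| gene   | PC1 loading | PC2 loading | μ (mean ratio) | σ (SD) |
|--------|------------:|------------:|---------------:|-------:|
| Bax    | −0.501      | 0.516       | 0.320          | 0.790  |
| Btg2   | −0.500      | 0.202       | 0.262          | 0.946  |
| Ccng1  | −0.516      | 0.079       | 0.562          | 1.166  |
| Cdkn1a | −0.483      | −0.828      | 0.402          | 1.352  |

Scores are

```
PC1 = Σ_g a1_g · (x_g − μ_g) / σ_g        (likewise PC2 with a2)
```

Consistency checks recomputed by the tests and acceptance script: the
loading vectors have squared norms 1.00055 and 0.99889 and dot product
−0.00036 (unit and orthogonal to rounding precision); a profile one σ
above every marker mean scores PC1 = −2.000; the all-ones log2 profile
scores −1.2288. Two constants in the source table contained obvious
typographical duplications of digits and are stored in their corrected
four-significant-figure form (σ(Bax) = 0.790, σ(Ccng1) = 1.166); the
consistency checks above are the evidence for those corrections.

## 4. Cutoff and zone classification

Given PC1 scores and class labels, `derive_cutoff` computes the
midpoint between the maximum PC1 among GTHC points and the minimum PC1
among non-genotoxic points (NGTHC and NGTNHC pooled;
intermediate-evidence chemicals excluded). Zones partition the PC1
axis:

* `PC1 ≤ gthc_max` → GTHC zone;
* `PC1 ≥ nongtx_min` → non-genotoxic zone;
* otherwise intermediate zone.

Boundary points belong to their class zone. If the boundaries are
inverted (classes overlap), zone classification refuses rather than
producing an ill-defined partition; separation *reports* remain
available and count each point against the midpoint cutoff, with a
point exactly at the cutoff counted as misclassified. Because the
cutoff is the midpoint of the two overlap extremes, any non-separable
configuration misclassifies at least those two points.

Two decision values coexist and are never conflated:

* the midpoint-rule cutoff derived from data;
* the fixed constant `PUBLISHED_CUTOFF = −0.507`, used only with the
  fixed-coefficient model.

Applying the midpoint rule to the published extreme scores (−1.168,
−0.778) yields −0.973 ≠ −0.507; the package stores the published value
as a literal and never recomputes it.

## 5. Reference study designs

`study_design` enumerates the dose points of the reference designs:
23 chemicals × 3 doses = 69 points at 24 h (78 with the three
intermediate-evidence chemicals), and 55 points at the 29-day repeat
time point (63 with intermediates), where four chemicals are absent
and three lack the high dose. These counts are asserted by the tests
and reported by the acceptance script.

## 6. Synthetic-study generator

`generate_study` emulates the reference design with an additive model
on the log2 scale:

```
log2 intensity = baseline(gene) + effect(class, dose rank, gene)
                 + Normal(0, noise_sd)
```

Defaults: baseline 10.0, noise SD 0.25, GTHC effect = 1.0 × dose rank
(rank 1/2/3 for low/middle/high) on every panel gene, zero effect for
NGTHC and NGTNHC. Intermediate-evidence chemicals respond per
`intermediate_mode` (`high_dose_only` or `half_magnitude`). Three
replicates per group and concurrent controls per chemical match the
reference design.

Each chemical draws from its own deterministic substream
(`np.random.default_rng([seed, crc32(abbrev)])`), so adding or removing
a chemical does not perturb the others' data — a property the tests
assert directly.

**Scope.** The generator is a test harness, not a biological model. It
encodes exactly the structure the pipeline assumes (coordinated linear
induction, homoscedastic Gaussian log-scale noise, no correlation
between genes beyond the shared class effect, no dose-independent
chemical effects, no outliers). Results on synthetic data therefore
validate the *implementation* — that the pipeline recovers known
structure at the predicted precision — not the biological claim that
four markers suffice for real compounds.

## 7. Numerical and I/O choices

* Sample statistics use `ddof=1` throughout.
* Eigendecomposition via `eigh` (symmetric), stable descending sort,
  deterministic sign policy (section 2); no randomized solvers.
* TSV parsing uses round-trip float precision, so save/load cycles are
  bit-exact and pipeline outputs are byte-identical across runs with
  the same seed (asserted by the tests).
* Unicode minus signs (−, –, —) in input tables are normalized to
  ASCII hyphens before parsing.
* All randomness flows from a single integer seed; derived seeds stay
  below 2³¹.

## 8. Limitations

* The published fixed-coefficient model is frozen at four genes and
  one tissue/species context; it must not be applied to other panels
  or designs without refitting.
* The midpoint cutoff depends on the two extreme points only, so it is
  sensitive to single outliers; the separation report exposes which
  dose points define the boundaries for exactly this reason.
* Reproduction of the original per-dose-point scores requires source
  ratio matrices that are not recoverable from the published summary
  statistics; the corresponding test fails by design rather than
  skipping (see `tests/test_acceptance.py`).
* Synthetic validation covers implementation correctness only
  (section 6); no claim about real-compound classification accuracy is
  made or tested here.
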