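# crypsis

Comparative analysis of camouflage: does animal colouration track the
colouration of the habitat, once shared evolutionary history, geography and
sampling artefacts are accounted for?

`crypsis` is built for comparative biologists working with specimen colour
measurements (museum skins or field photographs), remotely sensed habitat
reflectance, and a species phylogeny. It implements the full analysis chain
for phenotype–habitat colour matching in a clade of related species:

- **Colorimetry** — black/white-balance correction against ColorChecker
  references, patch means from specimen photographs, and total reflectance
  `L = 0.299 R + 0.587 G + 0.114 B` (ITU-R BT.601).
- **Habitat colouration** — per-pixel temporal averaging of multi-band
  reflectance rasters, buffer means around sampling points, and a
  two-period split for repeatability.
- **Phylogenetic eigenvector regression (PVR)** — the patristic distance
  matrix is double-centered (after a square-root transform, so that on an
  ultrametric tree the centered matrix equals the centered Brownian-motion
  covariance) and eigendecomposed; eigenvectors summarise relatedness as
  regression covariates. Eigenvectors are selected greedily until the
  Moran's *I* autocorrelation of trait residuals falls below a threshold
  (default 0.06).
- **Phylogenetic signal-representation (PSR) curves** — sequential R² of a
  trait on the leading *k* eigenvectors against the cumulative relative
  eigenvalue. The 1:1 line is the Brownian-motion expectation; a negative
  mean deviation means close relatives are *less* similar than Brownian
  motion predicts.
- **Partial least squares regression (PLSR)** — NIPALS PLS2 with single or
  multiple responses (a synthetic colouration variable combining R, G, B
  and L), Q² cross-validation for component retention, variable importance
  as variance-weighted squared weights (important if > 5% of response
  variance), and case-resampling bootstrap for coefficient standard errors
  and p-values.
- **Repeatability and classical tests** — one-way intraclass correlation
  τ = (MSB − MSW)/(MSB + (k−1)·MSW), sequential species ANOVA, partial
  Pearson correlations.
- **Synthetic data** — a generative model of the whole study (Yule tree,
  Brownian species effects, gradient habitat rasters, latitude and
  field/museum offsets) so every stage can be exercised and parameter
  recovery verified without the original specimens or imagery.

The package follows a Model/Results design: `PLSRegression(...).fit()`
returns a `PLSResults` with `summary()`, and the top-level
`CamouflageAnalysis(specimens, tree, config).fit()` returns an
`AnalysisResults` bundle with one table per analysis section.

## Worked example

Simulate a study of 460 specimens from 14 species and run the full
analysis:

```bash
crypsis simulate --out demo_data --seed 7
# wrote 460 specimens of 14 species to demo_data

cat > demo.yaml <<EOF
tree: demo_data/tree.nwk
specimens: demo_data/specimens.csv
bootstrap_B: 500
seed: 7
output_dir: demo_out
EOF
crypsis run --config demo.yaml
```

which prints:

```
Camouflage analysis (config e3894938b42a096b, seed 7)
  specimens: 460, species: 14
  species ANOVA: min F = 6.33 (fur), 0.92 (habitat)
  PSR mean deviation: red=-0.039, green=+0.081, blue=+0.062, L=-0.005
  selected eigenvectors: EV1, EV2
  global PLSR: 3 component(s), 60.7% variance explained
  variance partition: geography=15.8%, habitat=26.4%, origin=1.4%, phylogeny=17.1%
```

Reading the output: fur colour differs clearly among species (ANOVA
F = 6.3 on 13 df) while habitat does not in this draw (specimen locations
are spatially exchangeable by default); PSR deviations near zero are
consistent with Brownian-motion divergence of the species means; two
phylogenetic eigenvectors absorb the residual autocorrelation; and the
global multi-response PLSR explains 60.7% of fur-colour variance, of which
habitat colouration contributes the largest block (26.4 points) —
the generative habitat effect (`b_hab = 0.5`) recovered through the whole
chain, with geography, phylogeny and collection origin controlled.

The per-table output (ANOVA, PSR curves, eigenvector selection, global and
per-species PLSR with bootstrap SEs, correlations, metadata with config
hash and seed) lands in `demo_out/`.

The same analyses are available as a library:

```python
from crypsis.pipeline import CamouflageAnalysis, RunConfig
from crypsis.synthetic_data import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=7))
results = CamouflageAnalysis(ds.specimens, ds.tree, RunConfig(seed=7)).fit()
print(results.summary())
table = results.global_models["synthetic_colouration"].summary()
```

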