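# tmefib

Quantification of **tertiary lymphoid structures (TLS)**, **tumor-infiltrating
lymphocytes (TILs)** and **peritumoral fibrillary extracellular-matrix
morphology** in brightfield histology of basal cell carcinoma (BCC), for
researchers studying how stromal architecture modulates anti-tumor immunity.

TLS are ectopic lymphoid aggregates of T and B cells that arise near tumors
and are staged as *aggregate* (loose, T-dominant) or *primary* (B-cell
cluster without a germinal center).  The package quantifies three linked
questions on one lesion cohort:

1. **Prevalence** — which lesion characteristics (nodular/superficial/
   infiltrative subtype components, ulceration, body site, gender, age)
   associate with TLS presence?  2×2 odds ratios `OR = ad/bc` with Wald
   intervals `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` and Fisher exact tests.
2. **TLS maturation → TILs** — do tumors proximal (≤ 500 µm edge-to-edge) to
   primary-stage TLS carry more TILs?  Random-intercept linear mixed models
   (Laird–Ware) on Box-Cox or log transformed counts,
   `y_ij = x_ij'β + b_i + ε_ij`, `b_i ~ N(0, σ_g²)`, fitted by REML with
   Wald tests of the fixed effects.
3. **Fiber architecture → TILs** — thirteen fibrillary-matrix morphometrics
   (endpoints, branchpoints, their ratio, total/average fiber length, hyphal
   growth unit HGU = total length / endpoints, curvature, structure-tensor
   alignment, box-count fractal dimension, gliding-box lacunarity
   Λ = 1 + var/mean², density, high-density-matrix fraction, mean gap
   diameter) computed from a pruned skeleton graph of the segmented fiber
   mask; PCA of the standardized metrics followed by Ward clustering on the
   retained principal components (HCPC) and per-metric one-way-ANOVA cluster
   characterization (η², F-test).

Because the source imagery is not publicly deposited, a first-class
**synthetic generator** (`tmefib.synth`) produces calibrated IHC-like and
H&E-like slides, polygon annotations and cohort tables with known ground
truth — fiber networks as correlated random walks with von Mises
orientations, Beer–Lambert stain rendering, planted cell counts, and a
gamma-Poisson TIL model with a lesion random intercept — so every stage is
testable end to end.  A 30-lesion cohort table (covariates transcribed from
the published patient listing; per-lesion TLS status reconstructed to be
consistent with every published cross-tabulation) ships with the package.

## Worked example

```python
from tmefib.prevalence import load_table1, prevalence_table, lookup_or

tab = prevalence_table(load_table1())
print(lookup_or(tab, "nodular", "any_tls"))
```

prints

```
(10.285714285714286, 0.9723290037539605, 108.80670838665803, 0.04724011620563344)
```

i.e. lesions with a nodular component have odds ratio **10.29**
(95% CI 0.97–108.81, Fisher p = 0.047) for harboring a TLS — a ten-fold
enrichment that just touches the 95% boundary in a 30-lesion cohort.

The clustering route (`examples/05_hcpc_phenotype_clustering.py`) generates
64 stromal regions from two planted fiber phenotypes, measures all 13
morphometrics, and runs HCPC:

```
64 stromal regions, retained 7 PCs (98.9% of variance)
adjusted Rand index vs planted phenotypes: 1.00
...
pairwise TIL comparisons between clusters (Mann-Whitney):
 cluster_a  cluster_b  median_a  median_b  ...      U        p
         1          2      36.0      14.5  ...  422.5 0.006726
```

The long-fiber/high-lacunarity/low-density cluster (the permissive matrix)
carries significantly higher TIL counts than the dense aligned cluster — the
direction the analysis is designed to detect.

More narrative scripts live in `examples/` (one per capability:
prevalence, morphometrics, stain separation + segmentation, mixed models,
clustering, full pipeline).

## Command line

The pipeline is also exposed as a thin CLI over `tmefib.pipeline`:

```bash
tmefib all --out project --seed 7      # simulate → ... → report
tmefib table2                          # prevalence table from the packaged cohort
```

Stages (`simulate`, `deconvolve`, `segment`, `margins`, `morphometrics`,
`quantify`, `cluster`, `analyze`, `report`) read and write fixed artifact
paths under the project directory; every exclusion is logged with a reason
code.

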