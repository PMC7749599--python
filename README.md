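# cpcmorph

Longitudinal brain-structure analysis from tissue probability maps.  For
each voxel, a non-negative 4x4 matrix is fitted by non-negative least
squares over the surrounding 3x3x3 neighborhood, mapping the existence
probabilities of gray matter, white matter, CSF and background at
baseline to those at follow-up (108 stacked equations, 16 unknowns per
neighborhood).  Probabilities below 0.2 are excluded and survivors
renormalized before fitting; fitted elements are capped at 5.0 (the
reciprocal of the threshold).  Matrix elements averaged within labeled
volumes of interest feed ROC-based group discrimination and
PCA-reduced, cross-validated classification (linear/RBF SVM, random
forest, gradient boosting).

A synthetic atrophy phantom (parametric GM→CSF probability transfer at
tissue boundaries, partial-volume blur, simplex-projected noise) makes
the whole pipeline testable without real MRI.

## Modules

| module | purpose |
| --- | --- |
| `cpcmorph.phantom` | synthetic longitudinal probability-map pairs with ground truth |
| `cpcmorph.cpc` | thresholded, capped NNLS neighborhood fit (the core method) |
| `cpcmorph.voi` | VOI averaging of elements; direct probability-ratio baseline |
| `cpcmorph.stats` | rank-based AUC, region ranking |
| `cpcmorph.classify` | leakage-safe stratified CV with PCA + grid search |
| `cpcmorph.io`, `cpcmorph.cli` | NIfTI/manifest/config plumbing and the CLI |

## CLI

```sh
# synthetic cohort: volumes (NIfTI), manifest.csv, labels.nii, truth masks
cpcmorph simulate --out run/ --n-per-group 20 --groups NL=0.0,AD=0.6 --seed 1

# per-subject 16-channel element volume + validity mask + JSON sidecar
cpcmorph cpc --manifest run/manifest.csv --out run/cpc

# feature tables, ROC ranking, cross-validated classification report
cpcmorph analyze --manifest run/manifest.csv --cpc-dir run/cpc \
    --labels run/labels.nii --group-pair NL,AD --out run/analysis
```

Configuration (threshold 0.2, cap 5.0, neighborhood radius 1, 15 CV
folds, ...) can be overridden with `--config config.yaml`; see
`cpcmorph.io.PipelineConfig` for the keys.

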