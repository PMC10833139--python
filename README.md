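# mvintegrate

Multiview data integration in Python: prefilter each data view, associate two
views with cross-validated sparse canonical correlation analysis, predict a
clinical outcome from the learned canonical variates, jointly discriminate
classes across two or more views with sparse integrative discriminant
analysis (optionally structured by per-view variable networks), and compute
the tables behind the standard integration plots. Synthetic generators with
analytically known ground truth make the whole pipeline testable without any
external data.

## Components

| Module | What it does |
| --- | --- |
| `mvintegrate.core_data` | `MultiViewData`/`Outcome` containers, CSV/TSV loading with sample alignment, stratified train/test splitting |
| `mvintegrate.filtering` | log2/center/scale preprocessing; supervised (linear, logistic, t-test, Kruskal-Wallis) and unsupervised (variance, IQR) feature filtering with BH/Bonferroni adjustment; train-to-test propagation |
| `mvintegrate.selpcca` | sparse CCA: SVD initializer, l1/l-infinity sparsification (closed-form soft-thresholding), deflation for multiple components, CV threshold selection |
| `mvintegrate.prediction` | GLM (gaussian/binomial/poisson) and Cox outcome models on canonical variates; prediction; binomial/gaussian performance metrics |
| `mvintegrate.sida` | sparse integrative discriminant analysis for >= 2 views; normalized-Laplacian network variant; covariates as an unpenalized extra view; nearest-centroid classification |
| `mvintegrate.visualization` | volcano, UMAP, importance, discriminant, correlation, relevance-network, loadings and biplot tables + thin matplotlib rendering |
| `mvintegrate.synthetic` | latent-factor two-view generator (known canonical correlation), multiclass multiview generator (known Bayes error), support networks, survival outcomes |

## CLI

Every subcommand writes CSV/JSON outputs plus a `run_log.json` (parameters,
seed, version). A YAML file of per-subcommand defaults can be passed with
`--config`.

```bash
# synthetic two-view data with a planted sparse association
mvintegrate simulate --kind selp --n 200 --p1 100 --p2 100 --s1 10 --s2 10 \
    --sigma2 0.25 --seed 7 --out-dir sim

# supervised filtering on a stratified 80% training split
mvintegrate filter --views sim/view1.csv --views sim/view2.csv \
    --outcome sim/outcome.csv --method logistic --padjust --adjmethod BH \
    --alpha 0.05 --pct-train 0.8 --stratify --seed 7 --out-dir filt

# sparse CCA with 5-fold CV
mvintegrate selpcca --views filt/train_view1.csv --views filt/train_view2.csv \
    --test-views filt/test_view1.csv --test-views filt/test_view2.csv \
    --ncancorr 2 --folds 5 --seed 7 --out-dir cca

# outcome model on the canonical variates
mvintegrate selpcca-predict --model cca/selpcca_model.json \
    --views filt/train_view1.csv --views filt/train_view2.csv \
    --outcome filt/train_outcome.csv --family binomial --out-dir pred

# joint association + discrimination (add --networks adj1.csv,adj2.csv for the
# Laplacian-structured variant; adjacency as square CSV or i,j,weight list)
mvintegrate sida --views sim/view1.csv --views sim/view2.csv \
    --outcome sim/outcome.csv --folds 5 --seed 7 --out-dir sida

# plots (table CSV + PNG): volcano, umap, importance, discriminant,
# correlation, network, loadings, biplot-within, biplot-between
mvintegrate plot --kind network --model cca/selpcca_model.json \
    --views filt/train_view1.csv --views filt/train_view2.csv \
    --cutoff 0.58 --out-dir plots
```

## Notes on conventions

- Tables are samples x features, header row of feature names, first column
  sample identifiers; sample alignment across views is by ID intersection in
  first-view order.
- log2 transform is `log2(x + 1)`; IQR filtering uses type-7 quantiles;
  BH adjustment is the standard step-up rule.
- Canonical/discriminant loadings are unit-norm per component; CV ties within
  one standard error of the best score are resolved toward the sparser model.
- All randomness flows from the user-supplied `--seed`.
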