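# omicslink

Sequential integration of two molecular levels (e.g. SNPs and gene
expression, measured on partially overlapping patient sets) into a single
clinical survival risk-prediction signature.

## The problem

Molecular measurements from several platforms are increasingly available for
the same disease, but rarely for the same patients: one cohort may carry
genotypes, another expression profiles, and only a small subset both. A
risk-prediction model should nevertheless use both levels — and each level
should only contribute information the other does not already carry.

`omicslink` implements a stepwise strategy:

1. **First-level model.** Fit a sparse Cox proportional-hazards model to the
   first molecular layer on the samples where it was measured, with clinical
   covariates as mandatory (unpenalized) terms, by componentwise
   likelihood-based boosting. Condense the fit into a per-sample molecular
   *signature* — the molecular part of the linear predictor.
2. **Linking model.** On the samples measured on *both* layers, fit a
   continuous-response boosting model predicting the signature from the
   second layer, and use it to impute the signature for second-layer samples
   lacking first-layer measurements.
3. **Second-level model.** Fit the second layer's Cox boosting model with
   the (observed or imputed) signature as a fixed offset. The second layer
   then only picks up risk information *complementary* to the first.

A *reference* model — the identical second-level fit with zero offset —
quantifies what the adjustment changes, and the roles of the two layers can
be swapped to check whether the modeling order matters.

## Model

For sample $i$ with clinical covariates $z_i$, molecular features $x_i$ and
offset $o_i$, the hazard is

$$\lambda(t \mid x_i, z_i) = \lambda_0(t)\,
  \exp\!\left(z_i^\top \alpha + x_i^\top \gamma + o_i\right).$$

Boosting starts from $\gamma = 0$ and repeatedly updates the single feature
whose penalized one-parameter Newton step
$\hat\delta_j = U_j/(I_j + \lambda)$ most improves the Breslow partial
log-likelihood; the mandatory $\alpha$ is refit unpenalized after every
step. The number of steps — the only critical tuning parameter — is chosen
by cross-validation (held-out partial likelihood for Cox, held-out squared
error for the Gaussian linking model). The penalty defaults to a value
giving per-step shrinkage of roughly 0.1 and matters little beyond that.

Prediction performance is measured by inverse-probability-of-censoring
weighted Brier score curves combined over bootstrap resamples with the
.632+ estimator; selection stability by inclusion frequencies over
subsamples of size $\lfloor 0.632\,n \rfloor$ drawn without replacement,
re-running the entire model-building procedure (cross-validation included)
in every resample.

## Worked example

```python
from omicslink import (
    SimulationConfig, generate_two_layer_cohort,
    SequentialConfig, run_sequential, selected_features_report,
    evaluate_approaches, integrated_pec,
)

cfg = SimulationConfig(
    n_samples=160, k_layer_a=40, q_layer_b=40, n_clinical=3,
    n_true_a=4, n_true_b=3, effect_a=0.7, effect_b=0.5,
    clinical_effect=0.7, linkage=0.9, overlap_fraction=0.5,
    layer_a_kind="gaussian", seed=1,
)
cohort, truth = generate_two_layer_cohort(cfg)
result = run_sequential(cohort, SequentialConfig(n_steps_max=40, seed=1))
print(selected_features_report(result).to_string(index=False))
```

The cohort plants four hazard-driving features in layer A (`A0001`–`A0004`,
mirrored by the layer-B proxies `B0001`–`B0004`) and three layer-B-specific
features (`B0005`–`B0007`). The report shows the pipeline recovering this
structure:

```
        stage feature  coefficient
  first_level   A0001     0.103849
  first_level   A0002    -0.217761
  first_level   A0003     0.138707
  first_level   A0004    -0.179076
  first_level   A0009     0.268998
  ...
linking_model   B0001     0.068799
linking_model   B0002    -0.131295
linking_model   B0003     0.047158
linking_model   B0004    -0.126190
  ...
 second_level   B0005     0.247660
 second_level   B0007     0.152752
 second_level   B0002    -0.155244
  ...
```

The first level finds all four true layer-A features; the linking model
identifies exactly their four layer-B proxies; and after offset adjustment
the second level puts its largest weights on the layer-B-specific effects.
Comparing prediction error across approaches:

```python
curves = evaluate_approaches(cohort, SequentialConfig(n_steps_max=40, seed=1),
                             B=10, seed=1)
for name, c in curves.items():
    print(name, integrated_pec(c.times, c.e632plus, c.times.max()))
```

```
sequential integrated .632+ error: 0.1096
reference  integrated .632+ error: 0.1141
clinical   integrated .632+ error: 0.1498
km         integrated .632+ error: 0.1814
```

The same steps are available from the command line:

```bash
omicslink simulate --out data --n-samples 160 --seed 1
omicslink sequential --clinical data/clinical.tsv --layer-a data/layer_a.tsv \
    --layer-b data/layer_b.tsv --outcome data/outcome.tsv --out run1
omicslink evaluate   --clinical data/clinical.tsv --layer-a data/layer_a.tsv \
    --layer-b data/layer_b.tsv --outcome data/outcome.tsv --out eval1 --b 100
```

## Reproduction

All headline quantities — agreement of the boosting paths with an
independent brute-force implementation, the analytic reductions and error
identities, planted-feature recovery, the ordering of the four compared
approaches, and the overlap-size degradation — are recomputed from scratch
by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script is fully deterministic given `--seed` and finishes in roughly
ten minutes on one CPU. Methodological details, parameter defaults and the
benchmark study designs are documented in [docs/methods.md](docs/methods.md).
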