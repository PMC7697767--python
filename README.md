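# sdmlite

Presence-only species distribution modelling (SDM) at desk scale: occurrence
cleaning, pseudoabsence sampling, stepwise-AIC variable selection, a BIOCLIM
percentile envelope, a minimal maximum-entropy (maxent) model, maxSSS
thresholding, AUC evaluation, permutation importance and raster projection —
with a virtual-species simulator so the whole chain can be validated against
a known truth without downloading anything.

## Who it is for

Ecologists and biosecurity analysts who have georeferenced occurrence records
(e.g. a GBIF export) and a stack of aligned bioclimatic rasters (e.g. the 19
WorldClim layers, Bio1–Bio19), and want habitat-suitability maps and
presence/absence predictions with a fully reproducible, scriptable pipeline —
plus method developers who need a controlled synthetic testbed for SDM
algorithms.

## The models

Both models are *presence-only*: absences are replaced by random background
(pseudoabsence) points drawn from valid cells of the landscape.

**BIOCLIM percentile envelope.** For each climate variable $v$, the model
stores the empirical distribution of values at the training presences. A cell
with value $x_v$ gets the midrank percentile
$p_v = (\#\{t < x_v\} + \tfrac12\#\{t = x_v\})/n$, folded and doubled:

$$s_v = 2\,\min(p_v,\, 1-p_v),$$

so a value at the training median scores 1 and the score falls to 0 at the
envelope edges (0 outside the training min–max). The cell score is
$\min_v s_v$ — the most limiting variable. An optional `clamped10_90` mode
zeroes values outside the 10th–90th training percentiles.

**Minimal maxent.** The fitted distribution over the landscape is the Gibbs
distribution $P(x) \propto e^{\beta\cdot f(x)}$ closest to uniform subject to
matching feature expectations at the presences; $\beta$ maximizes the
L1-penalized log gain

$$G(\beta) = \frac1m\sum_{\text{presence}} \beta\cdot f(x)
  \;-\; \ln\!\sum_{\text{background}} e^{\beta\cdot f(x)}
  \;-\; \sum_j \lambda_j |\beta_j|,
  \qquad \lambda_j = \mathrm{rm}\cdot s_j/\sqrt{m}.$$

Features are linear, quadratic and pairwise-product transforms of the
min-max-scaled variables. The raw output is the relative occurrence rate
(ROR), which sums to 1 over the background; a logistic transform
$cr/(1+cr)$ with $c = e^H$ is also provided.

**Evaluation.** AUC is the Mann–Whitney rank statistic (probability that a
random presence outscores a random background point, ties counted half).
Continuous maps are binarized at the maxSSS threshold — the observed score
maximizing sensitivity + specificity. Permutation importance shuffles one
variable at a time (presences and background jointly), re-scores with the
unrefitted model and normalizes the AUC drops to percentages.

Both models follow the scikit-learn estimator convention (`fit`,
`predict`, `get_params`) and compose with sklearn tooling; the selector
`StepwiseAIC` implements `fit`/`transform`/`get_support`.

## Worked example

The packaged fixture is a 60×100-cell landscape with 6 correlated, spatially
smooth climate layers and a virtual species driven by two of them (`bio1`,
optimum 13 °C, σ = 1 °C; `bio4`, optimum 850 mm, σ = 60 mm), sampled at 400
occurrences:

```python
import numpy as np, pandas as pd
import sdmlite as sl

config, stack, species, occ = sl.load_default_fixture()
presence   = sl.extract_values(stack, occ.points, label=1)
background = sl.extract_values(stack, sl.sample_background(stack, 2000, seed=0), label=0)

folds = sl.kfold_partition(len(presence), k=5, seed=0)
train, test = presence[folds != 1], presence[folds == 1]

trace = sl.stepwise_aic(pd.concat([train, background], ignore_index=True), stack.codes)
print("selected variables:", trace.selected)

envelope = sl.BioclimEnvelope().fit(train[trace.selected])
report = sl.evaluate_scores(envelope.predict(test[trace.selected]),
                            envelope.predict(background[trace.selected]))
print(f"BIOCLIM  AUC={report.auc:.3f}  maxSSS threshold={report.threshold_maxsss:.4f}")

X = pd.concat([train[trace.selected], background[trace.selected]], ignore_index=True)
y = np.r_[np.ones(len(train), int), np.zeros(len(background), int)]
maxent = sl.MaxEntSDM().fit(X, y)
report_m = sl.evaluate_scores(maxent.predict_raw(test[trace.selected]),
                              maxent.predict_raw(background[trace.selected]))
print(f"maxent   AUC={report_m.auc:.3f}  maxSSS threshold={report_m.threshold_maxsss:.2e}")

grid = sl.project_maxent(maxent, stack)
binary = sl.apply_threshold(grid, report_m.threshold_maxsss)
print(f"cells predicted present: {int(np.nansum(binary))} of {stack.n_valid}")
```

prints

```
selected variables: ['bio1', 'bio3', 'bio4', 'bio5', 'bio6']
BIOCLIM  AUC=0.906  maxSSS threshold=0.0125
maxent   AUC=0.904  maxSSS threshold=7.08e-04
cells predicted present: 1410 of 5460
```

The stepwise search keeps both truth-driving variables (plus a few weakly
correlated ones — background cells share a latent climate field); both models
separate held-out presences from background with AUC ≈ 0.9; and maxent
permutation importance concentrates on `bio1` (43%) and `bio4` (56%), the two
variables that actually define the species' niche. Thresholding the maxent
ROR map at maxSSS marks about a quarter of the landscape as predicted
presence.

The same workflow runs from the shell — `sdmlite simulate` writes a fixture
bundle, `sdmlite run --config cfg.json` executes the full pipeline (clean →
background → select → fit → evaluate → threshold → project → importance) and
writes a JSON report plus continuous and binary rasters; each stage is also
its own subcommand.

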