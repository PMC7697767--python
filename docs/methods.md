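# Methods

This note documents the models, the synthetic study design, and the
numerical and design choices behind `sdmlite`, in the spirit of a package
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Presence-only species distribution modelling: given georeferenced occurrence
records and a stack of aligned bioclimatic rasters, estimate a habitat
suitability surface and binarize it into predicted presence/absence. True
absences are unavailable, so models contrast presences with *background*
(pseudoabsence) points sampled uniformly from valid landscape cells, and
evaluation uses presence-versus-background discrimination (AUC).

## Grid conventions

All point↔cell arithmetic goes through one function
(`ClimateStack.point_to_cell`). Row 0 is the northernmost row; cell (r, c)
covers the half-open box `[x0+c·res, x0+(c+1)·res) × (y0-(r+1)·res, y0-r·res]`
from the north-west corner `(x0, y0)`. Every boundary point therefore belongs
to exactly one cell, which keeps occurrence cleaning, background sampling,
extraction and projection mutually consistent. The validity mask is the
union of per-layer nodata: a cell missing in any layer is excluded
everywhere, so every retained point yields a complete climate vector.

Rasters are stored as ESRI ASCII grids (plain text, diffable — the format
used by all shipped fixtures) or single-band GeoTIFFs with standard
georeferencing tags. No reprojection or resampling is performed; inputs must
share one geographic grid, and any mismatch is an error rather than a silent
warp.

## Occurrence cleaning

Four rules, applied in order, each with a provenance count: (1) drop records
with missing coordinates; (2) drop coordinates outside ±180°/±90°; (3) drop
exact duplicate (lon, lat) pairs — equality is tested on the values as read,
with no rounding, and the first record in input order is kept; (4) drop
points whose containing cell is nodata in the reference stack. Rule 4 is the
operational definition of "on water": using the modelling grid's own mask is
reproducible and guarantees complete climate vectors, where a cross-check
against a separate world map would not be. Cleaning is idempotent, and the
retained count plus the per-rule drops always equals the input count.

## Sampling design

Background points are `n` distinct valid cells drawn uniformly without
replacement (cell centers; within-cell position is information-free because
extraction is cell-based). Restricting to valid cells departs from a literal
"random points on the globe" but matches standard practice: points without a
climate vector contribute nothing. Presences are split into `k` folds by
dealing a random permutation round-robin, so fold sizes differ by at most
one. The default `k = 5` reproduces the canonical 80/20 arithmetic: 9,246
presences split 7,397 train / 1,849 test when a minimal fold is held out.

## Variable selection

A binomial GLM (logistic regression of presence-vs-background) is fitted by
IRLS via statsmodels; predictors are standardized internally for
conditioning and coefficients are reported on the original scale. AIC is
`2k − 2 log L` with `k` counting the intercept. The stepwise search starts
from the full candidate set and at each step evaluates every single
addition and removal, applying the move with the largest AIC decrease
(ties break to the first candidate in input order) until no move lowers the
AIC. Quasi-separated candidate fits — easy to produce with global
presence/background tables — are re-maximized with standardized coefficients
bounded to ±15 and flagged `converged=False`; flagged fits are skipped as
stepwise moves and recorded in the trace. Exactly collinear candidates raise
an error naming the offending column (detected by a QR diagonal test).

## BIOCLIM envelope

Per variable, the midrank percentile of a cell value within the sorted
training-presence values, folded around the median and doubled; 0 outside
the training min–max; cell score = minimum over variables. Midrank tie
handling is symmetric and yields exactly 1.0 at an odd-n median. Min
aggregation (the most limiting variable) matches the classical
implementation of the algorithm. Two tail conventions exist in the
literature — a continuous doubled-percentile score, and a coarser variant
that zeroes anything outside the 10th–90th percentiles. Both are
implemented (`tails="continuous" | "clamped10_90"`); continuous is the
default because observed fitted thresholds in real studies (e.g. 0.005) can
only arise on the continuous scale. In clamped mode the cutoffs are applied
on the same midrank percentile scale (`p < 0.1` or `p > 0.9`), keeping the
two modes internally consistent; clamped scores are never above continuous
ones.

## Minimal maxent

A deliberately minimal maximum-entropy density estimator, not a port of the
reference program. Differences, chosen to keep the core small and
oracle-checkable: feature classes are linear, quadratic and pairwise
products of min-max-scaled variables (no hinge/threshold features), and the
per-feature L1 penalty is the single rule `λ_j = rm·s_j/√m` (`s_j` the
feature standard deviation over presences, floored at 1e-6 to keep constant
features penalized; `m` the presence count) rather than the reference
program's class-specific interpolation tables. Default `rm = 1`.

The objective — mean presence score minus log background normalizer minus
the L1 penalty — is concave; optimization is monotone FISTA (accelerated
proximal gradient with backtracking line search and momentum restart).
Only improving steps are accepted, so the recorded gain trace is
non-decreasing by construction, and the solution satisfies the L1 KKT
stationarity conditions (checked in tests to 1e-4). η is max-shifted before
exponentiation, and the shift is stored so projection onto new cells uses
the same normalizer.

Outputs: `raw` is the relative occurrence rate, a distribution summing to 1
over the background set; `logistic` is `c·r/(1+c·r)` with `c = exp(H)`, `H`
the entropy of the fitted background distribution — a monotone transform
that places a typical presence cell near 0.5 (and equals exactly 0.5
everywhere for the uniform model). Raw scores scale inversely with the
number of background points, so thresholds quoted on the logistic scale
(e.g. 0.38 in published work) are not comparable to raw-scale thresholds
(e.g. 0.005); both scales are exposed and the pipeline records which one it
thresholded.

## Evaluation

AUC is computed by midrank ranks (Mann–Whitney with tie correction,
O(n log n)); it equals the pairwise definition `P(presence > background) +
½P(tie)` and satisfies `auc(P,A) + auc(A,P) = 1`. The maxSSS threshold
scans every distinct observed score as a candidate with the rule "presence
iff score ≥ t" and returns the candidate maximizing sensitivity +
specificity, ties to the smallest threshold; the scan computes rates in
count form so mathematically tied objectives are bit-equal and the
tie-break is exact. Thresholds are selected on the held-out fold plus the
background sample (whether real studies used train or test partitions for
this is typically unstated; test is the defensible default and is
configurable). Permutation importance permutes presence and background rows
jointly and does not refit, per the usual definition for black-box SDM
evaluation; negative AUC drops are clipped at zero and drops are normalized
to percentages (all-zero drops give all zeros). `n_reps` defaults to 10 to
tame Monte-Carlo noise.

## Virtual-species simulator

Each climate layer is seeded Gaussian noise smoothed with a Gaussian kernel
(`length_scale`, in cells), optionally mixed with a shared latent field
(`correlation` weight) to induce inter-layer dependence, standardized and
affinely rescaled to a declared unit range (temperature-like °C ranges and
precipitation-like mm ranges alternate). The validity mask is a full
rectangle with an optional carved "ocean" block. The species responds to a
subset of variables through a Gaussian product,
`truth = Π_v exp(−(x_v−μ_v)²/(2σ_v²))` — a product, so every used variable
is limiting, mirroring the envelope model's min-aggregation logic and the
unimodal occurrence–climate profiles seen in real occurrence data.
Occurrences are valid cells sampled without replacement with probability
proportional to truth (default), or the top-n truth cells; cell centers are
returned so the true suitability of every record is exactly computable.

The packaged default fixture is a 60×100 grid (cell 0.5°), 6 layers,
`length_scale` 2 cells, correlation 0.15, with `bio1` (optimum 13 °C,
σ = 1 °C) and `bio4` (optimum 850 mm, σ = 60 mm) driving the species, 400
probabilistic occurrences, seed 20201111. The niche breadths are ≈3% of
each layer's range — a strongly climate-limited species. This design was
fixed once, at fixture-design time, such that the end-to-end recovery
properties (held-out AUC, truth rank-correlation, envelope medians,
selection and importance recovery) hold with margin; the fixture ships as a
config JSON and is regenerated deterministically at load, which keeps the
repository free of bulky raster files and makes "regenerate = identical"
a tested property.

What the simulator does *not* emulate: spatially biased sampling effort,
detection error, temporal dynamics, non-Gaussian (e.g. skewed or bimodal)
niche responses, and the heavy-tailed value distributions of real
precipitation layers. Passing the recovery tests therefore shows the
pipeline is correct and well-calibrated under a known smooth niche — not
that any real species' range is predicted accurately.

## Pipeline and determinism

One config drives clean → extract → background → k-fold split → stepwise
selection (on training presences + full background; the selected subset
feeds both models) → model fits on the training fold → held-out evaluation
→ maxSSS threshold → global and per-region projection (continuous + binary)
→ maxent permutation importance → JSON report with a file manifest. The
single config seed derives one sub-seed per named stage (CRC32 of
`"seed:stage"`, kept below 2³¹), so stages are independently reproducible
and two runs with the same config produce byte-identical reports. Models
are fitted on the training split only (refitting on all data before
projection is a config switch away in library use). Any stage failure
aborts with the stage name and writes the partial report of completed
stages.

## Known limitations

- The maxent variant omits hinge features, cloglog output, replicate
  averaging and tuned regularization; its raw/logistic outputs are
  comparable to the reference program's only qualitatively.
- Stepwise AIC on strongly collinear candidate sets is order-dependent at
  ties (the documented first-in-input-order rule) and is not a substitute
  for substantive variable screening.
- The empirical maxSSS threshold converges at the cube-root rate, so on
  small evaluation sets it is noisy; the reported sensitivity/specificity
  at the threshold are in-sample for the evaluation fold.
- No spatial cross-validation: random folds share spatial autocorrelation
  between train and test, which inflates AUC on smooth landscapes (real and
  synthetic alike).
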