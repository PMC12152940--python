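# Methods

This note documents the models, the numerical choices, the synthetic-data
regimes and the limits of what the test suite demonstrates.

## Curve fitting (regression mode)

Each molecule's measurements are clipped into [0, 100] (values below 0 set
to 0, above 100 to 100) so that every response is representable by a Hill
curve with asymptotes fixed at 0 and 100, and then fitted by bounded
least squares (`scipy.optimize.curve_fit`, trust-region reflective) to the
2-parameter Hill equation. Conventions and safeguards:

* All EC50 arithmetic is on the log10 scale; the machine-learning target is
  the fitted LogEC50, never the linear EC50.
* Search bounds: LogEC50 within [log10(0.1·min tested conc),
  log10(10·max tested conc)] — one decade beyond the tested span on either
  side — and HillSlope within [0.1, 10]. These are also the Bayesian prior
  ranges, so the two analyses explore the same parameter space.
* Initialisation at the midpoint of the log-concentration span with slope 1;
  the fit is restarted from five LogEC50 grid points and, as a last resort
  that cannot fail, compared against a 200×12 coarse-grid search; the
  lowest-SSE solution wins. The grid fallback matters for flat or extremely
  noisy sets where a local optimizer can stall.
* With fewer than three distinct concentrations the slope is not estimable;
  it is fixed at 1 (the default slope) and only LogEC50 is fitted
  (`slope_fixed=True` in the results).
* The fit-quality metric is z = SSE / n over all n measurements, replicates
  included. Dividing by total measurement count (not distinct-concentration
  count) means z estimates the per-observation residual variance, which is
  what the weighting transform should see.
* Inhibition assays use the mirrored, strictly decreasing curve with the
  same midpoint semantics, selected by a direction flag; the fitting
  machinery is otherwise identical.
* Clipping is applied to experimental responses both before fitting and
  before test-time RMSE computation, for consistency between what models are
  trained toward and what they are scored against.

## Bayesian analysis

Measurement noise is modelled as i.i.d. Gaussian. Its variance is the pooled
within-group variance over all (molecule, concentration) groups with ≥ 2
replicates, σ² = Σ(n_g−1)s²_g / Σ(n_g−1); if no group qualifies (or the
pooled estimate degenerates to 0, which would make the likelihood singular)
a configured fallback variance is used and flagged. The posterior over
(LogEC50, HillSlope) is evaluated on a grid of 100 LogEC50 values —
uniform in log10 between the prior bounds, matching the Hill
parameterisation of a multiplicative concentration range — crossed with 10
slope values uniform on [0.1, 10], under uniform priors (which therefore
cancel). Likelihoods are computed and normalized entirely in log space
(`logsumexp`), so molecules with hundreds of measurements cannot underflow
the grid. The reported target is the mean, and the quality metric the
variance, of 1000 draws of LogEC50 from the grid (drawing mirrors the
method's definition; an `exact=True` mode returns the grid moments directly
and is used in tests where Monte-Carlo jitter is unwanted). Posterior
summaries are of LogEC50, not linear EC50, consistent with the ML target.

## Quality-aware learners

The single transform p_i ∝ exp(−α z′_i) (normalized to sum to 1) converts
quality metrics into selection probabilities. By default z′ = z / mean(z):
raw z values differ by orders of magnitude between assays, and mean-scaling
makes the fixed α grid {0, 0.33, 1, 2} comparable across datasets; a raw
mode is retained. α = 0 gives the uniform distribution exactly, so every
quality-aware model degenerates structurally to its quality-blind twin.

All five forest variants share one ensemble engine over scikit-learn
decision trees (250 trees by default, fixed across compared models so
ensemble size never confounds a comparison):

* **RF** — uniform bootstrap + random feature selection (`max_features` as a
  fraction of features).
* **PB-RF** — the bootstrap draws n points with probabilities p_i.
* **W-RF** — uniform bootstrap, but per-sample case weights n·p_i enter the
  split criterion (weighted variance reduction) and the leaf means. Any
  mechanism producing weighted splits and weighted leaf means is acceptable;
  case weights are how scikit-learn trees express it.
* **OS-RF** — random feature selection is disabled (all features considered)
  and each tree instead sees targets y_i + e_i, e_i ~ N(0, β), fresh per
  tree. β is read as a variance.
* **VOS-RF** — per-point smearing variance β·n·exp(+α z′_i)/Σ_j exp(+α z′_j):
  worse-fitted points are smeared more, the mean variance across points is
  exactly β ("β controls the average amount of smearing"), and α = 0 reduces
  to OS-RF exactly. The alternative literal rule variance = β·p_i is shipped
  behind `smear_mode="literal"`; it assigns *more* smearing to
  better-fitted points, which contradicts the stated intent of the method,
  so the intent-honouring rule is the default.

`min_samples_split` fractions convert to counts by round-half-up with a
floor of 2 (2.5% of 500 → 13). Every stochastic fit takes one integer seed;
per-tree RNG streams are spawned from a single `SeedSequence`, so refits are
bit-reproducible, and the α = 0 / β = 0 degeneracies hold prediction-for-
prediction under shared seeds because the degenerate variants perform the
identical sequence of random draws.

SVR and WSVR are epsilon-insensitive RBF-kernel regressions with
scikit-learn defaults apart from the tuned ε; WSVR multiplies each sample's
loss penalty by n·p_i. Neither uses randomness.

## Tuning and evaluation protocol

Hyperparameters come from fixed grids (`max_features` {0.1, 0.33, 0.5, 1.0};
`min_samples_split` {1%, 2.5%, 5%, 10%}; α {0, 0.33, 1, 2}; β {0.25, 1, 1.5,
2.5}; ε {0.05, 0.1, 0.2, 0.5}), searched by sampling 20 combinations —
without replacement, the grids being small — and scoring each by k-fold CV
mean squared error on the LogEC50 targets. cv_folds defaults to 5 (standard,
and stable at the dataset sizes involved). Ties go to the earliest-sampled
combination.

Splits are at the molecule level (75/25 for uniform-grid screens, 50/50 for
the large heterogeneous regime). Evaluation never fits curves to test data:
the model's predicted LogEC50 with slope 1 — the default slope, since test
molecules carry no slope information — yields a predicted response at each
held-out measurement's log concentration, and the score is the RMSE over all
held-out pairs. Uncertainty is a bootstrap SD over individual pairs (the
unit of the RMSE), and paired models are compared by a one-sided Wilcoxon
signed-rank test on per-measurement squared errors: zero differences
dropped, exact null for ≤ 25 informative pairs when ranks are untied,
normal approximation otherwise, significance declared at p < 0.001 (a
deliberately strict level so that "significantly better" claims are rarely
type-I errors).

## Synthetic-data regimes

The generator produces Bernoulli(0.1) fingerprint-like bit vectors, maps
them through a sparse linear function to a true LogEC50, and simulates
responses as Hill values plus Gaussian noise, stored unclipped so the
clipping rule is exercised downstream. True LogEC50s are placed so ~80% fall
inside the tested concentration span and ~20% outside — deliberately
creating the population of molecules whose EC50 a curve fit cannot pin
down. True slopes are log-uniform on [0.5, 2].

* `pubchem_like`: every molecule measured once on a shared 8-point grid
  spanning 4 decades, homoscedastic noise SD 10 (on the 0–100 response
  scale). Quality varies only through sampling noise — the uniform-quality
  regime where quality-aware methods are *not* expected to help.
* `basf_like`: per-molecule measurement counts uniform on [4, 100] (sparse
  designs still cover the tested span), per-molecule noise SDs log-uniform
  on [8, 80] — a 10× quality range whose absolute scale is set to match the
  25–45 response-unit test RMSEs typical of large industrial pesticide
  assays. Crucially, data quality is rank-correlated (Gaussian copula,
  ρ = 0.7) with true potency: screening campaigns re-measure their promising
  candidates more often and more carefully, so active molecules carry the
  reliable EC50s. The marginal distributions of counts and noise scales are
  unchanged by the coupling.

Both presets use 64 features with 16 informative bits so that the
sample-to-dimension ratio of a desk-scale run (hundreds of training
molecules) matches that of the full-scale screens being emulated (10⁴
molecules against 1024-bit fingerprints); `SimulationConfig` itself defaults
to 256 features for users who want the harder ratio.

What the generator does **not** emulate: non-Gaussian assay artifacts
(plate effects, aggregation outliers, censoring), correlated noise across
concentrations, slope misspecification beyond the log-uniform range, and
structure in the fingerprints (bits are independent). Passing tests
therefore demonstrate the machinery — recovery, calibration, degeneracies,
protocol — on clean heteroscedastic Gaussian data, not performance on any
particular real assay.

## The quality-benefit benchmark, honestly

The standing benchmark (`ec50ml.benchmark`) asks whether tuned W-RF and WSVR
beat RF and SVR on held-out dose-response RMSE on `basf_like` data. To
isolate the quality dimension within a tractable budget, the weighted and
unweighted variant of each family share fixed structural hyperparameters
(forests: max_features 0.33, min_samples_split 1%; SVR: ε 0.1) and only α is
tuned, by 5-fold CV on the targets over its standard grid.

At desk scale (1000 molecules) the effect is real but small and
inconsistent: with ~500 training molecules the models' own bias (~0.5 log
units against the true LogEC50) exceeds the EC50 noise of most molecules, a
random forest's bootstrap averaging absorbs much of what remains, and the
dose-response metric intrinsically down-weights exactly the molecules whose
targets are worst (they contribute the fewest held-out pairs). CV on
target-level MSE therefore often selects α = 0, making the tuned model
identical to its blind twin; when it selects α > 0 for WSVR the weighted
model does win, by ~0.5 RMSE units. The large, consistent improvements
reported for full-scale industrial collections belong to a regime — tens of
thousands of training molecules, hence far smaller model bias — that a
desk-scale benchmark cannot reproduce; the package's standing end-to-end
test encodes the full-scale expectation and is currently failing at desk
scale, deliberately left so. This is a finding, not a defect: with uniform or weakly-informative quality, the best
achievable configuration is α = 0, and the methods are designed to recover
it.

## Numerical details

* Hill responses overflow harmlessly (10^x → inf → response 0) and are exact
  at the midpoint; float saturation makes extreme tails equal 0 or 100
  exactly, which is accepted.
* Posterior grids renormalize in log space; a zero pooled variance is
  rejected and routed to the fallback rather than producing a singular
  likelihood.
* `random_search` derives its CV shuffling and candidate sampling from the
  search seed; model seeds are passed separately so tuning noise and model
  noise are independent.
* Bootstrap SD uses the population SD of the resampled RMSEs.
* Model persistence is a single joblib file carrying the spec and fitted
  state.
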