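# Methods

## Screening model

`screenbo` simulates pool-based screening campaigns over a finite library of
`N` molecules with hidden true activities.  Actives ("hits") are defined by
a quantile rule: the hit threshold is the `ceil(q·N)`-th largest true
activity (default `q = 0.10`), compared with `≥`, so molecules tied at the
threshold count as active and the rule is deterministic and order
independent.  For assay tables that ship explicit active labels, the
threshold is instead the minimum activity among labelled actives.  The
threshold is a function of true activities only; measurement noise can never
move it.

A campaign starts from a uniformly random initial batch (default 100
molecules), then repeats: refit the surrogate on all measurements so far,
score the untested pool with the acquisition metric, measure the top
`batch_size` candidates, and record the cumulative number of acquired hits
and *true hits* (acquired hits with at least one measurement at or above the
threshold).  The loop stops once total measurements exceed
`stop_fraction · N` (default one half); the final batch may overshoot the
bound, since the rule is checked after each full batch.  The batch count is
therefore the smallest `k` with `(k+1)·batch_size > stop_fraction·N`.
`max_batches` can truncate the loop for checkpointed experiments.

## Measurement noise

Measured activity is `y = y_true + ε`, `ε ~ N(0, σ₂²)`, one global variance
per campaign.  Real assay data additionally carry intrinsic noise
(variance σ₁², typically ≈ 0.6 on pXC50 scales); the package documents σ₁²
but never injects it — synthetic pools are noise-free apart from σ₂², so
the effect of added noise is observed directly.

σ₂ is tied to the pool's activity range through a single coefficient α
(canonical sweep 0, 0.05, 0.1, 0.15, 0.2, 0.25).  Two calibrations are
implemented behind one function:

- `sd` (default): `σ₂ = α · range(y)`.
- `variance`: `σ₂² = α · range(y)`.

The default was fixed by an identification argument rather than taste: on
the 5000×10 linear pool the two forms predict misidentified-hit fractions of
roughly 38% versus 7% at α = 0.2 after 8 active-learning batches, and only
the `sd` form reproduces the ≈40% misidentification plateau that the
simulated-data experiments this package models are known to exhibit.  The
`variance` form remains a one-line config switch (`noise_form`).

Noise draws are *counterbalanced*: the value added to replicate `k` of
molecule `i` is a pure function of `(base_seed, i, k)` (a dedicated PRNG is
keyed by the triple).  Consequences: (1) all acquisition arms of a run see
identical noise for any (molecule, replicate) they share, so arm comparisons
are paired; (2) retests receive fresh but reproducible draws; (3) results do
not depend on call order or batch membership.  At α = 0 measurements equal
true activities exactly, which forces hits ≡ true hits in every campaign —
a structural identity the tests assert.

## Surrogate

The QSAR surrogate is a scikit-learn random-forest regressor with 100 trees
and otherwise default settings (all features considered per split,
squared-error criterion, single-sample leaves), refit from scratch after
every batch.  Training rows are (features, measured value) pairs; a
retested molecule contributes one row per replicate with no averaging.

The predictive mean μ̂ is the average of per-tree predictions.  The
uncertainty σ̂ is a pluggable strategy:

- `tree_variance` (default): the population *variance* of per-tree
  predictions.  Carrying squared activity units, it dominates UCB/EI scores
  on pools with a large activity scale (those metrics then degrade toward
  random selection there) and vanishes on small-scale pools such as the
  Friedman #3 surface (UCB then tracks greedy).  This scale-dependent
  behaviour — UCB/EI near-random on the linear pool, UCB ≈ greedy on
  Friedman #3, PI intermediate — is exactly the acquisition-ordering
  pattern the reference experiments show, which is why it is the default.
- `tree_std`: the population standard deviation, the conventional ensemble
  uncertainty in activity units.

The incumbent `f*` used by EI and PI is the maximum *measured* activity in
the current training set.

## Acquisition

Greedy (`μ̂`), UCB (`μ̂ + βσ̂`, β = 2), EI and PI with margin ε = 0.01, and
a uniform-random baseline.  EI and PI use the standard closed forms; at
σ̂ = 0 they degenerate to `max(μ̂ − f* − ε, 0)` and the step
`1{μ̂ > f* + ε}` respectively, avoiding division by zero.  Both closed
forms are tested against Monte-Carlo oracles (2×10⁶ antithetic normal
draws per case) to three decimals.  Batch selection is naive top-k with
ties broken by ascending molecule id — deterministic and identical across
arms.  Molecules are scored independently; no batch-diversity scheme is
used, deliberately.

## Retest policies

After a batch is measured, the policy flags molecules for re-measurement in
the *next* batch (the initial random batch is never flagged — no model
existed when it was selected).  Each queued retest displaces one new
selection, keeping every batch at exactly `batch_size` measurements; if the
queue ever exceeds the batch size, the overflow carries over.

- `basic`: flag iff the selecting model predicted the molecule at or above
  the threshold but the measurement fell below it.
- `uncertainty_augmented`: flag iff `value + w·σ̂ ≥ threshold` and the
  measurement fell below it (default weight `w = 0.1`).  The inflated value
  is the model's prediction by default; a variant using the just-measured
  value is selectable (`basis="measured"`).  This rule matters when hits
  are rare (e.g. top 1%), where almost no raw prediction clears the
  threshold and the basic rule nearly never fires.

The predictions used by the predicate come from the model that *selected*
the batch, not the post-measurement refit.  Each molecule is retested at
most `max_retests_per_molecule` times (default 1), and never after any
measurement reached the threshold.  With per-test identification
probability `a` and at most `n` retests, the identifiable fraction of hits
is bounded by `1 − (1−a)^(n+1)` (e.g. 60% → 84% for `a = 0.6`, `n = 1`);
the bound is exposed as `retest_ceiling`.

## Evaluation

Hit and true-hit curves are cumulative unique-molecule counts per batch and
can be recounted independently from a trace's raw measurement log.
Enrichment of an arm is its hit count divided by the *paired* random arm's
(same run seed) at a checkpoint, aggregated as the mean of per-run ratios;
ratios with a zero denominator are reported missing and excluded.
Checkpoints may be batch indices or pool fractions (resolved by cumulative
measurements).  The retests-vs-no-retests comparison classifies each
dataset win/draw/loss on mean true hits; reported win/loss percentages are
shares of all datasets with draws excluded from display.

## Reproducibility and seeds

Per-run seeds derive from a base seed via `SeedSequence([base, run_index])`
(kept below 2³¹).  Within a run, the initial batch, the random-metric
scores, the per-batch forest seeds, and the noise stream are separate
tagged substreams of the run seed, so arms are paired and every output is
bit-reproducible.  Grid runs (`screenbo run`) write byte-identical traces
and summary CSVs on re-execution.

## Problem sizes used in the shipped experiments

The packaged experiments run the canonical pools at full size (5000
molecules, batches of 100, 100-tree forests) but truncate campaigns at 8
active-learning batches — the checkpoint at which the headline quantities
are defined — with 10 runs for the quantitative summaries and 5 runs for
the qualitative ordering checks.  Unit tests use a 600-molecule pool with
batches of 50 and 25-tree forests, which preserves every structural
invariant at a fraction of the cost.

## What the synthetic pools do and do not capture

The linear and Friedman #3 generators provide controlled landscapes with a
known activity range, exact hit sets, and zero intrinsic noise — ideal for
isolating the effect of injected noise and surface complexity.  They do not
emulate fingerprint feature sparsity, activity cliffs, assay-specific error
structure (σ₁² > 0, heteroscedastic or activity-dependent noise), or
externally labelled actives at non-10% rates.  Passing tests on these pools
therefore validate the machinery and the noise/retest arithmetic, not
performance claims on any particular real assay; real activity tables can
be loaded through the CSV interface to test those directly.

## Known limitations

- Noise is additive, Gaussian, homoscedastic; no assay-chemistry model.
- No batch-diversity acquisition; no neural surrogates.
- Retests happen in the immediately following batch; end-of-campaign retest
  scheduling is not implemented.
- Model persistence is out of scope; traces, not models, are the artifact.
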