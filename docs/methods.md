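# Methods

`fermxfer` implements a local transfer soft-sensor workflow for multi-phase
fed-batch fermentation, together with a seeded process simulator that makes
every experiment in the package reproducible without external data. This
note records the models, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## The modelling problem

Key biochemical state variables of a *Pichia pastoris*-style fermentation —
biomass (µg/mL), product activity (inulinase, U/mL) and methanol (g/L) —
are measured offline every 4 h, while auxiliary process variables
(temperature, pH, dissolved oxygen, feed rates, agitation, base addition,
air flow, broth volume) are available online. A soft sensor maps the
auxiliary variables to the biochemical targets. Two features of the process
break a single global regression model:

* **multi-phase dynamics** — cell proliferation, fed-batch transition and
  protein induction have different metabolic regimes, so one model averages
  across phases;
* **batch-to-batch heterogeneity** — inoculum and feed-schedule differences
  shift the data distribution between historical (source) batches and the
  new (target) batch.

The workflow addresses both: K-means partitions source samples into
phase-specific *sub-source domains*, one optimized network is trained per
domain, a new batch is matched to the most similar domain by Euclidean
centroid distance, and the matched model is adapted to the new batch by
freeze/fine-tune transfer with a mean-embedding MMD alignment term.

## Pipeline stages

1. **Augmentation.** Each 61-sample source batch is expanded to 181 samples
   by inserting two linearly interpolated points per sampling gap (at 1/3
   and 2/3 of each gap, applied identically to auxiliaries and targets so
   their correspondence is preserved). Target batches are never augmented.
2. **Standardize + PCA.** Auxiliary channels are z-scored (fit on source
   data only) and projected onto principal components obtained by
   eigen-decomposition of the unbiased sample covariance. The retained
   component count is the smallest k whose cumulative explained variance
   meets a threshold. The `select_components` default is 0.99; the
   *pipeline* default (`RunConfig.cum_var`) is 0.9999 because the
   standardized setpoint-style channels of the simulated campaigns put
   more than 99 % of total variance into 3 of 9 components, and the
   within-phase variation a soft sensor actually regresses on lives in the
   tail; 0.9999 retains 8 of 9 components, the near-full decomposition this
   class of data calls for.
3. **Clustering.** Lloyd's K-means with k-means++ (greedy-spread,
   D²-sampled) seeding, 10 restarts, deterministic lowest-index
   tie-breaking, run to an assignment fixpoint so that centroids equal
   cluster means and every sample sits with its nearest centroid. The
   cluster count is chosen on the SSE-versus-k curve (k = 1..10) by the
   discrete maximum-curvature proxy `SSE(k−1) − 2·SSE(k) + SSE(k+1)`,
   ties to the smallest k; a fixed K can be forced.
4. **Sub-models.** One single-output sigmoid network per (domain, target
   variable). Architecture: 2 hidden layers in the reduced study (depth is
   configuration, not a constant; the reference depth of 9 hidden layers is
   available but pointless at this problem size). Training is full-batch
   gradient descent on the half-sum-of-squares loss; targets are min-max
   scaled into [0.05, 0.95] because the output neuron is a sigmoid.
   Hyperparameters (learning rate on a log scale, hidden width, init range,
   epochs) are searched by the improved firefly algorithm; the search
   objective is validation MSE on a held-out 20 % split, with the
   weight-init seed and the split held fixed across candidates (common
   random numbers).
5. **Matching + transfer.** The labeled window of the target batch (by
   default its earliest 25 % of samples — the portion a running
   fermentation has assayed) is matched to the sub-source domain with the
   smallest mean centroid distance. That domain's models are fine-tuned on
   the labeled samples: full-batch descent on
   `MSE(target) + mmd_weight · MMD(source features, target features)`,
   with the first k layers frozen (learning rate 0) and sequential
   output-side-first unfreezing governed by a validation stopping rule
   (relative improvement ≥ `unfreeze_tol`, default 1e-3). The unadapted
   model is always retained as the stage-0 candidate, so adaptation is
   kept only when it improves held-out target error. Prediction either
   uses the adapted model for the whole batch (`matching="batch"`, suited
   to single-phase target windows) or routes every target sample to its
   nearest domain (`matching="per_sample"`), substituting the adapted
   model for the matched domain.

### Losses and conventions

Two squared-error conventions are exposed deliberately: `sse_loss`
(½·Σ residual², the training loss whose gradients backpropagation uses) and
`mse_loss` (mean form, used for reporting, validation and fine-tuning).
Transfer with no frozen layers and `mmd_weight=0` reproduces plain
mean-loss training bit-for-bit, which the tests assert.

The MMD here is the linear-kernel (mean-embedding) form
`‖mean(z_S) − mean(z_T)‖²` on the activations of the last hidden layer
(configurable); no Gaussian kernel is introduced. Its gradient flows
through both the source and the target feature stream.

### Improved firefly algorithm

Each candidate hyperparameter vector is a firefly with brightness
`1/(1+loss)`. Per iteration: (i) each firefly moves toward every brighter
one with attractiveness `β₀·exp(−γ·r²)` plus an `α`-scaled uniform step
(ε ~ U(0,1), as specified, hence a positively biased walk — clipping to the
search box bounds it); (ii) a differential perturbation
`δ·(x_p − x_q)`, p ≠ q ≠ i, δ ~ U(0,1); (iii) fitness-proportional
crossover with the global best followed by an α-scaled Mantegna Levy kick
(`s = u/|v|^{1/λ}`, λ = 1.5 by default), accepted greedily only if the
objective improves. The Levy step is scaled by α because an unscaled
heavy-tailed step almost always leaves the search box. Best-ever loss is
non-increasing by construction; disabling stages (ii)–(iii) recovers the
plain firefly algorithm used as the weaker baseline. Early stopping when
the best loss plateaus is available (`plateau_patience`).

## The simulator

`synthetic.simulate_batch` generates 240 h runs sampled every 4 h
(61 samples): piecewise-logistic biomass with phase-specific growth rates
(defaults 0.008, 0.035, 0.005 h⁻¹; slow proliferation, exponential
fed-batch rise, induction plateau), product formed proportionally to
biomass only during induction (yield 1.8·10⁻⁴ U/mL per µg/mL·h), and
methanol integrated as feed minus biomass-proportional uptake with a 24-h
oscillating feed schedule. The nine auxiliary channels mix pure
phase-setpoint signals (temperature, pH, glycerol feed, air flow) with
state-coupled ones (DO drained by oxygen demand and feed bursts, agitation
cascaded on demand, cumulative base addition tracking growth, broth volume
tracking cumulative feed) — the mixture real bioreactor telemetry shows,
and the property that makes the phases separable *and* the within-phase
regression solvable. Gaussian measurement noise is added per channel as a
fraction of its typical range (default 1 % for auxiliaries, 2 % of the
trajectory range for the offline assays) and nonnegative quantities are
truncated at zero. Batch-to-batch heterogeneity multiplies the inoculum
biomass and the methanol feed rate and jitters the per-phase growth rates
(relative SD 0.02 by default); the reference target batch uses 0.90 /
1.05. All randomness flows from one integer seed through named
per-batch streams, so campaigns are bit-reproducible.

What the simulator does **not** emulate: substrate/DO mechanistic balances,
sensor drift and missing values, irregular sampling, within-batch control
actions, or real *P. pastoris* kinetic constants. Passing studies therefore
demonstrate that the algorithmic chain behaves as designed under its stated
assumptions — not calibrated performance on real fermentations.

## The comparison study

`pipeline.study_benchmark(seed)` mirrors the reference experiment at
reduced scale: two source batches, one target batch with 10 % lower
initial biomass and 5 % higher methanol feed, variants

* **DNN** — one global model per target, hyperparameters at the centre of
  the search box (no optimization);
* **FA-DNN** — global model, plain firefly search;
* **K-IFA-DNN** — per-domain models with the improved search, per-sample
  centroid matching;
* **K-IFA-DNN-TL** — plus transfer fine-tuning of the labeled-window-matched
  domain;

all sharing the augmented/standardized/PCA-reduced source representation
bit-exactly and scored on the same held-out target samples (everything
after the labeled 25 %). Because the three targets have incommensurate
units, the ordering statistic is the scale-free aggregate
mean(RMSE/SD(truth)) across targets; per-target RMSE/R² tables are also
produced. Study sizes (2 hidden layers, 4 fireflies × 5 iterations,
epochs searched in 200–1000) are the package's reduced problem-size
choices; the transfer schedule at this scale is lr 0.02 for 200 epochs
(the reference schedule 1e-5/50 is the `TransferPlan` class default and a
near-no-op on these scaled problems).

## Numerical choices and degenerate inputs

* Ties everywhere (assignment, matching, elbow) break to the lowest index;
  eigenvector signs are fixed by making each component's largest loading
  positive.
* Rank-0 PCA input yields all-zero eigenvalues and zero projections, not an
  error; an empty K-means cluster is an error instructing a re-fit rather
  than a silent re-seed.
* Sigmoid saturation bounds activations, so training cannot produce
  non-finite losses; divergence checks still guard the update loops.
* `gd_step` accepts per-layer learning rates; a zero rate leaves a layer's
  parameters bit-identical (the freezing contract).
* Gradients are validated against central finite differences (h = 1e-6,
  relative tolerance 1e-5) on 100 random small networks.

## Known limitations

* Batch-level matching assumes the target window lies in one phase; for a
  full heterogeneous batch use per-sample matching.
* Transfer adapts only the matched domain; phases without labeled target
  samples keep their source models (no multi-source fusion by design).
* The elbow proxy (discrete second difference) is a heuristic; for SSE
  curves without a distinct bend it returns the smallest interior k, so a
  manual K override is provided.
* Full-batch gradient descent is intentionally plain (no momentum/Adam),
  matching the modelled update rule; it is not a competitive optimizer for
  large networks.
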