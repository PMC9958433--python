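# Methods

## Problem

For each hospitalization with feature vector `x` and observed length of
stay `LOS` (hours), produce an interval `[max(c(x) − α·s(x), 0), c(x) + α·s(x)]`
expected to contain `LOS`.  Two quantities summarize a method on an
evaluation set: *accuracy* — the fraction of patients covered (closed
interval) — and the *overall prediction error* (OPE) — the mean unclamped
half-width `α · mean(s)`, the width budget the accuracy was bought with.
Coverage is monotone in α, so calibrating α to a target accuracy (default
95%, grid step 0.01, α ≤ 50) is an exact grid scan.  The lower-bound clamp
at zero is coverage-neutral because LOS is non-negative.

## Synthetic cohorts

Real critical-care EHR sources are credential-restricted, so all
experiments run on generated cohorts.  The LOS marginal is log-normal with
median 162 h and log-SD 0.84, back-solved from the published summary of a
38,597-stay adult cohort (median 6.75 days, quartiles 3.88–12.07 days);
closed-form quartiles are exp(ln 162 ± 0.6745·0.84) ≈ 92 h and 285 h.
Three feature regimes:

- **A** (27 features, default noise SD 15 h): one column is an affine
  transform of the latent LOS (a discharge-time analog); the label adds
  independent Gaussian noise.  Residuals of any well-fit model are Gaussian
  with known SD — the calibration oracle.
- **B** (27 features): a linear score explains only `signal_fraction`
  (default 0.1) of the log-LOS variance; LOS is exactly log-normal.
- **C** (136 features, noise baseline 40 h): the conditional mean is
  `m(x) = 162·exp(0.84·clip(w·x, ±2.5))` with `w` supported on 8 features
  (a few strong predictors among many irrelevant ones, as in real EHR
  panels; the ±2.5-SD winsorization tempers physiologically implausible
  months-long means).  Additive Gaussian noise has SD
  `σ(x) = 40·(0.3 + 1.4·expit(x0+x1))·(m(x)/162)^0.75` — a two-feature
  logistic ramp times a mean-coupling factor encoding that longer expected
  stays are proportionally more variable, the dominant heteroscedasticity
  pattern in LOS data.  The spread of σ(x) across patients is well over
  3-fold.  The generator emits `true_sigma` and `true_mean` side channels
  (never model inputs) so tests can check parameter recovery.

What the generator does **not** emulate: missingness mechanisms, temporal
structure, feature correlation blocks, informative censoring, site effects.
Passing tests therefore demonstrate the machinery and its calibration
behaviour under known noise, not clinical performance.

Splits are uniform at 9:1 with floor on the training side
(38,597 → 34,737/3,860).  Continuous missing values are mean-imputed;
categorical missing values become an explicit `N/A` level.

## Network stack

All fits use a small fully connected ReLU network (default 3×64) on
standardized features (one-hot categoricals) and a standardized target,
trained by minibatch Adam (lr 1e-3, batch 256) with L2 weight decay 1e-3
on the weight matrices, early stopping on a 10% validation slice
(patience 10, restoring the best parameters) and a halve-on-plateau
learning-rate schedule.  The weight decay matters: without it the network
memorizes label noise (training RMSE below the generator's noise floor,
test RMSE far above), which corrupts every interval whose scale is the
training RMSE.  Everything is seeded; identical config + seed gives
bit-identical predictions.

- **Point regressor**: MSE; its *training-set* RMSE is the global interval
  scale (test RMSE is reported separately).
- **Error network**: target `|LOS − LOS_pred|`, softplus output so the
  predicted half-width is non-negative (signed-residual mode behind a
  flag; half-widths must be non-negative, which is why the absolute target
  is the default).  For centered Gaussian residuals of SD σ its ideal mean
  prediction is σ·√(2/π).
- **Distributional network**: two outputs `(μ, z)`, `σ = e^z`, trained with
  one of the losses below in standardized target space (σ₀ in hours is
  rescaled accordingly).  Gradient clipping (global norm 1) is on by
  default for losses 1–2, whose surfaces are nearly flat (loss 1) or kinked
  (loss 2).  A fit that exhausts its epochs without the validation loss
  plateauing is returned flagged `converged=False` rather than raised —
  loss 1 is the usual culprit.

## The three distributional losses

With `d = μ_pred − μ0` (μ0 = observed LOS) and `σ_pred = e^z`:

1. `loss1 = (e^z/2)·[erf(0.707·e^{−2z}(d+1)) − erf(0.707·e^{−2z}(d−1))]` —
   the difference between target and predicted probability mass over a
   ±1-unit window.  It vanishes as `d → 0, z → −∞`, but it also vanishes
   for large |d| at fixed z, so most of the surface is flat — the source of
   its training instability.  z is clamped to ±30 against overflow.  An
   alternative argument scaling `e^{−z}` (i.e. 1/(σ√2)-like) is selectable;
   the printed `e^{−2z}` form is the default since it satisfies the stated
   limit.
2. `loss2 = 1 − overlap/normalizer`, where `overlap` is the signed overlap
   of `[μ0 ± σ0]` and `[μ_pred ± σ_pred]` (negative when disjoint, not
   clamped, to preserve gradients).  Two normalizers exist: `σ0 + σ_pred`
   (default; zero exactly when the intervals coincide) and `2(μ0 + μ_pred)`
   (selectable for fidelity to the published formula; at matching
   parameters it leaves 1 − 2σ0/(4μ0) ≈ 0.95 rather than 0, contradicting
   the stated limit — both behaviours are unit-tested).  σ0 defaults to
   1 h, the smallest scale keeping the target interval non-degenerate.
3. `loss3 = d² + (σ_pred − σ0)² + λ·d²/(σ_pred² + ε)` with σ0 = 0,
   ε = 1e-6, λ = 1 (no published value).  The first two terms are the
   squared 2-Wasserstein distance to the point-mass target; alone they
   collapse σ to 0, which the coupling penalty prevents.

**Equilibrium caveat.**  None of the three losses is a proper scoring rule
for σ.  Pointwise minimization of loss 3 in σ gives
`σ* = (λ·E[d²|x])^{1/4}` (in training units), not the residual SD; loss 2's
optimum sits near 2.4× the residual scale.  Consequently σ_pred *ranks*
patients by residual scale (what the per-patient methods need) but is not
itself calibrated — the α-calibration step absorbs exactly this per-method
scale bias, which is why every method gets its own α.  Tests assert the
derived equilibria, not naive σ ≈ noise-SD claims.

## Conditional WGAN-GP

Generator: `(x, 16-dim Gaussian noise) → LOS sample` (standardized space,
clipped at 0 h after decoding).  Critic: scores `(x, LOS)` pairs; real and
generated pairs share the same features, the standard conditional reading.
Objective: critic minimizes `E[D(fake)] − E[D(real)] + 10·(‖∂D/∂LOS‖ − 1)²`
with the penalty differentiated along the LOS coordinate at fixed features
(the generated object is the LOS scalar; a joint-input penalty is a flag),
interpolating between real and fake LOS.  5 critic steps per generator
step, Adam betas (0, 0.9), lr 1e-4 for both.  The double backpropagation
the penalty needs (gradients of an input-gradient with respect to weights)
is implemented forward-over-reverse with ReLU masks treated as constant —
exact almost everywhere.

Adversarial training oscillates: the generator's pooled mean drifts
through the target with a period of hundreds of epochs.  The returned
generator is therefore the epoch snapshot whose pooled mean/SD on a fixed
512-row *training* monitoring slice best match the real moments
(restore-best selection; no evaluation data involved).  Default 600 epochs
at n = 2,000 rows (≈ 4,200 generator steps, ≈ 1–2 min on one CPU).  Each
patient's interval scale is the population SD of 500 generated samples
(divisor n; at 500 samples the sample-SD distinction is < 0.1%).

## Evaluation design

- α is calibrated directly on the evaluation set, mirroring the
  methodology this package operationalizes; a separate calibration split is
  available for deployment use.
- Interval membership is closed on both ends; ties have measure zero for
  continuous predictions.
- Method comparison reports (a) OPE at the α reaching target accuracy and
  (b) accuracy at fixed OPE budgets (default 48 h and 96 h), with α
  back-solved as budget / mean(scale).
- On regime C the per-patient methods beat the global band where the
  predictable noise spread dominates: lower OPE at 95% accuracy and higher
  accuracy at the 96-h budget.  At the tight 48-h budget the
  mean-estimation error floor (≈ 30 h at n = 20,000, unpredictable from
  features) erodes the advantage of trained fits; an ideal-allocation
  oracle (widths ∝ √σ(x), the loss-3 equilibrium shape, centered on the
  true mean) confirms the allocation rule itself wins at both budgets.
  The error-network method degrades fastest at tight budgets — an error
  model of an error is noisy — matching its known behaviour.

## Problem sizes

Test and acceptance runs use cohorts of 20,000 (training experiments),
12,000 (error/distributional oracles), 4,000–6,000 (loss comparisons) and
2,000 (adversarial training) stays — sizes at which every Monte-Carlo
tolerance asserted in the tests holds with margin while the full suite
stays in the minutes range on a single CPU.

## Known limitations

- Loss 1 frequently fails to converge within its epoch budget (recorded on
  the fit, not raised); its σ profile should not be interpreted.
- Loss 2's strong σ ranking comes with a weaker μ head (bounded gradients);
  at fixed tight budgets its intervals can underperform despite near-perfect
  σ ordering.
- GAN training quality varies by seed even with snapshot selection; the
  pooled-moment match is a two-moment criterion, not distributional
  equality.
- The deep default regressor leaves multi-hour errors in the sparse far
  tail of noiseless regime-A data (an optimization plateau; a linear head
  recovers the signal exactly) — interval methods are insensitive to this,
  but point predictions in the extreme tail are not exact.
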