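# Methods

## The model

`vam` implements an image-computable model of speeded four-alternative
perceptual decisions in a flanker task.  Behavior on trial *i* — a response
time *t⁽ⁱ⁾* and a choice *c⁽ⁱ⁾* — is generated by a linear ballistic
accumulator (LBA): evidence for each response *k* grows linearly from a
start point drawn uniformly on [0, *A*] at a rate *d_k ~ N(v_k, s²)*
(*s* = 1 fixed for identifiability); the first accumulator to reach the
threshold *b* determines the choice, and the RT adds a constant
non-decision time *t₀*.  What makes the model image-computable is that the
drift-rate means are not free parameters but the output of a convolutional
encoder applied to the raw stimulus raster:

    v⁽ⁱ⁾ = CNN_ζ(s⁽ⁱ⁾)

The joint density is the LBA likelihood (closed form; defective, because a
trial on which every sampled drift is non-positive never terminates) times
a standard-normal prior over θ = (b, A, t₀).

## Inference

The posterior over θ is approximated by a full-covariance Gaussian on the
unconstrained scale θ\* = (log(b−A), log A, log t₀), parameterized by its
mean μ and Cholesky factor L.  The fit maximizes a reparameterized
Monte-Carlo estimate of the evidence lower bound: each datapoint in a
minibatch receives its own ε-draws, θ\* = Lε + μ, and the integrand is

    log p(t, c | v, T⁻¹(θ*)) + w·[log N(T⁻¹(θ*); 0, I) + (b* + A* + t0*)
                                  − log q(θ*; μ, L)]

The Jacobian adjustment of the inverse transform is log|det J| =
b\* + A\* + t₀\* = log((b−A)·A·t₀) (each coordinate map is an exponential,
so the Jacobian is triangular with the exponentials on its diagonal); it is
validated against a finite-difference Jacobian determinant in the tests.

The weight *w* defaults to 1/N_train (`prior_mode="scaled"`): the joint
density contains a single prior for the entire dataset, so splitting the
prior, Jacobian and entropy terms evenly across datapoints makes the batch
mean an unbiased estimate of the full-dataset ELBO divided by N.  Attaching
the full terms to every datapoint (`prior_mode="per_datapoint"`) is also
implemented; it effectively raises the prior to the Nth power, and in
parameter-recovery simulations it biases the threshold gap by ~30% — far
outside the recovery tolerance — which is why it is not the default.

Gradients are fully analytic (no autodiff library is used anywhere):

* The single-accumulator first-passage CDF/PDF derivatives with respect to
  (v, b, A, u) reduce, after cancellation of the φ-terms, to compact
  expressions (e.g. ∂F/∂v = (u/A)(Φ(z₂) − Φ(z₁))); they are verified
  against central finite differences.
* Because θ\* is affine in ε, the per-sample entropy term is
  (3/2)log 2π + log|det L| + ‖ε‖²/2, so its total derivative with respect
  to μ vanishes and with respect to L is diag(1/L_ii).
* The encoder receives ∂ELBO/∂v and backpropagates it through a
  hand-written reverse pass (convolutions as nine shift-and-add channel
  contractions, instance-norm and max-pool backward in closed form); the
  whole chain is finite-difference checked in the test suite.

Optimization is Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), minibatch 256, 10 MC
samples per datapoint, a fixed epoch budget, and a 65/15/20
train/validation/holdout split.  The posterior is initialized at
T(b = 1.5, A = 0.75, t₀ = 0.3) with L = 0.1·I; if the fastest observed RT
is at or below the initial t₀, the initializer clamps t₀ to 0.8·min RT
(otherwise the first epoch would start in the zero-density region).  The
Cholesky diagonal is optimized through an exponential map so Σ remains
positive definite along the whole trajectory.

### Numerical choices

* Survival factors 1 − F are clamped to [1e-300, 1] and densities floored
  at 1e-300 before logs; CDFs are clipped to [0, 1 − 1e-12] inside the
  survival product.
* A < 1e-6 switches the single-accumulator distribution to its point-start
  limit F(u) = Φ((uv − b)/(us)).
* In the training path, a posterior draw with t₀ ≥ rt would make the trial
  density exactly zero; the decision time is clamped below at 1e-4 s,
  producing a large finite penalty with zero gradient instead of a NaN.
  The strict API (`trial_loglik`) still returns −inf for rt ≤ t₀.
  Non-finite ELBOs abort the fit with the offending trial index.
* Failed-run diagnostics mirror the known failure modes of this model
  class: a chance-accuracy flag (simulated choice agreement ≤ 0.30) and a
  runaway-negative-drift flag (more than 50% undefined trials).

## Synthetic stimuli and ground-truth behavior

The generator stands in for the game-play data the model class was built
for.  Stimuli are arrowhead glyphs on a uniform blue background in a
640×480 window: one central target pointing left/right/up/down, four
flankers sharing an independent direction, arranged in one of seven layouts
(four V formations, two lines, a cross); ~50% of trials are congruent;
positions are uniform inside per-layout edge margins so no glyph is ever
clipped.  Rendering is deterministic, anti-aliased (2× supersampled
polygon coverage), and bilinearly resized to the encoder input (128×128 at
full scale).  The number of flankers (4) and the glyph art are
conventions; direction is the only shape cue.

Ground-truth behavior comes from an LBA (b = 1, A = 0.5, t₀ = 0.25 s) with
a congruency-dependent drift rule: the target response accumulates at
v_t = 3, the flanker's response at v_f = 1 on incongruent trials, all
other responses at v_o = −1, and the target drift is reduced by a conflict
decrement of 0.6 on incongruent trials.  The decrement is essential: in an
independent race, boosting a competing accumulator lowers incongruent
accuracy but *speeds* the conditionally-correct RTs (the slow target wins
less often), so without it the RT congruency effect would be negative.
With these defaults the generator produces an RT congruency effect of
≈ +40 ms and an accuracy effect of ≈ 0.17 — a strong but realistic conflict
signature.  What the generator does **not** emulate: sequential effects,
learning/fatigue drifts, attention lapses, background clutter, or any
demographic structure; passing tests therefore certify the machinery, not
behavioral realism beyond the congruency/layout/position structure built
in.

Augmentation during training follows the image-classification recipe the
model class uses: per-image integer translations (horizontal round(U[0,2]),
vertical round(U[0,1]) px) and an elastic warp (coarse Gaussian
displacement field, node spacing 32 px, amplitude 3 px, bilinear
resampling) applied with probability 0.75.

## Analyses

Behavioral: the RT congruency effect (incongruent − congruent mean RT,
correct trials only), the accuracy congruency effect, decile delta plots
(linear-interpolation quantiles), RT-quintile conditional accuracy
functions, and stimulus-feature modulation (one-way ANOVA on RTs,
chi-squared on accuracy proportions, α = 0.05).  RT filtering removes
trials ≤ 250 ms and then |rt − median| > 10·MAD, with the *unscaled*
median absolute deviation and the floor applied before the MAD pass.
The stated horizontal bins (60 px edges, 50 px interior) do not tile
640 px exactly; the implementation uses [0,60), ten 50-px bins, and a
final bin absorbing the remainder, and 25-px vertical bins with the 5-px
remainder in the last bin.  Empty bins are dropped with a warning.

Representation geometry operates on N×K activation matrices (per-channel
spatial maxima of post-ReLU conv maps, taken before instance norm; all FC
units; silent units removed), incongruent trials only whenever target and
flanker features could cross-contaminate:

* one-vs-rest squared-hinge linear SVMs (C = 1, standardized features,
  80/20 stratified split) for feature decoding; the stacked hyperplane
  normals define target/flanker subspaces;
* subspace alignment = mean singular value of V_targ·V_flnkᵀ after
  row-space orthonormalization by reduced SVD (1 parallel, 0 orthogonal);
* participation ratio (Σλ)²/Σλ² of the class-centered activation
  covariance, in [1, K];
* plug-in normalized mutual information with 10 equal-width activity bins
  (equal-count binning available by flag), normalized by feature entropy;
* a single-unit selectivity taxonomy: ANOVA gate at p < 1e-3 on z-scored
  activity, Tukey HSD (α = .05) for uniformly higher/lower directions, and
  a rank-sum comparison of |z| magnitudes to resolve units with both a
  positive and a negative winning direction (ties → "complex").

Where the underlying procedure was ambiguous we chose: equal-width MI
bins over each unit's observed range; per-decile congruency effects as
quantile differences (not within-bin mean differences); z-scored activity
throughout the selectivity decision tree; activation extraction before
instance normalization.

## Problem sizes

The default test and validation runs use desk-scale sizes chosen so the
full pipeline exercises every code path on a single CPU: 32×32 stimuli
rasterized on a quarter-resolution canvas, a (16, 16, 32)-channel encoder
with a 64-unit FC layer, 2,000 trials, batch 64, and 25-epoch budgets
(augmentation off in the fixed-budget validation runs so they are exactly
reproducible).  Constant-encoder parameter recovery uses 4,000 trials and
a 1,600-epoch budget, which recovers b − A and t₀ to within a few percent.
The full-scale geometry (128×128 images, widths 64–256/1024, batch 256,
200 epochs) is the package default for real use.

## Known limitations

* The LBA is static: no within-trial dynamics, leakage or inhibition, so
  delta plots from the model are near-flat-to-positive and cannot show
  the negative-going segments some conflict tasks produce.
* The likelihood is defective by construction and no renormalization for
  the all-negative-drift event is applied; simulated datasets exclude
  undefined trials and report their fraction.
* Desk-scale encoders trained for minutes learn the congruency structure
  (positive RT/accuracy effects) but reach only moderate target-decoding
  accuracy; layer-profile analyses at that scale are qualitative.
* The pushforward posterior SD reported by `summary()` describes the
  variational Gaussian, which ignores any posterior skew the true
  posterior may have.
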