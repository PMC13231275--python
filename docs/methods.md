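# Methods

## Model

`osnn` fits a nonparametric cumulative-logit model for an ordinal response
y ∈ {1, …, K} observed with p high-dimensional "G" features x (gene expression
or imaging features), q pre-selected environmental variables z, and all p·q
products r = (x₁z₁, …, x_pz_q) as candidate interactions.  The model assumes a
latent continuous variable u = −f(x, r, z) + ε with logistic noise and ordered
thresholds −∞ = α₀ < α₁ < … < α_K = ∞, so that

    P(y ≤ k | x, z) = sigmoid(α_k + f(x, r, z)).

The unknown f is a feedforward network applied to a *sparse input layer*: the
assembled input t = (x, r, z) is weighted elementwise by β = (b, vec(η), 1_q)
before entering L dense ReLU layers with a scalar output s.  Class
probabilities come from the ordinal output function
σ_α(s)_k = sigmoid(α_k + s) − sigmoid(α_{k−1} + s), which is a probability
vector by construction.  The q environmental variables carry fixed unit
weights: they are assumed pre-selected and are never penalized or excluded.

Cutpoint order is enforced by reparameterization, α₁ = γ₁ and
α_k = α₁ + Σ_{j≤k} exp(γ_j), so the free vector γ can be trained without
constraints.  The softmax-head variant (width-K final layer, nominal
cross-entropy) exists purely as an ablation: it discards the category order.

## Penalty and strong hierarchy

The training objective is Q = L + pen1 + pen2 with L the cross-entropy of the
predicted class probabilities,

    pen1 = Σ_j ρ(‖κ_j‖₂; λ₁, ξ) + Σ_{j,d} ρ(η_{jd}; λ₂, ξ),
    pen2 = λ Σ_l ‖W_l‖_F²,

where κ_j = (b_j, η_{j1}, …, η_{jq}) groups a main effect with its q
interactions and ρ is the minimax concave penalty (MCP)
ρ(t; λ, ξ) = λ∫₀^{|t|}(1 − x/(λξ))₊ dx, i.e. λ|t| − t²/(2ξ) below the
saturation point λξ and constant λ²ξ/2 beyond it.  Killing a group norm
removes the main effect *and* all its interactions, which is exactly strong
hierarchy; within a surviving group the individual MCP can still prune single
interactions.  Biases and cutpoints are never penalized.

Because pen1 is nonsmooth, optimization uses a local quadratic approximation
(LQA): at iterate m the penalty is replaced by Σ w·coef² with

    w_b[j]    = ρ′_{λ₁}(‖κ_j‖) / (2(‖κ_j‖ + ε)),
    w_η[j,d]  = w_b[j] + ρ′_{λ₂}(|η_{jd}|) / (2(|η_{jd}| + ε)),

whose gradient matches the exact penalty gradient at the expansion point (the
`standard_lqa` mode; verified by a finite-difference tangency test).  The
typeset form of the surrogate admits a second parse with an extra
|coef|/‖κ_j‖ factor on the group contribution; it is retained behind
`surrogate_mode="as_printed"` for fidelity experiments but does not satisfy
tangency and is not used.  ε = 1e-8 guards the denominators; since the smooth
surrogate never produces exact zeros, a threshold τ (default 1e-2) truncates
negligible estimates after training: main effect j is selected iff
‖κ̂_j‖ > τ, interaction (j, d) iff j is selected and |η̂_{jd}| > τ, so the
reported selection obeys strong hierarchy by construction.  Thresholding the
group norm (rather than b_j alone) is consistent with the group penalty.

## Optimization

All gradients are exact backpropagation implemented in NumPy (full batch; the
problem sizes here do not need minibatching or GPU autodiff).  Two optimizers
are provided:

* `plain_gd` — the literal algorithm: simultaneous gradient-descent updates of
  γ (then α via the reparameterization), the dense parameters and the sparse
  coefficients on the LQA surrogate, with the LQA weights refreshed at each
  iterate.  On the full-size problem (m₀ = 605 inputs, 2×128 hidden) it needs
  very many iterations: it either stalls on a long plateau or, at large rates,
  destabilizes.
* `adam` — the same loop with adaptive-moment steps; it reaches comparable or
  better objective values in a few hundred iterations and is the default for
  the experiment drivers.

Defaults for the experiment protocol: learning rate 0.01, at most 600
iterations, stopping when the relative change of the surrogate objective over
a 10-iteration window falls below 1e-5.  γ is initialized from N(0, 4)
(standard deviation 2).  Dense weights use Glorot-uniform initialization.

The sparse-layer coefficients start at the nonzero constant 0.2.  This
constant matters: nonzero initialization is essential, and with a start of 0.1
the initial group norms (≈ 0.1·√(q+1) ≈ 0.25) sit deep inside the MCP's
penalized region for the default λ₁ ∈ {0.1, 0.2} (saturation at λ₁ξ = 0.3–0.6),
and in a sizable fraction of replicates every group is driven to zero before
the network can learn any signal.  Starting at 0.2 places the group norms near
the saturation boundary, where the MCP exerts little force until the data
fails to support a group — which is the penalty's intended behaviour — and the
collapse mode disappears.

Tuning: λ, λ₁, λ₂ are chosen by grid search on a held-out validation set, one
fit per grid point from an identical seeded initialization, ties resolved
toward larger penalties.  The library default criterion is validation
cross-entropy; the experiment drivers select by validation macro-AUC, the
study's headline prediction metric — cross-entropy can prefer a degenerate
all-zero-sparse-layer fit (honestly unconfident) over a slightly overconfident
fit that ranks far better.  ξ is fixed at 3 throughout.

## Synthetic data

The generator reproduces the simulation design the experiments need:
X ~ N_p(0, Σ(ρ)) with AR entries ρ^{|s−t|} (p = 100); five E variables drawn
from N₅(0, Σ(0.5)) with the *last two* dichotomized at 0 into {0,1} (which two
is an arbitrary fixed choice); 15 important main effects (the first 15
indices) with coefficients ω_j ~ U(0.6, 0.9); 15 interactions, all with the
first (continuous) E variable, c_{j1} ~ U(0.6, 0.9), parents inside the
important mains so the truth itself obeys strong hierarchy; E-coefficients
s_d ~ U(0.6, 0.9).  The latent response is u = η + sin(η) + ε with η the
linear predictor and ε standard logistic; y cuts u at the empirical quantiles
of the *pooled* train+validation+test sample at the cumulative class
proportions (1:1:1 balanced, 1:2:1 imbalanced), per replicate.  Validation
sets equal the training size; test sets hold 1000 observations for stable
metric estimates.  One master seed per replicate spawns sub-streams for
coefficients, covariates and noise.

What the generator does not emulate: real expression data are heavy-tailed,
normalized, and correlated in blocks rather than AR bands; real class
boundaries are not exact latent quantiles; environmental variables are not
centered Gaussians.  Passing the simulation suite therefore demonstrates
correctness of the machinery and qualitative method behaviour, not performance
on real tumor-genomics data.

An oracle bound worth knowing: with the true data-generating parameters the
Bayes predictor of this design reaches macro-AUC ≈ 0.90 at these settings, so
observed differences between methods reflect estimation quality, and small
implementation choices (optimizer, iteration budget, initialization) move
results by several AUC points at n = 300.

## Evaluation

* accuracy — fraction of argmax-correct predictions (argmax is the Bayes rule
  under 0–1 loss; ties break to the smaller class).
* macro-AUC — unweighted mean of one-vs-rest AUCs over classes present in the
  evaluation set, Mann–Whitney with ties counting ½; classes without positives
  or negatives are skipped with a warning.  Verified exactly against an
  all-pairs brute-force estimator and against scikit-learn.
* RPS — mean over samples of Σ_{k<K}(F̂_k − 1{y ≤ k})², the squared distance
  between predicted and observed cumulative distributions, *unnormalized* over
  the K−1 categories (a near-uniform K = 3 predictor scores ≈ 0.444, matching
  the magnitudes reported for weak baselines; the 1/(K−1) variant is available
  via `normalized=True`).
* selection TPR/FPR — against the generating truth, with null-set denominators
  p − 15 and pq − 15.
* OOI — per-variable selection frequency across repeated splits.

## Experiment protocol (desk scale)

`scripts/acceptance.py` and the heavy acceptance tests run 10 replicates per
scenario (the full-scale protocol uses 100; means at 10 replicates carry a Monte
Carlo standard error of roughly 0.01 AUC, absorbed by the widened tolerances).
All methods of a replicate share its dataset (paired comparison, lower
variance of contrasts).  Per-method reduced grids hold two pre-selected
(λ, λ₁, λ₂) combinations — chosen once by validation performance on
development replicates — and each replicate still picks between them on its
own validation split.  The whole protocol (balanced scenario with four
methods, imbalanced scenario, and the ρ=0 sample-size trend) completes in
roughly 10–12 minutes on one CPU.

## Known limitations

* The product parameterization of the depth-zero linear baseline (sparse layer
  times a trainable 1×m₀ map) has slow multiplicative dynamics: under the
  shared iteration budget it remains underfit, and run to full convergence it
  matches a well-tuned penalized ordinal regression.  Mid-trajectory values
  between those two states are not reproducible targets.
* Selection FPR of the proposed method is sensitive to τ and to the chosen λ₁;
  the default protocol trades some FPR for main-effect TPR.
* `plain_gd` is faithful but impractical at full scale; conclusions from the
  experiment drivers rest on the adam variant.
* No theoretical convergence guarantees are claimed for the LQA loop with
  nonconvex penalties; the objective-trace monotonicity is checked empirically
  in the tests.
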