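# Methods

## The decision model

A third-party observer watches a dictator allocate 100 CNY between
themself (x₁) and a recipient (x₂) and chooses a punishment amount
p from {0, 5, 10, 15, 20, 25, 30} CNY out of an endowment x₃ = 50 CNY.
Punishment reduces the dictator's payoff threefold (multiplier m = 3,
exposed as a parameter). The third-party inequity-aversion utility is

    U(x1, x2, x3, p) = own(p) − γ · | max(x1 − m·p_impact, 0) − x2 |

with own(p) = max(x₃ − p, 0) in the costly condition and own(p) = x₃ in
the free (control) condition, where punishing costs the observer
nothing. Both payoff clamps at zero are part of the task rules: neither
the observer nor the dictator can go negative. γ ∈ [0, 1] weighs the
post-punishment |dictator − recipient| gap against the observer's own
payoff.

Social distance SD (rank 1 = closest, 100 = stranger) modulates the
model through one of four transforms:

1. **Hyperbolic punishment**: p_impact = (1 + 1/(k·SD)) · p. The
   punishment's impact on the dictator is inflated at close distances
   and approaches the nominal amount as SD → ∞; k > 0 is the discount
   rate.
2. **Hyperbolic inequity**: γ = σ((1 + 1/(k·SD)) · γ_SD) with σ the
   logistic sigmoid and γ_SD unbounded.
3. **Power punishment**: p_impact = p + k·SD^W; punishment impact grows
   additively with distance (curvature k, exponent W).
4. **Power inequity**: γ = σ(γ_SD + k·SD^W).

The scalar "normalisation onto (0, 1)" in the inequity transforms is
the logistic sigmoid — the only monotone map of a single real value
onto (0, 1) consistent with the γ bound.

**Substitution scope.** In the punishment-transform models the
transform scales the punishment's *impact* on the dictator (the
reduction term); the observer's own cost is always the nominal amount
actually spent. This is a deliberate design choice: substituting the
subjective punishment into the cost term as well makes the inflation
factor at SD 1–2 (≈ 21 at k = 0.05) saturate both clamps, so every
nonzero option ties in utility and simulated mean punishment at the
closest distances *exceeds* that at mid distances — inverting the
monotone rise of punishment with social distance that the model exists
to capture. With nominal cost, expected punishment under e.g.
γ = 0.8, k = 0.05, β = 0.5 rises from ≈ 5.5 CNY at SD = 1 to ≈ 20 CNY at
SD = 100 (exact-expectation oracle), matching the behavioural pattern.

**Choice rule.** A deterministic "pick the best option" rule has a
degenerate likelihood, so choices follow a softmax with inverse
temperature β > 0 fitted per subject: P(option i) ∝ exp(β·Uᵢ). The
deterministic account is the β → ∞ limit; exact utility ties yield
equal probabilities, so no separate tie-breaking is needed.

## Synthetic data

The generator reproduces the scanning-phase design: 6 sessions × 54
trials; 12 blocks per session (6 costly, 6 free); per session and
condition the 48 unfair targets cover all 24 combinations of
SD ∈ {1, 2, 3, 5, 10, 20, 50, 100} × allocation ∈ {90/10, 85/15, 80/20}
exactly once, four targets per block; 6 quasi-fair fillers (65/35,
60/40, 55/45, each twice) are assigned to random blocks (a
`symmetric_fillers` switch instead splits them evenly between the two
conditions' blocks). Fillers get a random SD from the study levels and
are simulated under the same model but excluded from all fitting, as
they existed to keep unfairness from becoming normative, not to test
the models. One integer seed drives design shuffling, parameter draws
and choice sampling through independent sub-streams. An optional miss
rate (default 0) injects no-response trials, which are dropped from
likelihoods.

Population simulations draw per-subject parameters uniformly from
γ ∈ (0.2, 0.8), k ∈ (0.02, 0.5), β ∈ (0.2, 1.0) (γ_SD ∈ (−1, 1) for
inequity-transform models; W ∈ (0.3, 1.0) for power models). These
ranges span clearly punishing, clearly discounting subjects without
piling on parameter bounds, at a choice stochasticity (β ≈ 0.2–1 on a
utility scale of tens of CNY) that leaves recovery hard but feasible.

What the generator does *not* emulate: reaction times, trial timing and
jitter, session-order or learning effects, and any between-subject
correlation structure in parameters. Passing recovery tests therefore
show the estimation machinery is correct and well-conditioned at the
study's trial counts — not that real participants obey the model.

## Estimation

Parameters are fit per subject on an unconstrained space: log k, log β,
logit γ (punishment-transform models), identity for unbounded γ_SD and
W. Independent N(0, 3²) priors on the transformed parameters make the
estimate a MAP; at σ = 3 the priors are weak over the plausible natural
ranges (k ∈ [0.01, 1], β ∈ [0.05, 5]) and mainly regularise boundary
drift. Optimisation is L-BFGS-B with 10 restarts (first start at the
prior mean, the rest drawn N(0, 1.5²), seeded) inside a [−12, 12] box;
parameter values whose utilities overflow return a large finite penalty
(1e10) so the search simply retreats. Fits with γ within 0.01 of a
bound or k outside [1e−4, 1e4] carry boundary diagnostics.

The log model evidence defaults to the Laplace approximation at the
mode, log p(y) ≈ LL + log prior + (d/2)·log 2π − ½·log|H|, with H the
finite-difference Hessian of the negative log posterior
(central differences, step 1e−4; eigenvalues clipped at 1e−8 before the
log-determinant — the prior contributes a 1/9 floor to the curvature, so
clipping only ever repairs finite-difference noise). A BIC evidence,
LL − (d/2)·log n, is available as a fallback. Variational free energy
is the other common evidence surrogate in this literature; Laplace and
BIC preserve model rankings at 288 trials per subject, and the prior
sensitivity is ours to report: the priors are stated above, and the
BIC option provides a prior-free cross-check of every ranking.

Both payment conditions enter one likelihood per subject with shared
parameters; k is kept positive (log transform) in all four models
during estimation, although the raw power-transform functions accept
any real k.

## Model selection

Given the subjects × models log-evidence matrix, model identity is a
random effect: Dirichlet(α₀ = 1) prior over population frequencies r,
variational updates z_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα)),
α = α₀ + Σₙ z_n, iterated to |Δα| < 1e−8 (warning and last iterate on
non-convergence). Exceedance probabilities P(r_k > r_j ∀ j) are
Monte-Carlo estimates from 10⁶ Dirichlet draws (seeded; the two-model
incomplete-beta closed form is kept for verification). The Bayesian
omnibus risk compares the variational free energy F₁ of the
random-effects model against the null F₀ = Σₙ(logsumexp(lmeₙ) − log K)
in which every subject picks uniformly among models:
BOR = 1/(1 + exp(F₁ − F₀)), and pEP = EP·(1 − BOR) + BOR/K. Evidence
matrices are centered per subject before the updates; all outputs are
invariant to subject-wise constants.

## Numerical and design choices

- Social distance must be ≥ 1 (the study's minimum rank); SD = 0 is
  rejected rather than special-cased, as the hyperbolic transform
  diverges there.
- CNY and "MU" are treated as the same unit.
- Summary tables pool responded, non-filler trials; empty cells are
  absent rather than zero. No smoothing is applied to
  punishment-vs-distance curves (presentation-layer concern).
- The utility surface reports max over the 7 options per
  (SD, allocation) cell and takes explicit parameters; which subject's
  fitted parameters to use is the caller's choice.
- Determinism: every randomised stage takes an explicit seed, recorded
  in CLI provenance sidecars; identical seeds give byte-identical
  numeric outputs.
- Problem sizes: recovery analyses use 31 subjects × 288 target trials
  (the study's scale); convergence spot-checks use 10⁴ simulated
  choices per trial type.

## Known limitations

- The Laplace/BIC evidences are asymptotic surrogates, not a
  variational lower bound; on strongly separated synthetic data the
  ranking is insensitive to this, but near-tied models on real data
  could rank differently.
- The best-option utility surface is not guaranteed monotone in
  inequity level: when the inflated impact zeroes the dictator's
  payoff, the recipient's larger share itself becomes the residual
  inequity. The qualitative "utility falls with inequity" ordering
  holds in the mild-discounting regime.
- Real behavioural statistics (condition means, mixed-model F tests)
  require the study's data and are out of scope; the package computes
  descriptive analogs on synthetic or user-supplied datasets only.
- No hierarchical pooling of parameters across subjects; fits are
  independent per subject.
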