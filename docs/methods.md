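# Methods

## The model

Two latent state variables track the trained motor memory of the two grasp
strategies a macaque uses to retrieve pellets from a Klüver board after a
motor-cortex lesion: `x_p` for the precision grip (thumb–index terminal
opposition, the "true recovery" skill) and `x_c` for the compensatory grip
(index flexion against the thumb's dorsum). Both start at 0 at the beginning
of postlesional training. Every executed trial `k` updates both memories:

    x_p(k+1) = α_p x_p(k) + β_p use_p(k) + β_int use_c(k)
    x_c(k+1) = α_c x_c(k) + β_int use_p(k) + β_c use_c(k)

`use_a ∈ {0,1}` indicates the grip used, `α` is the per-step retention
(1−α is forgetting), `β` the use-dependent update rate, and `β_int` the
cross-skill generalisation: practising one grip partially updates the other's
memory. On days without any trials the memories decay once, `x ← α x`. The
same `α` thus acts on two time scales (per trial and per rest day); this is
deliberate and reproduced as printed in the model this package implements.

The executed skill level `μ` combines the memory with a spontaneous-recovery
factor that depends only on the postlesion day:

| variant        | performance map                          |
|----------------|------------------------------------------|
| training_only  | μ = x                                    |
| mult_f         | μ = x · k_sp f(day)/f(day_max)           |
| add_f          | μ = x + k_sp f(day)/f(day_max)           |

with `f ∈ {log, identity, exp}`, giving seven candidate models (k = 7 free
parameters for training-only, 8 otherwise). The exp factor is computed as
`exp(day − day_max)`, algebraically identical to `exp(day)/exp(day_max)` but
overflow-safe. `day_max` is the last day of the modelled span.

A trial's motor command is `u ~ N(μ, σ_a²)` on an axis normalised so the
ideal command is 1. Retrieval from a well of diameter `d` mm succeeds when
the command exceeds the near edge of the reward region, `1 − w/2` with
`w = w0·d` and `w0 = 0.001` a fixed task-demand scale, so

    p(success | a, w) = 1 − Φ((1 − w/2 − μ_a)/σ_a).

This one-sided region (overshoot always succeeds) is the fitted form; a
two-sided variant (`reward_region="two_sided"`) is available for comparison.
Success probabilities are clamped to `[1e−12, 1 − 1e−12]` before entering any
logarithm.

The grip choice itself is not modelled: an exogenous action policy
`q(day) = p(precision)`, piecewise-constant between its measurement days,
drives both which grip trains the memories and how test successes are
marginalised: `p_w = q p_p,w + (1−q) p_c,w`.

## Likelihood and estimation

A forward simulation over the actual schedule (well sizes, trial counts,
rest days) produces per-day success probabilities. Observed test counts are
scored with binomial log-terms: on days without video classification, `s` of
`n` successes at the marginal `p_w`; on video days, per-action selection and
success counts at the per-action `p_a,w`. Following the printed total
likelihood, the no-video terms are summed over both actions, i.e. doubled
(`nv_action_sum=True`); the un-doubled version is available and both are
covered by the likelihood oracle tests.

Per-trial use indicators are replaced by their expectation under the policy
(`use_p = q` per trial), which is how trial counts and measured selection
probabilities are combined in this design; the n-trial block update then has
the closed form `x ← αⁿx + c(1−αⁿ)/(1−α)` with `c = β_own q_own +
β_int(1−q_own)`, making a likelihood evaluation O(days).

Within a day, test sessions are evaluated at the state carried over from the
previous day — i.e. tests precede that day's training — and the resulting
success probability is held across the day's test trials (one binomial `p`
per day and well). This ordering is the package's design choice where the
protocol leaves it open, and it matters: with ~200 training trials/day and
α ≈ 0.85, αⁿ ≈ 10⁻¹⁵, so a post-training state sits at the day's
quasi-static fixed point `c(q)/(1−α)` and the likelihood would then depend on
α only through ratios `k_sp·β/(1−α)`, leaving the retention rates completely
unidentified. Evaluating tests on the carried-over state exposes the
rest-day decay (a post-weekend test sees α²·Friday's state) and restores
what identifiability the data can offer. Test trials also update the
memories (they are executed grips); `test_trials_update=False` restricts
updates to training sessions.

Estimation maximises the total log-likelihood with L-BFGS-B from 20 seeded
multistarts drawn uniformly within bounds (α, β, β_int ∈ [0,1];
σ ∈ [10⁻⁴, 1]; k_sp ∈ [0, 10]), followed by a Nelder-Mead polish and a final
refinement; convergence tolerance 10⁻⁸ on the objective. 95% confidence
half-widths are `2·sqrt(diag(H⁻¹))` with `H` the central finite-difference
Hessian (step `10⁻⁴·max(1,|θ_i|)`) of the negative log-likelihood at the
maximum. The printed formula this implements, `CI = 2 diag{H⁻¹}`, omits the
square root, which would yield a variance rather than a length; the square
root is taken here. Flat or negative-curvature directions yield NaN with a
warning, and estimates at a bound are flagged rather than given a Hessian CI.
Model comparison uses `AIC = 2k − 2L`, lower is better.

## The synthetic experiment generator

The original animals' data are not deposited, so every downstream stage is
exercised on synthetic experiments that emulate the protocol: daily training
5 days/week starting on postlesion day 8, well size fixed within a day and
advancing 13 → 12 → 11 → 10.5 → 10 mm on the training day after the
cumulative pellets retrieved from the current size exceed 1,000 (the counter
uses the simulator's own training successes, training sessions only); two
daily test sets totalling 10 trials in each of the five wells; an exogenous
sigmoidal policy shift from compensatory to precision grip sampled onto the
ten video days; rest-day decay on weekends. Days carrying a video-analysed
test session are forced to be training/test days even when the 5-on/2-off
pattern would make them rest days, because the real calendar alignment of
the printed test days is unknown and no weekly phase is consistent with all
of them.

The latent trajectory uses the same expected-use convention as the fitter,
so the generating path is exactly reconstructable from the written dataset;
all observed counts are stochastic: `Binomial(n, p_w)` successes per well,
`Binomial(n, q)` video-day selections, with independent seeded streams for
schedule noise and observation noise. Training defaults to 200 trials/day (a
free protocol knob; the real counts are unpublished). A test-count
"inflation" factor multiplies only the number of observed test trials per
well (replicated measurement) and never the number of memory-updating
trials, keeping the latent trajectory at the nominal protocol.

Two ready-made scenarios use the published best-fit parameter sets as
generating truths: a 45-day multiplicative-log scenario (policy rising
logistically from 0.05 to 0.95 around day 30, steepness 0.5 — the values of
the 45-day animal's transition window) and a 61-day additive-log scenario
(floor 0.2, ceiling 0.9, transition near day 38, steepness 0.3 — that animal
used both grips from the start and switched later and more gently; its
real, non-monotone policy backlash is not emulated). The 45-day scenario
reproduces the recovery valley: the marginal success rate rises while the
compensatory grip dominates, drops sharply when the policy switches to the
still-weaker precision grip, and recovers as precision skill catches up.

What the generator does not emulate: video-classification noise, day-to-day
motivation or attention fluctuations, non-monotone policies, time-varying
motor noise, or mechanistic differences between lesions. Passing recovery
tests therefore show that the estimation machinery is correct and calibrated
for data that follow the model, not that the model is correct for real
animals.

## Sensitivity analysis and the valley metric

Sensitivity runs multiply one parameter — or the retention pair (α_p, α_c)
jointly — by a set of factors (β's ×2/×1/×0, α pair ×1.02/×1/×0.98, k_sp
×1.1/×1/×0.9) and re-simulate the noiseless expected success rate, averaged
without weights over the five wells. Retention factors above 1 are permitted
here (they are forbidden during fitting); the state is capped at 10¹² so the
success probability saturates at 1 instead of overflowing. These trajectories
are evaluated at the end-of-day state, giving the smooth profiles a recovery
figure shows, free of the post-weekend dips that the test sessions themselves
see.

The recovery valley is quantified as the largest *fractional* drop from the
preceding running maximum: `depth = max_t (M_t − v_t)/M_t`. An absolute drop
was considered and rejected: perturbations that suppress the whole curve
(e.g. removing the interaction term halves the peak and then collapses the
rate to zero for a week) would register *shallower* absolute valleys than
baseline, inverting the comparison the metric exists to support. The
fractional form is scale-invariant — a collapse to zero is a full-depth
valley regardless of peak height — and on both scenarios reproduces the
central sensitivity finding: doubling β_int removes the valley, removing
β_int deepens it.

## Identifiability: what these data can and cannot estimate

Two structural limits of the model/protocol combination, established
analytically and confirmed by the recovery studies, temper any reading of
individual parameter estimates:

1. **Multiplicative scale ridge.** The memories are linear-homogeneous in
   (β_p, β_int, β_c) with zero initial condition, so for the multiplicative
   variants the transformation β → cβ, k_sp → k_sp/c leaves every prediction
   exactly unchanged. Only the products k_sp·β are identified; the
   likelihood is exactly flat along the ridge, bounded only by the box
   constraints. Recovery studies on the 45-day scenario recover
   k_sp·β_int and k_sp·β_c to ~2% while the individual k_sp and β_int land
   anywhere on the ridge. The additive variants have no such ridge and
   recover all parameters. Reported CIs for multiplicative fits flag the
   flat directions as NaN rather than inventing a width.

2. **Near-binary precision success.** With σ_p ≈ 0.016 and the five reward
   thresholds spanning only ~0.1σ_p, the precision grip's success
   probability is almost always ≈0 or ≈1; days with informative intermediate
   probabilities are rare. The precision retention rate α_p, whose signature
   is the post-weekend dip in μ_p, is therefore only coarsely bracketed (its
   profile likelihood is flat over a wide interval), while α_c — observed
   through the moderate-noise compensatory grip — is recovered to ~0.1%.

## Problem sizes and defaults

Recovery studies default to 10 replicates, test counts inflated ×20 (n = 200
per well per day), 20 multistarts per fit; model-selection recovery uses 8
multistarts per variant. A single likelihood evaluation is ~0.1 ms and a
20-start fit a few seconds, so the full study suite runs in minutes on one
core. All randomness flows from a single base seed: replicate i uses data
seed 1000·base+i and fit seed 2000·base+i.
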