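# recovery-valley

State-space modelling of grip-skill recovery after a motor-cortex lesion:
why does food-retrieval success *drop* partway through rehabilitation
training — the "valley of recovery" — and what lets the subject climb out
of it?

The package is written for computational-neuroscience and neurorehabilitation
researchers who want to fit trial-level skill-recovery models to
Klüver-board-style behavioural data (daily training sessions, per-well test
counts, video-classified grip choices), compare candidate models of
spontaneous recovery, and probe which parameters shape the valley. Because
the original macaque data are not publicly deposited, the package ships a
synthetic-experiment generator that emulates the full protocol, so every
stage — simulation, fitting, model comparison, sensitivity analysis — is
testable end to end.

## The model

Two latent memories track the precision grip `x_p` (true recovery) and the
compensatory grip `x_c`, both 0 at the start of postlesional training.
Each executed trial updates both:

    x_p(k+1) = α_p x_p(k) + β_p use_p(k) + β_int use_c(k)
    x_c(k+1) = α_c x_c(k) + β_int use_p(k) + β_c use_c(k)

with retention rates α, use-dependent update rates β, and a cross-skill
generalisation term β_int; memories decay once (`x ← αx`) on days without
trials. Executed skill level adds a spontaneous-recovery factor that depends
only on postlesion day: μ = x (training-only), μ = x·k_sp f(day)/f(day_max)
(multiplicative) or μ = x + k_sp f(day)/f(day_max) (additive), with
f ∈ {log, linear, exp} — seven model variants in all. A trial's motor
command is u ~ N(μ, σ²) and retrieval from a well of normalised width
w = w0·diameter succeeds when u > 1 − w/2:

    p(success | a, w) = 1 − Φ((1 − w/2 − μ_a)/σ_a)

An exogenous, piecewise-constant action policy q(day) = p(precision grip)
selects which grip trains and marginalises test successes. Parameters are
estimated by bounded maximum likelihood over binomial test counts
(marginalised on ordinary days, per-action on video-classified days), with
multistart L-BFGS-B, finite-difference-Hessian confidence intervals
(2·sqrt(diag H⁻¹)) and AIC = 2k − 2L model comparison. See
`docs/methods.md` for the full account, including the identifiability
limits of the multiplicative variants.

## Worked example

Simulate a 45-day experiment at the published multiplicative-log best-fit
parameters (test counts replicated 20-fold) and refit it:

```python
import recovery_valley as rv
from recovery_valley.data_io import RunConfig

ds = rv.make_monkey_r_fixture(seed=1, inflation=20)
fit = rv.fit_model(ds.variant, ds.schedule, ds.observations, ds.policy,
                   ds.geometry, config=RunConfig(n_multistart=20, seed=1))
print(f"variant={fit.variant}  k={fit.k}  L={fit.log_likelihood:.2f}  AIC={fit.aic:.2f}")
for name, half in fit.ci.items():
    print(f"  {name:8s} = {getattr(fit.theta_hat, name):7.4f}  (CI half-width {half:.4f})")
traj = rv.success_rate_trajectory(fit.theta_hat, fit.variant, ds.schedule,
                                  ds.policy, ds.geometry)
depth, day = rv.valley_metrics(traj)
print(f"recovery valley: depth={depth:.2f} at day {day}")
```

which prints:

```
variant=mult_log  k=8  L=-590.21  AIC=1196.43
  alpha_p  =  0.8486  (CI half-width nan)
  alpha_c  =  0.9141  (CI half-width 0.0028)
  beta_p   =  0.9414  (CI half-width nan)
  beta_c   =  0.5834  (CI half-width nan)
  beta_int =  0.4772  (CI half-width nan)
  sigma_p  =  0.0155  (CI half-width 0.0009)
  sigma_c  =  0.0755  (CI half-width 0.0022)
  k_sp     =  0.1860  (CI half-width nan)
recovery valley: depth=0.86 at day 33
```

The well-identified parameters (the compensatory retention rate and both
motor-noise SDs) come back close to the generating values (0.9135, 0.0158,
0.0740) with tight intervals. The NaN half-widths are deliberate: the
multiplicative performance map is exactly invariant under rescaling all β's
by c and k_sp by 1/c, so those directions carry no curvature — only the
products k_sp·β are identified, and the package flags rather than hides
this. The valley metrics quantify the success-rate collapse around day 33,
when the policy switches to the still-weaker precision grip.

The same workflow is available from the shell:

```bash
recovery-valley simulate --monkey R --seed 1 --out data/
recovery-valley fit --variant mult_log --schedule data/schedule.csv \
    --observations data/test_counts.csv --video-observations data/video_counts.csv \
    --policy data/policy.csv --seed 1 --out fit.json
recovery-valley compare ...      # all seven variants, AIC table
recovery-valley sensitivity ...  # ×2/×1/×0 perturbation trajectories
recovery-valley pipeline --monkey R --seed 1 --out report/
```

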