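# Methods

This note documents the models, the generative cohort, the numerical
choices and the known limitations of `efbattery`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The adaptive response-window staircase

Each adaptive trial carries a deadline (the *response window*). Feedback is
tri-colour: GREEN (correct and on time), YELLOW (correct but late), RED
(incorrect; an omitted response on a response-required trial is RED — no
separate omission class exists). After a GREEN the window shrinks by
`step_down · 2^c` ms, where `c` counts the *previous* consecutive GREEN
trials; after YELLOW or RED it grows by `step_up · 2^l` with `l` the
previous consecutive non-GREEN trials (late responses feed the lapse streak
because the increment rule groups "incorrect or late"). Defaults:
`step_down = 10` ms, `step_up = 40` ms.

Parameters the source design leaves open, fixed here as configurable
defaults:

| parameter | default | rationale |
|---|---|---|
| initial window | 1500 ms | generous start; reached equilibrium well within a 40-trial block in simulation |
| clamp bounds | [200, 5000] ms | keeps the window behaviourally meaningful; clamping never resets streaks |
| streak-exponent cap | 6 | a single streak step never exceeds 640/2560 ms, so one update cannot jump past the clamp range; invisible in practice |

With streak scaling off and a continuous RT distribution the stationary
GREEN rate solves the zero-drift balance `p·step_down = (1−p)·step_up`,
giving `p = step_up/(step_down+step_up) = 0.8`; the Monte-Carlo staircase
reproduces this within ±0.02 over 10 000 trials (acceptance suite).

The continuous-performance (go/no-go) tasks bypass the window entirely.
For the adaptive go/no-go task (tap-and-trace) only target trials update
the window; correct rejections have no RT and no colour feedback.

## 2. Task battery

Eleven paradigms with pinned condition structures: basic RT (right-hand
block then left-hand block, 20 trials each), forward/backward spatial span,
flanker (50/50 congruent/incongruent, 40 trials), CPT-impulsive (80%
targets of 50), CPT-sustained (20% targets), Stroop (48, 50/50, four
response options), Boxed visual search (blocks feature-4, feature-12,
conjunction-4, conjunction-12 of 16), Compass cueing (48, equal thirds
neutral/congruent/incongruent), TaskSwitch (48, 50/50 stay/switch — the
stay/switch ratio is a package default, as is the flanker/Stroop congruency
split), Tap & Trace (tap block then dual block of 30 go/no-go trials each;
the trace-only block generates no detection responses and is not
simulated, since the metric uses only the dual block). Condition counts
honour the proportions *exactly* via largest-remainder rounding; block
orders are fixed; within-block order is a seeded permutation. Trial counts
are defaults sized for 5–10-minute tasks and are configurable per task.

The span staircase starts at length 3; two successful recalls in a row
raise the length by one (cap 9, where the task continues until the
failure criterion); three consecutive failures terminate. A variant rule —
advance after three successes at a length with at most one interleaved miss
— is selectable (`advancement_rule="three_correct_allow_one_miss"`);
the two-in-a-row rule is the default. **Object span** is the longest
length attempted on two consecutive trials. Note a corner this definition
implies: a deterministic respondent with capacity 5 climbs 3,3,4,4,5,5 and
then fails three times at 6 — so its object span is 6, one above capacity,
because the failed attempts are still attempts. The exhaustive controller
test (all outcome strings to length 12) pins this behaviour.

## 3. The generative cohort

Ten scored metrics (basic RT is the processing-speed covariate, not a
network variable) share a latent precision matrix `K = I − Ω_plant` built
by `planted_precision`: ring edges within each of three communities — set
reconfiguration {span_fwd, span_bwd, taskswitch}, attentional control
{cpt_impulsive, cpt_sustained}, interference resolution {flanker, stroop,
boxed, compass, tap_trace} — at partial correlation 0.30, eight bridge
edges at 0.10, zeros elsewhere; 17 nonzero edges in total. With unit
diagonal, partial correlations read back exactly and positive definiteness
is verified (smallest eigenvalue reported on failure).

Groups: the older group's abilities are shifted −0.4 SD and rescaled ×0.8
with *identical* edges, giving the invariance analysis a true
positive (means/scalings differ) and a true negative (edges equal) in one
cohort. Sessions: `η⁽ˢ⁾ = r_tt·η⁽¹⁾ + √(1−r_tt²)·ζ` with `r_tt = 0.70`.
Comparator battery: score `λ_cv·η + √(1−λ_cv²)·noise` with `λ_cv = 0.45`,
so the true concurrent correlation is `λ_cv` by construction.

Trial behaviour: with probability `anticipatory` the response is a guess at
a uniform RT in [80, 199] ms (below the cleaning cutoff); otherwise
`rt = t0 + LogNormal(m_task + condition_cost − 0.1·η, σ)` and accuracy is
`(1−lapse)·logistic(η + logit_task + logit_condition)`; span recall
succeeds with probability `logistic(1.2·(κ − length))`, `κ = base + η`.
All constants live in `src/efbattery/data/calibration.yaml` and were chosen
so that default-cohort summary metrics land inside ranges published for
comparable tasks (e.g. mean basic RT within 231–518 ms, span means within
4.8–9.6); the acceptance script recomputes the basic-RT calibration.
What the generator does **not** emulate: practice and fatigue effects,
diffusion-style speed–accuracy trade-offs, item-level effects, and any
dependence of trial noise on the adaptive window. Passing tests therefore
certify the *pipeline* (estimators, filters, decisions) under a known
truth, not distributional fidelity to any real population.

## 4. Cleaning and scoring

Stage order is fixed and enforced: anticipatory trim (RT < 200 ms on
responded trials) → ±3 individual-SD trim per participant × task → task
metrics → minimum-trials (<5 per condition) and below-chance filters →
±3 MAD score outliers. Removals are attributed to exactly one stage and
tallies conserve counts.

Decisions worth noting:

* **RCS denominator** — `n_correct / Σ rt_seconds` over responded trials,
  i.e. average correct responses per second; the alternative literal
  reading (divide additionally by the trial count) is available as
  `CleaningConfig(rcs_literal_product=True)` for sensitivity analysis.
  Correct-but-late responses count as correct (the metric has no
  timeliness qualifier); omissions contribute to neither numerator nor
  denominator (they have no RT), also flagged for sensitivity.
* **MAD filter** — `|x − median| > 3 · 1.4826 · MAD` (normal-consistent
  constant; raw-MAD mode via `mad_scale_constant=1`). A zero MAD removes
  nothing (an explicit degenerate-input rule: with a majority of identical
  scores the rule would otherwise remove every other value).
* **Chance accuracy** — `1/option-count` for forced choice, strictly
  "less than" (at-chance is retained). Go/no-go tasks have no symmetric
  option count; chance is the accuracy of the better blind strategy
  (always/never respond), i.e. `max(p_target, 1−p_target)` — equivalent to
  requiring better-than-baseline discrimination. Single-option speeded
  tasks are not accuracy-filtered.
* **Screening** — any high-risk indicator excludes; ≥4 moderate-risk
  indicators exclude.
* **Residualisation** — each task score (after the `−x/100` orientation
  transform for mean-RT metrics) is residualised by simple least squares on
  the hand-appropriate basic-RT mean: the two-hand mean for two-hand
  response tasks, the dominant-hand mean otherwise. The hand assignment per
  task is a package default on `TaskSpec.rt_control`.
* **ICC** — ICC(2,1) (two-way random effects, absolute agreement, single
  measures) from the ANOVA mean squares; sessions are a random facet in a
  test-retest design. p-value from `F = MSR/MSE` on (n−1, (n−1)(k−1)) df.
  Qualitative bands: >0.75 excellent, 0.60–0.74 good, 0.40–0.59 fair.
  Cross-checked against pingouin's ICC(A,1) in the test suite.

## 5. The network model

Parameterisation `Σ_g = Δ_g (I − Ω_g)⁻¹ Δ_g` with means `μ_g`; per group
the saturated model has `p` means + `p` scalings + `p(p−1)/2` edges (65 for
p = 10), saturating the mean-and-covariance structure. Estimation:

* complete data, no constraints — analytic (inverse sample covariance);
* missing data — casewise ("full-information") ML over missingness
  patterns; the saturated solution comes from an EM algorithm, constrained
  solutions from direct optimisation of the pattern-wise likelihood;
  a listwise-deletion mode exists for debugging;
* constrained models (pruned edges, cross-group equality) — L-BFGS with the
  analytic gradient (`dΣ/dω_ij = ΔB(E_ij+E_ji)BΔ`, `B = (I−Ω)⁻¹`), scalings
  optimised on the log scale. Infeasible iterates (non-PD `I − Ω`) return a
  large finite penalty rather than `inf`, which the Fortran line search of
  L-BFGS-B handles by backtracking; the optimiser is restarted from its own
  solution until the gradient norm is small. A fully unconstrained
  multigroup model factorises into independent per-group fits and is solved
  that way.

**Pruning** is one-shot: estimate the saturated model, fix edges with
two-sided `p > α = .05` to zero, refit once. Edge p-values use the Fisher-z
approximation with standard error `1/√(n − (p−2) − 3)` (a partial
correlation controls the remaining p−2 variables); a Wald alternative was
considered and rejected as the two agree to the precision relevant here.
At n = 600 this test has power ≈ 1.0 for edges of 0.30 and ≈ 0.68 for edges
of 0.10 — pruning sensitivity is a property of edge size, which is why the
operating-characteristics check plants bridges at 0.15 (power ≈ 0.96)
while the default cohort keeps weaker 0.10 bridges.

**Fit indices** for every fitted structure (network and factor models share
one code path): `χ² = 2(LL_sat − LL_model)`;
`CFI = 1 − max(χ²_M − df_M, 0)/max(χ²_B − df_B, χ²_M − df_M, 0)` against
the independence baseline (diagonal covariance, free means);
`RMSEA = √(max(χ²−df,0)/(df(n−1)))` with the 90% CI from bisection
inversion of the noncentral χ² CDF (bracket `[0, 10χ²]`, tolerance 1e-6;
df = 0 reports RMSEA 0 with a "undefined" flag); `AIC = −2LL + 2k`,
`BIC = −2LL + k·ln n`.

**Communities**: the spin-glass Hamiltonian (negative-weight extension when
negative edges are present) is minimised by igraph's simulated annealing,
replicated `n_reps` times with seeds drawn from the caller's generator;
the annealing schedule is pinned (start 1.0, stop 0.005, cooling 0.995 —
slower than igraph's default because replication reliability matters more
here than speed). Each annealing result is then polished by a
deterministic greedy single-node-move pass on the same quality function
(Traag–Bruggeman negative-weight modularity, γ = 1), so every replication
reports a local optimum. Partitions are canonicalised by first-occurrence
relabelling before frequency counting; the modal partition and its
selection frequency are returned. Components are detected separately:
isolated nodes form their own communities and two-node components are
solved exactly (the annealer does not terminate on 2-node graphs).
Defaults γ = 1, 10 spins — the source design names none of these.

**Bootstrap**: case-resampling; per edge the 95% percentile CI of the
saturated edge weight and the pruning inclusion frequency. (Recording
pruned-refit weights instead is available but makes percentile CIs
degenerate for weak edges, which are exact zeros in most resamples.)

**Centralities**: strength `Σ|ω|`, expected influence `Σω`, and
closeness/betweenness on the distance graph `1/|ω|` via networkx.

**Invariance ladder**: unconstrained → equal edges → + equal means →
+ equal scalings, all sharing the pooled pruning mask; adjacent models
compared by `Δχ²` on `Δdf = Δ(free parameters)`, all models by AIC/BIC.
The LRT verdict walks the ladder and stops at the first significant
deterioration; AIC/BIC verdicts are the respective minima.

## 6. Factor models

Correlated-factor and bifactor models `Σ = ΛΦΛᵀ + Θ`, identified by unit
factor variances (a convention — the source does not state its
identification; marker-loading identification gives the same fit). The
bifactor general factor loads on all ten metrics and the specific factors
are mutually orthogonal and orthogonal to the general factor. Estimation is
L-BFGS on the exact ML discrepancy with the analytic gradient
(`∂F/∂Λ = 2GΛΦ`, `∂F/∂Φ = ΛᵀGΛ`, `∂F/∂θ_i = G_ii`,
`G = Σ⁻¹(Σ−S)Σ⁻¹·n/2`), with up to 10 seeded random restarts on
non-convergence; non-convergence is reported on the results object, never
raised. Residual variances are deliberately *not* bounded below, so
improper (Heywood) solutions surface as `HeywoodWarning`s naming the
offending variables — the diagnostic the two-indicator bifactor specific
factor is prone to; a bounded mode (`bound_theta=True`) pins them at zero
instead and is used as a cross-check. Standardised loadings divide by the
model-implied SDs; sign indeterminacy is resolved by making each factor's
loading sum positive. With 10 variables the correlated 3-factor model has
33 parameters including means (df 32), the bifactor 40 (df 25).

## 7. Orchestration, seeding, formats

One integer seed fans out through `numpy.random.SeedSequence.spawn` to
fixed per-stage streams (cohort, administration, retest, comparator,
bootstrap, spinglass, cfa, flags), so toggling one analysis never perturbs
another and the full report bundle is byte-identical across runs with the
same seed (checked file-by-file in the acceptance suite). Trial logs,
score tables and report tables are UTF-8 CSV with pinned columns (empty
field = missing; malformed rows rejected with 1-based line numbers); the
manifest JSON records seed, package version, config and any stage
failures. Default study sizes (`RunConfig`: 240 validation, 60 retest, 80
concurrent participants; 200 bootstrap resamples; 250 spin-glass
replications) are desk-scale choices that keep a full run under a minute
while leaving every analysis estimable; all are configurable, and the
statistical simulations in the acceptance checks use the sizes stated
there (e.g. n = 600 cohorts, matching the adult-arm scale the network
analyses target).

## 8. Known limitations

* The generative response model is an artifact choice; no trial-level
  distributions are fitted to real users, so calibration claims are about
  published summary ranges only.
* FIML assumes missingness at random; the validity filters in fact censor
  by performance, which mildly violates MAR in the simulated pipeline —
  at default rates (a few percent of scores) the effect on edge estimates
  is well inside sampling noise, and the structure-recovery checks sample
  scores directly.
* The bifactor likelihood can be genuinely flat or divergent (the
  two-indicator specific factor is underidentified); results objects carry
  convergence status and warnings, and comparisons involving a
  non-converged bifactor should be read as evidence of over-complexity,
  not as precise estimates — which is itself the substantive conclusion
  such a comparison supports.
* Spin-glass replication frequencies depend on the annealing schedule; the
  pinned schedule plus greedy polish makes separable cases exact, but
  frequencies on estimated (noisy) networks remain seed-distribution
  quantities, which is why they are reported with their replication count.
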