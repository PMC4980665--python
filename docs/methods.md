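# Methods

`paimem` reimplements, end to end, the modeling and analysis machinery of a
paired-associate inference (PAI) study: the task's four experiment schedules,
a retrieval-based recurrent memory network (REMERGE) and three encoding-based
"blend" competitors with mismatch-driven source judgments, trial-level
NLL/BIC model comparison, and three hierarchical Bayesian behavioral models
(accuracy, reaction time, logistic regression) fitted by MCMC. Because the
human data are not deposited, every analysis runs on synthetic data whose
generative structure matches the published group-level summaries; the test
suite and the acceptance script are parameter-recovery and model-property
studies on that synthetic ground truth.

## The task

Eighty object triplets A-B-C are studied as overlapping pairs A-B and B-C.
Memory is tested with two-alternative **choice** trials (cue on top, target
vs. a same-role foil from another triplet) for the studied AB and BC
relations and the never-studied AC relation, and with **source** trials that
follow every choice: was the chosen object "directly" presented with the cue,
or only "indirectly" related through an unseen item? Schedules:

- **Experiment 1**: 5 study-test cycles of 16 triplets; each pair studied
  once per cycle; 16 AB + 16 BC + 16 AC choice (and source) tests per cycle;
  AC tests precede the corresponding AB/BC tests. 10-s response cap.
- **Experiment 2**: all study before test; each pair studied twice within its
  session with a minimum 10-trial gap between an AB presentation and its
  related BC presentation; 240 choice + 240 source tests at the end; 5-s cap.
  The published session arithmetic is internally inconsistent (16 triplets
  per session but "32 associative trials" with every pair repeated twice);
  we keep 80 triplets and 16 per session, giving 64 study trials per session.
  The BC block is ordered round-robin by each triplet's last AB appearance,
  which guarantees a gap of at least 16.
- **Experiment 3**: as experiment 1, plus a scene before every BC study trial
  (8 novel / 8 familiar per session), a familiarization list of 40 scenes,
  and a final old/new recognition test (40 old, 20 foils).
- **Experiment 4**: as experiment 1, but AC tests omitted for exactly half
  the triplets (8 per cycle), with AB-before-BC order balanced separately
  within AC-tested and AC-omitted triplets.

Test order within a block is uniform random keys with a stable repair that
hands each triplet's smallest key to its AC trial. `validate_schedule`
checks every constraint and returns named violations; construction is
deterministic given a seed, and randomization never changes counts or
precedence (checked over many seeds in the tests).

## Network models

All models share one connectionist vocabulary: a **feature layer** (one unit
per object), a **conjunctive layer** (one unit per stored trace), and a
response readout. Feature units pass net input through a logistic at
temperature `tau_net` with a fixed offset `theta0` chosen so an unstimulated,
unconnected unit rests at 0.05 (`theta0 = tau_net * ln 19`); the offset gives
the mismatch signal a meaningful floor. Conjunctive units compete through a
softmax over the whole layer at the same temperature. Choice probabilities
are a two-option softmax over the response values of target and foil, where
response values are one feedforward projection of conjunctive activity
through the same weights.

**REMERGE** (5 free parameters) stores one conjunct per *studied pair* —
pattern-separated traces — with bidirectional symmetric weights `w_pair`
(feature <-> AB conjunct) and `w_pair - delta_bc` (feature <-> BC conjunct;
`delta_bc` implements proactive interference as a subtractive weight
reduction). Retrieval is an iterative constraint-satisfaction settling:
damped synchronous updates (damping 0.2) of

    a_c <- softmax(W' a_f / tau_net)
    a_f <- logistic((e + W a_c - theta0) / tau_net)

until the undamped residual falls below `tol` (default 1e-9; residual-based
stopping keeps the state within ~tol/(1-contraction) of the true fixed
point, which the tests verify against an independent root finder at 1e-6).
The dynamics are deterministic. Big-loop recurrence — output fed back as
input — lets a cue A activate its AB trace, recall B, and thereby activate
the BC trace: AC inference without any stored A-B-C representation.

**Blend models** are feedforward (one forward pass, plus one backward pass
only to compute mismatch) and implement encoding-based integration: blend_1
(4 parameters) stores a single ABC conjunct per triplet at weight `w_blend`;
blend_2 (5) adds pattern-separated AB and BC conjuncts at a shared `w_pair`;
blend_3 (6) additionally reduces the BC weight by `delta_bc`. Conjuncts with
zero encoding strength are dropped, so the nested variants reduce exactly
(blend_3(delta=0) = blend_2; blend_2(w_pair=0) = blend_1). Backward
reconstructions pass through the same logistic-with-offset so the mismatch
scale is commensurate with REMERGE.

### Source judgments: mismatching recall

Source judgments threshold the amount of *mismatching activity* on the
feature layer. We implement the recall-to-reject scheme of the mismatch
literature this mechanism descends from: the network is probed with **each
member of the judged pair in turn** (external input = that object alone);
each run's mismatch is the summed above-rest activation of feature units
outside the judged pair (per-unit rest subtracted, floored at zero, rest =
the no-input fixed point); the judgment uses the **stronger** of the two
runs. Then

    P("direct") = logistic((thresh - x) / tau_source),

strictly decreasing in the mismatch x and exactly 0.5 at `x = thresh` (the
published functional form is not printed; the logistic is our choice).

Why cue-by-cue probing rather than clamping the pair: under these update
equations a pair-clamped settle is winner-take-all at the fixed point, so the
partially active competing trace that carries the asymmetry signal cannot
survive, and the fitted model then predicts identical AB and BC source
performance — contradicting the mechanism the model family exists to
express. With cue-by-cue probing the mechanism works exactly as described:
cueing B during a B-C judgment partially activates the *A* unit (because AB
weights are stronger than BC weights), and that above-rest A activity is the
evidence that drags BC source judgments toward chance; cueing A or C during
an A-C judgment recalls B strongly, correctly signaling "indirect". Taking
the max over the two runs (rather than their sum) keeps the AB/BC symmetry at
`delta_bc = 0` exact while preserving the gradient. Structurally, blend_1's
single symmetric ABC trace yields *identical* mismatch for direct and
indirect probes under any parameters — its balanced source accuracy is
exactly one half — which is the architectural signature the model comparison
exploits.

## Model fitting

Trial likelihoods: a choice response has probability `p` or `1-p` from the
choice softmax; a source response `p_direct` or `1 - p_direct`. Source
trials whose parent choice was wrong are excluded (the judgment presumes the
chosen object); timeouts are dropped. The per-participant NLL divides the
summed negative log likelihood by the number of subjects; probabilities are
floored at 1e-12 inside logs only. `BIC = 2 * NLL + k * ln N` with `N` the
observation count pooled over subjects (24 x 480 for a full experiment-1
dataset) — the convention that reproduces the analytic chance row (NLL
480 ln 2 ~ 332.7, BIC ~ 664) exactly. The chance model (every probability
0.5, zero parameters) anchors the table.

Fitting is an exhaustive grid sweep (`NetworkGridFit`), with ties broken by
lexicographic parameter order. Because all triplets are architecturally
equivalent, category probabilities are computed once per parameter point from
representative trials, and settling results are shared across grid points
that differ only in `thresh`/`tau_source`. Default grids use round-number
coverage of the regime where the dynamics operate (weights a small multiple
of the temperature, asymmetries up to ~25% of `w_pair`); the sweep is
exhaustive within the grid by construction and the tests spot-check that
no grid point beats the winner.

## Synthetic behavior generator

The generator is the study-conditions oracle for every recovery test. Per
subject and category (relation x phase), accuracy rates are drawn from
Beta distributions in the mode/concentration parameterization
(`a = omega (kappa-2) + 1`, `b = (1-omega)(kappa-2) + 1`) with modes set to
each experiment's reported group summaries (experiment 1: choice .93/.89/.83,
source .83/.57/.69; experiment 2: choice .89/.80/.66, source .72/.50/.54;
experiment 3: choice .91/.88/.80, source .79/.59/.69; experiment 4 reuses
experiment 1's profile). Defaults chosen where the study reports none, fixed
once:

- `kappa = 50`: between-subject accuracy SD 0.04-0.07, consistent with the
  width of the published group-level 95% HDIs at n = 24.
- AC-choice correctness is not drawn from a Beta but from the logistic model
  `logit p = beta0 + 0.66 x_ABsource + 0.70 x_BCsource + 0 x_ACsource +
  0.72 x_BCchoice + b_s` (experiment-1 coefficient values; the AC-source
  coefficient is unreported and defaults to 0), `b_s ~ Normal(0, 0.5)`; the
  intercept is calibrated by Monte Carlo root-finding so the marginal AC
  accuracy matches its configured mode within 0.005.
- log RTs are Student-t with `nu = 5`, scale 0.35, a per-subject shift of SD
  0.15, locations set so the back-transformed category values equal the
  published choice-RT means (2.80/3.55/4.70 s in experiment 1); source-trial
  locations are anchored to the published AB-vs-BC/AC contrasts (absolute
  source RTs were not printed). Draws are truncated at the response cap by
  rejection. Timeouts default to rate 0 (rates were not reported); when
  enabled, a timed-out choice also times out its source probe.
- Experiment 3: the novelty factor shifts the log-odds of novel-scene
  triplets by `novelty_effect` (default 0 — the study found no credible
  effect), and scene recognition is independent Bernoulli (hit rate 0.45,
  false-alarm rate 0.16, corrected hit rate 0.29), so subsequent-memory
  splits are null by construction.

AB/BC choice and all source correctness are independent across triplets given
the subject rates; correlation enters only through the AC logistic model —
exactly the dependence the hierarchical regression estimates. What the
generator does *not* emulate: learning across cycles, item-level memorability,
sequential effects, and any choice-RT coupling; passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
assumed generative structure, not robustness to violations of it. Identical
config and seed give byte-identical CSVs, and the latent per-subject rates
are returned for recovery and calibration tests.

## Hierarchical Bayesian models

All three models are sampled with a blocked adaptive Metropolis-within-Gibbs
sampler written for this package: conditionally independent blocks
(per-category, per-subject parameters) are proposed and accepted jointly in
one vectorized likelihood pass; proposal scales adapt per component toward
0.44 acceptance during warm-up and are frozen afterwards; extra
translation moves along the likelihood-invariant baseline-vs-deflection
directions fix the slowly mixing ridge that plagues redundantly parameterized
hierarchical models. The published analyses used a Gibbs engine at 5 chains x
60k-85k draws with thinning 5; the contract is the posterior, not the
sampler, so defaults here are a test scale of 4 chains x 5000 draws (2000
burn-in, 1000 adaptation, no thinning), with the published run lengths
available via `MCMCConfig.paper_scale()`.

**Accuracy**: per subject s and category j, `y ~ Binomial(N, p)`,
`p ~ Beta(mode omega_js, concentration kappa_j)`, `omega = logistic(beta0 +
beta_j + beta_s [+ beta_k + beta_jk])`. The subject-level p is marginalized
analytically (beta-binomial) for sampling and reconstructed exactly by
conjugacy when reporting. Priors (the published "fixed hyperparameters" are
not printed; each is a config constant here): `kappa - 2 ~ Gamma(0.01,
0.01)`, deflection scales folded-t(df 4, scale 10), `beta0 ~ Normal(0, 10)`.
Deflections are identified by post-hoc sum-to-zero recentering with
compensation into the baseline. Reported category accuracy is the average
of subject-level p draws; the mode-scale `logistic(beta0 + beta_j)` is also
summarized. Contrasts are elementwise differences of draws, "credible" when
the 95% HDI excludes zero.

**Reaction time**: log-transformed, `y ~ Student-t(nu, mu, sigma_j)`, `mu =
beta0 + beta_j + beta_s`, per-category scales with folded-t priors, `nu ~
Exponential(mean 30)`, baseline prior SD tied to the data SD. Fitted per
phase (choice/source, 3 relation levels). Summaries are reported in seconds
by exponentiating the location posterior before summarizing.

**Logistic regression**: AC-choice correctness on the four same-triplet
indicators (AB/BC/AC source, BC choice; AB choice excluded as collinear with
AB source), plus a subject effect. Coefficient priors Normal(0, 100); the
subject-effect scale gets a folded-t hyperprior rather than a fixed broad
Normal — perfectly scoring subjects (separation) are regularized by the
hierarchy instead of drifting to the prior edge. Odds ratios are
exp(coefficient) draws. Rows with identical (subject, indicator pattern) are
aggregated to binomial counts; the likelihood is unchanged.

Diagnostics: classic Gelman-Rubin potential scale reduction, ESS by Geyer's
initial positive-pair sequence on chain-averaged autocorrelations, FFT-based
ACF, and the narrowest-interval HDI. Fits flag (but do not discard)
posteriors whose worst rhat exceeds 1.1; on well-posed synthetic data the
mean rhat is at or below 1.01, which the tests assert. arviz serves as an
independent cross-check of rhat/ESS/HDI in the test suite, never as the
implementation.

## Numerical and design choices worth knowing

- Cue/target conventions: the cue is the earlier item of the relation (A for
  AB and AC, B for BC); foils are same-role objects from another triplet of
  the same 16-triplet context. The network context defaults to 16 triplets —
  one study-test cycle's worth of competing traces.
- The exact AB/BC choice-trial symmetry at `delta_bc = 0` is approximate
  (the two trial types are not graph-isomorphic given the cue conventions;
  probabilities agree to ~1e-5); source mismatches are exactly symmetric.
- Dataset problem sizes in the tests follow the study (24/21/16/16 subjects);
  the regression recovery uses more subjects (300-500) because coefficient
  recovery at +/-0.1 needs them, and the qualitative fitted-profile check
  uses 96 subjects so it measures the model, not small-sample noise.
- Recovery caveat: with category accuracy reported as the average of
  subject-level p draws, the estimand is the mean of the Beta, which sits
  slightly below the generating mode for high-accuracy categories (0.913
  vs 0.93 at omega = .93, kappa = 50); this bias is well inside the recovery
  tolerances but visible.
- The sweep's NLL landscape has two near-tied regimes for the source
  parameters (a graded-mismatch compromise and a sharper regime with BC
  source near chance); which wins can flip under 24-subject sampling noise,
  which is why the qualitative profile is asserted at larger n.

## Limitations

The networks set weights by hand (no study-phase learning), read out a single
settled state (no reaction-time predictions), and the blend family does not
cover other encoding-based formalisms (e.g. temporal context models). The
sampler is a random-walk scheme: adequate for these posteriors at the tested
scales, slower-mixing than gradient-based samplers for much larger models.
Fitted NLL/BIC values on the *real* data cannot be reproduced without the
undeposited behavioral data; the chance-model row is exact, and all other
quantitative checks are recovery properties on synthetic data.
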