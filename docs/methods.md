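# Methods

This note records the modeling choices behind `tlab`: the update rules, the
statistical model and its priors, what the synthetic-data generators do and
do not emulate, numerical conventions, and known limitations. Nothing here
states an empirical result that the test suite or the acceptance script does
not itself compute.

## 1. Testimony models

### Binary-reliability network (`tlab.models.BHState`, `bh_update`)

Three variables: the hypothesis HYP, the source's binary reliability REL,
and the report. HYP and REL are independent a priori with P(HYP) = h and
P(REL) = ρ. A reliable source asserts the true polarity with certainty; an
unreliable source asserts "positive" with probability *a* regardless of the
truth. We analyze the unbiased case a = 0.5 throughout but expose *a* as a
parameter, since biased randomization is a meaningful variant. Conditioning
on a report updates both marginals in closed form; the implementation is
checked to 1e-12 against an eight-cell enumeration oracle.

Consequences used downstream: belief moves toward the asserted polarity
whenever the source is net informative; ρ′ > ρ after a positive report
exactly when h > 0.5 (expected claims raise trust, unexpected claims lower
it); and ρ = 0 makes reports inert (an unreliable source is merely
uninformative — this model cannot produce belief *reversal*).

### Reliability-profile model (`ReliabilityGrid`, `OAJointState`, `oa_update`)

The source carries a truth-telling propensity τ ∈ [0, 1]; the recipient
holds a distribution over profiles, tracked jointly with HYP. Reports are
conditionally independent given (HYP, τ), with P(assert truth | τ) = τ —
the minimal reading of a profile that can be negatively correlated with the
truth. τ < 0.5 is anti-reliability: a positive report lowers belief when
all mass sits below 0.5 (property-tested), and τ = 0 maximal
anti-reliability.

The profile distribution is a **discrete grid** (default 101 equally spaced
points, uniform prior; both configurable). A parametric family (e.g. Beta)
was deliberately avoided: the grid makes every posterior an exactly
computable finite sum, so sequential updates can be verified against
single-shot conditioning to 1e-10, and no claim is smuggled in about the
original model's (unstated) prior family. The binary model embeds exactly
as the two-point grid {τ = 0.5: 1 − ρ, τ = 1: ρ}; the embedding is only
valid for a = 0.5 and raises otherwise.

Degenerate evidence (a report with zero marginal likelihood, e.g. certainty
plus a perfectly informative contradicting source) raises
`ImpossibleEvidenceError` rather than renormalizing garbage — silent NaNs
would corrupt every later update in a sequence.

### Two-claim carry-over (`second_claim_posterior`)

For the two-claim paradigm, one source asserts two propositions with
independent priors and a single shared τ. That sharing *is* the paradigm's
premise: reliability learned from the first claim carries to the second.
Conditioning on both assertions gives the second claim's posterior; with a
uniform τ prior and a neutral (0.5) second claim, this reduces to E[τ |
first assertion], making the direction of the carry-over effect transparent.
The "null" condition is treated as the unconditioned prior (no first
assertion), since nothing else is determined by the design.

### Default prediction scenario

`predict_experiment` defaults: claim priors 0.8 (expected) / 0.2
(unexpected); high-reliability source P(REL) = 0.8 for the binary model and
its exact two-point embedding for the profile model (so the models agree
wherever they should); low-reliability source P(REL) = 0 (binary) versus a
point profile τ = 0.2 (profile). The divergence table then contains
exactly the disagreements the models actually have: belief change from
unreliable sources, and the valence of a second claim after an unexpected
first claim.

## 2. Agent society (`tlab.society`)

No concrete simulator mechanics are fixed by the theory; this module's
choices are a deliberately minimal stand-in sufficient to exhibit the
polarization mechanism, not a reconstruction of any published simulation:

- agents hold one shared-hypothesis belief and an independent trust grid
  per peer (21 points; no second-order trust);
- per round, speakers take the floor in a random order; an agent asserts
  positive when belief > 0.75, negative when belief < 0.25, else stays
  silent (threshold configurable in [0.5, 1));
- each listener conditions the product joint (own belief × trust in the
  speaker) with the profile-model update, then keeps the two marginals.
  Keeping marginals rather than a full joint over all peers is an
  independence approximation that keeps the state linear in society size;
- `allow_anti_reliability=False` truncates every trust grid to [0.5, 1],
  which provably makes every heard assertion pull the listener toward the
  asserted polarity;
- initial beliefs come from a two-component Beta mixture, default
  0.5·Beta(8, 2) + 0.5·Beta(2, 8) — a population already split on the
  issue; topology defaults to complete.

Two dispersion metrics are reported side by side without privileging
either: across-agent belief variance, and the fraction of agents with
belief outside (0.1, 0.9). A green polarization test establishes only the
qualitative mechanism — that admitting anti-reliable trust sustains
extremity that truncated trust dissolves — under these specific mechanics.

## 3. Synthetic data (`tlab.synth`)

The emulated studies reported only Likert summaries, never a generative
model, so the generator is built to match the *analysis* model's
assumptions (t-distributed participant-level effects), making parameter
recovery well-posed:

- per participant, a latent change score (pre/post designs) or endorsement
  level (two-claim design) is drawn from t(μ_c, σ_c, ν_c) for the
  condition's primary factor level;
- per item, ratings add a fixed zero-mean item offset (sd 0.5; offsets
  cancel in change scores and in expectation across items) and Gaussian
  noise (sd 0.5), then are clipped to [0, 10] **before** rounding; rounding
  is half-away-from-zero; ratings are integers, as the original scales
  almost certainly were;
- initial-rating means default to 7 (expected claims) and 3 (unexpected) —
  unexpected claims are implausible but not known-false;
- default per-condition sample sizes divide the emulated studies' total N
  evenly (25/33/20/20 per cell; 139 per two-claim condition), and default
  latent effects are the location/scale estimates those studies reported,
  with ν = 30;
- the two-claim endorsement means reproduce the reported between-condition
  differences (expected − null = 0.09, null − unexpected = 0.56) around a
  neutral baseline of 5.

The **model-driven mode** replaces the distributional latents with
quantities computed from the profile model (prior and posterior belief, or
prior and posterior E[τ], scaled by 10), so the directional structure of
the data is mathematically guaranteed rather than parameterized. Its
source grids are dispersed two-point grids (E[τ] = 0.9 high, 0.26 low) so
that perceived reliability itself is learnable.

Not emulated: item-order effects (counterbalanced and unanalyzed in the
originals), participant-level response styles, non-integer responses, and
any dependence between the two factors beyond the latent effects.

## 4. Robust estimation (`tlab.robust`)

Likelihood: each observation t-distributed with location μ_g, scale σ_g,
degrees of freedom ν; the two-group model shares one ν ("only one
parameter for normality"). Priors, set from the pooled data:

| parameter | prior | rationale |
| --- | --- | --- |
| μ_g | Normal(mean(D), 100·sd(D)) | vague; "precision equivalent to 100 sd" read as prior sd = 100 × sample sd |
| σ_g | Uniform(sd(D)/1000, 1000·sd(D)) | the conventional broad interval |
| ν − 1 | Exponential(mean 29) | ≈ 63/37 prior split between heavy-tailed (ν < 30) and near-normal regimes — the standard "roughly equal credibility" default |

The ν-prior rate is configurable; `nu_floor` truncates ν from below, which
pins the likelihood to the near-normal regime for conjugate-limit checks.

Sampler: Metropolis-within-Gibbs with univariate Gaussian random walks on
(μ_g, log σ_g, log(ν − nu_floor)); per-parameter proposal scales adapt
every 50 iterations during burn-in toward 44% acceptance and are frozen
afterwards, preserving detailed balance for the recorded draws. Defaults:
100,000 recorded steps, 10,000 burn-in, no thinning; the pipeline's
reduced setting (10,000 / 2,000) is used in tests and the acceptance
script, with the `--faithful` flag restoring full length. The sampler is
vectorized over a batch axis so Monte-Carlo studies run one array-level
chain set. Correctness is established against two independent oracles: a
dense (μ, σ, ν) grid integration of the identical unnormalized posterior,
and the conjugate normal-model solution in the truncated-ν limit.

Diagnostics: effective sample size (via `arviz.ess`) is reported per
quantity; ESS(μ) < 1,000 raises a warning, and a hard floor (default 50)
raises `SamplerDivergenceError` — a chain that poorly mixed must never be
summarized silently.

Derived quantities: log10(ν); standardized effect (μ − c)/σ per draw
(comparison value c defaults to 0); for two groups,
(μ₁ − μ₂)/√((σ₁² + σ₂²)/2) — a package convention (the root-mean-square of
the group scales), recorded in the model spec, reducing to (μ₁ − μ₂)/σ for
equal scales.

### HDI and posterior mode

The 95% HDI is the narrowest window over ⌈0.95·n⌉ sorted draws, ties broken
toward the lowest start index. Note a limitation of any sample-based
shortest-window estimator: strict nesting of the 99% inside-out of the 95%
interval can fail for ragged heavy-tailed draw vectors (width monotonicity
always holds, and nesting holds for smooth unimodal posteriors). The
posterior mode is the maximizer of a Gaussian KDE evaluated on a 512-point
grid over the draw range; constant draw vectors short-circuit to the
constant. Both require ≥ 100 draws.

## 5. Decision grammar (`tlab.decisions`)

Scores: pre/post designs use the per-participant mean of (final − initial)
across items; the two-claim design uses the per-participant mean rating.
Decisions are made on the **effect-size** HDI against a ROPE of [−0.1, 0.1]
(both configurable): HDI disjoint from the ROPE → effect; HDI contained →
practical null; otherwise undecided. A shared endpoint is a zero-length
intersection and counts as disjoint (→ effect); the trichotomy is
exhaustive and mutually exclusive by construction and property-tested.
Because "how much the HDI overlaps the ROPE" admits two natural readings,
both are reported: absolute overlap length and the fraction of the HDI's
extent inside the ROPE; neither is privileged.

Hypothesis verdicts combine decision and posterior-mean sign: H1 (reliable
sources raise belief), the mutually exclusive pair H2(i) (unreliable
sources lower belief — anti-reliability) / H2(ii) (no change), H3 / H4
(expected / unexpected claims raise / lower perceived reliability), and the
two-claim carry-over contrast. An undecided decision yields an undecided
verdict; a practical null supports H2(ii) and refutes directional
hypotheses.

## 6. Pipeline and reproducibility

`replicate_all` derives one generation seed and one fitting seed per
experiment from the master seed via `SeedSequence`, logs every stage as
JSON-lines, and writes a manifest (config hash, seeds, outputs, wall-clock)
sufficient to re-run any stage in isolation. Identical config + seed gives
bit-identical tables and reports (timing aside). Two-claim contrasts are
ordered (expected, null), (null, unexpected), (expected, unexpected), so a
positive effect means the theoretically higher condition is higher.

## 7. Known limitations

- The profile-model grid introduces O(1/points) discretization error;
  tests use 101–1001 points where precision matters.
- The society simulator makes no quantitative claim; its scheduling,
  thresholds and mixtures are package choices.
- Printed posterior summaries of the original studies cannot be reproduced
  because the participant data were never deposited; the pipeline
  establishes properties (directions, calibration, decision grammar), not
  those numbers.
- The two-group effect-size denominator and the exact ν-prior rate are
  conventions where the source methods leave them unstated; both are
  configurable and flagged in output metadata.
- Random-walk MCMC is adequate at these dimensions (3–5 parameters) but
  would mix poorly for hierarchical extensions; any sampler passing the
  grid-oracle test is conformant.
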