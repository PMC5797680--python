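# tlab

Bayesian models of testimony, synthetic Likert-scale experiments, and robust
Bayesian re-analysis — an end-to-end desk-scale laboratory for studying the
**bi-directional relationship between message content and source
reliability**.

When a source asserts a claim, a rational recipient should update two things
at once: belief in the claim (moderated by how reliable the source seems)
and belief in the source's reliability (moderated by how plausible the claim
was). `tlab` implements the two classic formal accounts of this process,
derives their competing predictions, generates synthetic experimental data
with the corresponding structure, and re-analyzes such data with robust
Bayesian estimation and an HDI + ROPE decision rule.

## Who this is for

Computational cognitive scientists and formal epistemologists who want
runnable, oracle-tested implementations of source-reliability updating
models; and methodologists who want a self-contained, from-scratch robust
Bayesian estimation pipeline (t-likelihood, vague priors, MCMC, highest-
density intervals, regions of practical equivalence) for Likert-style
pre/post designs.

## The models

**Binary-reliability network.** A report Rep depends on the hypothesis HYP
and a binary reliability variable REL. A reliable source (probability
ρ = P(REL)) asserts the truth; an unreliable one asserts "positive" with
probability *a* (default 0.5 — a coin flip). Conditioning on a positive
report gives

    P(pos) = hρ + a(1 − ρ),   h′ = (hρ + h(1 − ρ)a) / P(pos),   ρ′ = hρ / P(pos),

so belief and perceived reliability move together: an unexpected claim
(h < 0.5) drags ρ down, and a maximally unreliable source (ρ = 0) is merely
uninformative.

**Reliability-profile model.** The source instead carries a latent
truth-telling propensity τ ∈ [0, 1] with a full distribution over profiles,
tracked *jointly* with the hypothesis. A positive report reweights the
joint by τ on the HYP-true sheet and (1 − τ) on the HYP-false sheet.
Profiles with τ < 0.5 are **anti-reliable**: a positive assertion from such
a source is evidence *against* the claim. The binary model embeds exactly
as the two-point prior {τ = 0.5 with mass 1 − ρ, τ = 1 with mass ρ}.

The models disagree only about unreliable sources — uninformative versus
actively disbelieved — and `tlab.pipeline.predict_table()` isolates exactly
that divergence. A seeded multi-agent simulator (`tlab.society`) shows the
population-level consequence: with anti-reliable trust admitted, a bimodal
society stays polarized; with trust truncated to [0.5, 1], it drifts to
consensus.

## The analysis pipeline

Participant-level scores (mean pre-to-post rating change, or mean
endorsement of a second claim) are modeled as draws from a t-distribution
with location μ, scale σ and normality ν (one-group), or two locations and
scales with a shared ν (two-group). Priors are the conventional vague
defaults: μ ~ Normal(mean(D), 100·sd(D)); σ ~ Uniform(sd/1000, 1000·sd);
ν − 1 ~ Exponential(mean 29). Sampling is adaptive Metropolis-within-Gibbs,
validated against brute-force grid integration of the same posterior. The
95% HDI of the standardized effect (μ − 0)/σ is compared against a ROPE of
[−0.1, 0.1]: entirely outside → effect; entirely inside → practical null;
otherwise → undecided.

## Worked example

```python
from tlab.models import BHState, POSITIVE, bh_update

bh_update(BHState(h=0.3, rho=0.6), POSITIVE)
# BHState(h=0.631578947368421, rho=0.47368421052631576, a=0.5)
```

An unexpected claim (prior 0.3) asserted by a fairly trusted source: belief
in the claim rises to 0.63, but trust in the source *falls* from 0.60 to
0.47 — the bi-directional signature.

The full pipeline, with synthetic data whose latent structure comes from the
profile model (so effect directions are guaranteed by construction):

```bash
tlab replicate-all --seed 11 --out runs/full --model-driven
```

From `runs/full/exp1a_report.json` (reduced 10,000-step chains):

```
reliable_sources    mu mean  3.26   effect-size mode  1.81, 95% HDI [ 1.36,  2.29]  -> effect
unreliable_sources  mu mean -1.58   effect-size mode -2.25, 95% HDI [-2.87, -1.70]  -> effect
verdicts: H1 supported, H2i supported, H2ii refuted
```

Reliable sources credibly raised belief (supporting H1: reliable sources
increase belief in a claim) and unreliable sources credibly *lowered* it —
supporting the anti-reliability alternative H2(i) and refuting the
uninformativeness alternative H2(ii). Use `--faithful` for full
100,000-step chains.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the package's main computation from scratch: model predictions for
both testimony models, model-driven synthetic data for all five emulated
designs, robust fits with ROPE decisions and hypothesis verdicts, and a
seeded agent-society run. Intermediate reports are written next to the
output file; the JSON output records the (empty) set of numeric targets.

## Layout

| module | contents |
| --- | --- |
| `tlab.models` | both testimony models, enumeration oracles, prediction generator, scenario YAML I/O |
| `tlab.society` | seeded multi-agent trust/polarization simulation |
| `tlab.synth` | synthetic rating-table generators (distributional and model-driven) |
| `tlab.robust` | robust Bayesian estimation: t-likelihood, MCMC, HDI, posterior mode |
| `tlab.decisions` | change scores, ROPE decisions, hypothesis verdicts |
| `tlab.pipeline` / `tlab.cli` | reproducible runs, manifests, `tlab` command |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
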