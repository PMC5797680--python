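"""Score computation and the HDI + ROPE decision grammar.

Analyses proceed on one scalar per participant: for the pre/post designs the
*change score* (mean over items of final minus initial rating), and for the
two-claim design the *endorsement mean* (mean rating of the second claim).
A fitted posterior's 95% highest-density interval for the standardized
effect size is then compared against a region of practical equivalence
(ROPE) around the comparison value:

* HDI entirely outside the ROPE  -> a credible **effect**;
* HDI entirely inside the ROPE   -> a **practical null**;
* otherwise                      -> **undecided**.

A shared endpoint (zero-length intersection) counts as outside, hence
'effect'.  Hypothesis-level verdicts combine the decision with the sign of
the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RatingTable

__all__ = [
    "ScoreSet",
    "Rope",
    "RopeDecision",
    "compute_scores",
    "rope_decision",
    "hypothesis_verdicts",
    "HYPOTHESES",
]


@dataclass(frozen=True)
class ScoreSet:
    """One scalar score per participant, with condition labels.

    provenance is "change_score" (bounded by the rating scale to [-10, 10])
    or "endorsement_mean" (bounded to [0, 10]).
    """

    scores: pd.DataFrame  # columns: participant_id, condition columns..., score
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in ("change_score", "endorsement_mean"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.scores["participant_id"].duplicated().any():
            raise ValueError("one score per participant required")
        s = self.scores["score"]
        lo, hi = (-10.0, 10.0) if self.provenance == "change_score" else (0.0, 10.0)
        if (s < lo).any() or (s > hi).any():
            raise ValueError(f"scores outside [{lo}, {hi}] for {self.provenance}")

    def values(self, **condition_filters: str) -> np.ndarray:
        sub = self.scores
        for col, val in condition_filters.items():
            sub = sub[sub[col] == val]
        return sub["score"].to_numpy()


def compute_scores(table: RatingTable) -> ScoreSet:
    """Collapse a rating table to per-participant scores.

    Pre/post designs: mean over items of (final - initial).  Two-claim
    design: mean rating over items.  A participant with a missing item is an
    error (the emulated studies had complete data by construction).
    """
    df = table.data
    counts = df.groupby("participant_id", sort=False).size()
    incomplete = counts[counts != table.design.n_items]
    if len(incomplete) > 0:
        raise ValueError(
            "participants with missing items: " + ", ".join(map(str, incomplete.index.tolist()))
        )
    if table.design.is_change_design:
        work = df.assign(change=df["final_rating"] - df["initial_rating"])
        grouped = (
            work.groupby(
                ["participant_id", "claim_expectedness", "source_reliability"], sort=False
            )["change"]
            .mean()
            .reset_index()
            .rename(columns={"change": "score"})
        )
        return ScoreSet(grouped, "change_score")
    grouped = (
        df.groupby(["participant_id", "first_claim_condition"], sort=False)["rating"]
        .mean()
        .reset_index()
        .rename(columns={"rating": "score"})
    )
    return ScoreSet(grouped, "endorsement_mean")


@dataclass(frozen=True)
class Rope:
    """Region of practical equivalence on the effect-size scale."""

    lower: float = -0.1
    upper: float = 0.1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("rope lower bound must be below upper bound")


@dataclass(frozen=True)
class RopeDecision:
    """Trichotomous outcome of comparing a 95% HDI with a ROPE."""

    decision: str  # "effect" | "practical_null" | "undecided"
    hdi: tuple[float, float]
    rope: Rope
    overlap_length: float
    hdi_fraction_in_rope: float


def rope_decision(hdi: tuple[float, float], rope: Rope | None = None) -> RopeDecision:
    """Classify an HDI against a ROPE.

    'effect' iff the intersection is empty (a shared endpoint has zero-length
    intersection and counts as empty); 'practical_null' iff the HDI lies
    within the ROPE; 'undecided' otherwise.  Both the absolute overlap length
    and the fraction of the HDI's extent inside the ROPE are reported, since
    'how much overlap' admits either reading.
    """
    rope = rope or Rope()
    lo, hi = float(hdi[0]), float(hdi[1])
    if lo > hi:
        raise ValueError(f"inverted HDI ({lo}, {hi})")
    overlap = max(0.0, min(hi, rope.upper) - max(lo, rope.lower))
    width = hi - lo
    fraction = 1.0 if width == 0 and overlap >= 0 and rope.lower <= lo <= rope.upper else (
        overlap / width if width > 0 else 0.0
    )
    if overlap <= 0.0 and not (rope.lower <= lo and hi <= rope.upper):
        decision = "effect"
    elif rope.lower <= lo and hi <= rope.upper:
        decision = "practical_null"
    else:
        decision = "undecided"
    return RopeDecision(decision, (lo, hi), rope, overlap, fraction)


# Hypothesis grammar: each hypothesis names the analysis it reads and the
# predicted sign of the effect.  H2 comes as mutually exclusive alternatives:
# (i) anti-reliability (unreliable sources actively lower belief) and
# (ii) mere uninformativeness (no belief change).
HYPOTHESES = {
    "H1": ("reliable_sources", "positive"),
    "H2i": ("unreliable_sources", "negative"),
    "H2ii": ("unreliable_sources", "null"),
    "H3": ("expected_claims", "positive"),
    "H4": ("unexpected_claims", "negative"),
    "H_carryover": ("expected_vs_unexpected", "positive"),
}


def _verdict(decision: RopeDecision, mean_sign: float, predicted: str) -> str:
    if decision.decision == "undecided":
        return "undecided"
    if predicted == "null":
        return "supported" if decision.decision == "practical_null" else "refuted"
    if decision.decision == "practical_null":
        return "refuted"
    observed = "positive" if mean_sign > 0 else "negative"
    return "supported" if observed == predicted else "refuted"


def hypothesis_verdicts(
    analyses: dict[str, tuple[RopeDecision, float]]
) -> dict[str, str]:
    """Map per-analysis (decision, posterior-mean sign) pairs to verdicts.

    ``analyses`` keys are analysis names as in :data:`HYPOTHESES` (e.g.
    "reliable_sources"); values are (RopeDecision, posterior mean of the
    effect).  Returns {hypothesis: "supported" | "refuted" | "undecided"},
    covering every hypothesis whose analysis is present.  A missing analysis
    for a requested hypothesis set is an error only when nothing matches.
    """
    verdicts: dict[str, str] = {}
    for hyp, (analysis, predicted) in HYPOTHESES.items():
        if analysis not in analyses:
            continue
        decision, mean = analyses[analysis]
        verdicts[hyp] = _verdict(decision, mean, predicted)
    if not verdicts:
        raise ValueError(
            f"no recognized analyses among {sorted(analyses)}; "
            f"expected names like {sorted({a for a, _ in HYPOTHESES.values()})}"
        )
    return verdicts
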