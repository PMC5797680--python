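"""Bayesian models of testimony: binary-reliability and reliability-profile updating.

Two classic formal models of how a recipient should revise beliefs on hearing
an assertion from a partially reliable source:

* The **binary-reliability network** (:class:`BHState`, :func:`bh_update`):
  a three-node belief network over the hypothesis HYP, the source's binary
  reliability REL, and the report.  A reliable source asserts the truth; an
  unreliable one asserts "positive" with probability ``a`` (a coin flip when
  ``a = 0.5``) regardless of the truth.  Both P(HYP) and P(REL) are revised
  by Bayes' rule on each report.

* The **reliability-profile model** (:class:`OAJointState`, :func:`oa_update`):
  the source carries a latent truth-telling propensity tau in [0, 1] with a
  distribution over profiles, tracked jointly with the hypothesis.  Profiles
  below 0.5 are *anti-reliable*: a positive assertion from such a source is
  evidence against the claim.

The binary model embeds in the profile model as a two-point prior on
{tau = 0.5, tau = 1} (:func:`oa_from_bh`), which only holds for the unbiased
randomization case ``a = 0.5``.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Polarity",
    "BinaryReport",
    "POSITIVE",
    "NEGATIVE",
    "BHState",
    "ReliabilityGrid",
    "OAJointState",
    "PredictionRecord",
    "Scenario",
    "ImpossibleEvidenceError",
    "bh_update",
    "bh_enumeration_oracle",
    "oa_update",
    "oa_belief",
    "oa_expected_reliability",
    "oa_from_bh",
    "sequence_update",
    "second_claim_posterior",
    "predict_experiment",
    "load_scenario",
    "trajectory_to_csv",
]

_EPS = 1e-300
_DIRECTION_TOL = 1e-12


class ImpossibleEvidenceError(ValueError):
    """The observed report has zero marginal likelihood under the prior state."""


class Polarity(str, enum.Enum):
    """Polarity of an assertion: the source claims the hypothesis is true or false."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    def negate(self) -> "Polarity":
        return Polarity.NEGATIVE if self is Polarity.POSITIVE else Polarity.POSITIVE


@dataclass(frozen=True)
class BinaryReport:
    """A single assertion by a source, for or against the hypothesis."""

    polarity: Polarity = Polarity.POSITIVE

    def __post_init__(self) -> None:
        object.__setattr__(self, "polarity", Polarity(self.polarity))

    def negate(self) -> "BinaryReport":
        return BinaryReport(self.polarity.negate())


POSITIVE = BinaryReport(Polarity.POSITIVE)
NEGATIVE = BinaryReport(Polarity.NEGATIVE)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class BHState:
    """Belief state of the binary-reliability network.

    Parameters
    ----------
    h
        Prior degree of belief P(HYP) that the hypothesis is true.
    rho
        Prior probability P(REL) that the source is reliable (truth-telling).
    a
        Randomization bias: the probability that an *unreliable* source
        asserts the positive polarity.  ``a = 0.5`` is the unbiased
        coin-flip case analysed throughout; other values model sources
        biased toward positive or negative reports.
    """

    h: float
    rho: float
    a: float = 0.5

    def __post_init__(self) -> None:
        _check_prob("h", self.h)
        _check_prob("rho", self.rho)
        _check_prob("a", self.a)


def _bh_report_likelihoods(state: BHState, report: BinaryReport) -> np.ndarray:
    """P(report | HYP, REL) over the four joint cells, as a 2x2 array.

    Axis 0 indexes HYP in {true, false}; axis 1 indexes REL in {reliable,
    unreliable}.  A reliable source asserts the truth with certainty; an
    unreliable one asserts positive with probability ``a``.
    """
    a = state.a
    p_pos = np.array([[1.0, a], [0.0, a]])
    if report.polarity is Polarity.POSITIVE:
        return p_pos
    return 1.0 - p_pos


def bh_update(state: BHState, report: BinaryReport) -> BHState:
    """Condition the binary-reliability network on one report.

    Returns the posterior state with ``h' = P(HYP | report)`` and
    ``rho' = P(REL | report)``; the randomization bias is a fixed model
    parameter and is carried over unchanged.

    Raises
    ------
    ImpossibleEvidenceError
        If the report has zero probability under the prior (e.g. a fully
        reliable source asserting a hypothesis the recipient is certain
        is false).
    """
    h, rho = state.h, state.rho
    lik = _bh_report_likelihoods(state, report)
    joint = np.array([[h * rho, h * (1 - rho)], [(1 - h) * rho, (1 - h) * (1 - rho)]])
    post = joint * lik
    marginal = post.sum()
    if marginal <= _EPS:
        raise ImpossibleEvidenceError(
            f"report {report.polarity.value!r} has zero marginal likelihood "
            f"under state {state!r}"
        )
    post /= marginal
    return BHState(h=float(post[0].sum()), rho=float(post[:, 0].sum()), a=state.a)


def bh_enumeration_oracle(state: BHState, report: BinaryReport) -> BHState:
    """Reference implementation of :func:`bh_update` by exhaustive enumeration.

    Tabulates all eight joint outcomes (HYP, REL, Rep), conditions on the
    observed report by discarding inconsistent rows, and reads off the
    posterior marginals.  Intended for testing only; O(1) but deliberately
    naive.
    """
    h, rho, a = state.h, state.rho, state.a
    mass_h, mass_hyp = 0.0, 0.0
    marginal = 0.0
    for hyp in (True, False):
        p_hyp = h if hyp else 1 - h
        for rel in (True, False):
            p_rel = rho if rel else 1 - rho
            for rep_positive in (True, False):
                if rel:
                    p_rep = 1.0 if rep_positive == hyp else 0.0
                else:
                    p_rep = a if rep_positive else 1 - a
                p = p_hyp * p_rel * p_rep
                observed = report.polarity is Polarity.POSITIVE
                if rep_positive != observed:
                    continue
                marginal += p
                if hyp:
                    mass_hyp += p
                if rel:
                    mass_h += p
    if marginal <= _EPS:
        raise ImpossibleEvidenceError(
            f"report {report.polarity.value!r} has zero marginal likelihood "
            f"under state {state!r}"
        )
    return BHState(h=mass_hyp / marginal, rho=mass_h / marginal, a=a)


@dataclass(frozen=True)
class ReliabilityGrid:
    """Discrete distribution over truth-telling propensities tau in [0, 1].

    ``tau`` must be strictly increasing; ``weights`` are renormalized to sum
    to one (an input off by more than 1e-6 is rejected as malformed).
    """

    tau: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if tau.ndim != 1 or tau.shape != w.shape or tau.size == 0:
            raise ValueError("tau and weights must be matching 1-D arrays")
        if np.any(tau < 0) or np.any(tau > 1) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau values must be strictly increasing within [0, 1]")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        total = w.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1 (got {total})")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def uniform(cls, n_points: int = 101) -> "ReliabilityGrid":
        """Uniform prior over ``n_points`` equally spaced profiles on [0, 1]."""
        tau = np.linspace(0.0, 1.0, n_points)
        return cls(tau, np.full(n_points, 1.0 / n_points))

    @classmethod
    def point_mass(cls, tau: float) -> "ReliabilityGrid":
        return cls(np.array([float(tau)]), np.array([1.0]))

    @classmethod
    def two_point(cls, tau_lo: float, tau_hi: float, mass_hi: float) -> "ReliabilityGrid":
        return cls(
            np.array([float(tau_lo), float(tau_hi)]),
            np.array([1.0 - mass_hi, mass_hi]),
        )

    def truncated(self, lo: float = 0.5, hi: float = 1.0) -> "ReliabilityGrid":
        """Restrict support to [lo, hi] and renormalize (drops anti-reliable mass)."""
        keep = (self.tau >= lo) & (self.tau <= hi)
        if not keep.any() or self.weights[keep].sum() <= 0:
            raise ValueError("truncation removes all probability mass")
        return ReliabilityGrid(self.tau[keep], self.weights[keep] / self.weights[keep].sum())

    def mean(self) -> float:
        return float(self.tau @ self.weights)


@dataclass(frozen=True)
class OAJointState:
    """Gridded joint distribution over (hypothesis truth, reliability profile).

    ``w_true[i]`` is the joint mass P(tau_i, HYP true); ``w_false[i]`` the
    mass P(tau_i, HYP false).  The two vectors jointly sum to one.  Tracking
    the joint (rather than the two marginals) is what lets repeated reports
    correlate belief in the hypothesis with belief about the source.
    """

    tau: np.ndarray
    w_true: np.ndarray
    w_false: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        wt = np.asarray(self.w_true, dtype=float)
        wf = np.asarray(self.w_false, dtype=float)
        if not (tau.shape == wt.shape == wf.shape) or tau.ndim != 1:
            raise ValueError("tau, w_true, w_false must be matching 1-D arrays")
        if np.any(np.diff(tau) <= 0) or np.any(tau < 0) or np.any(tau > 1):
            raise ValueError("tau values must be strictly increasing within [0, 1]")
        if np.any(wt < 0) or np.any(wf < 0):
            raise ValueError("joint masses must be nonnegative")
        total = wt.sum() + wf.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"joint mass must sum to 1 (got {total})")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "w_true", wt / total)
        object.__setattr__(self, "w_false", wf / total)

    @classmethod
    def from_prior(cls, belief: float, grid: ReliabilityGrid) -> "OAJointState":
        """Independent prior: P(HYP) = belief, tau ~ grid."""
        _check_prob("belief", belief)
        return cls(grid.tau, belief * grid.weights, (1.0 - belief) * grid.weights)

    @property
    def belief(self) -> float:
        return float(self.w_true.sum())

    @property
    def expected_reliability(self) -> float:
        return float(self.tau @ (self.w_true + self.w_false))

    def reliability_marginal(self) -> ReliabilityGrid:
        return ReliabilityGrid(self.tau, self.w_true + self.w_false)


def oa_belief(joint: OAJointState) -> float:
    """Marginal belief P(HYP true) of a joint state."""
    return joint.belief


def oa_expected_reliability(joint: OAJointState) -> float:
    """Expected truth-telling propensity E[tau] of a joint state."""
    return joint.expected_reliability


def oa_update(joint: OAJointState, report: BinaryReport) -> OAJointState:
    """Condition the (hypothesis, profile) joint on one report.

    A source with profile tau asserts the true polarity with probability tau,
    independently across reports given (HYP, tau).  A positive report hence
    weighs the HYP-true sheet by tau and the HYP-false sheet by 1 - tau;
    a negative report swaps the factors.
    """
    if report.polarity is Polarity.POSITIVE:
        wt = joint.w_true * joint.tau
        wf = joint.w_false * (1.0 - joint.tau)
    else:
        wt = joint.w_true * (1.0 - joint.tau)
        wf = joint.w_false * joint.tau
    marginal = wt.sum() + wf.sum()
    if marginal <= _EPS:
        raise ImpossibleEvidenceError(
            f"report {report.polarity.value!r} annihilates all joint mass"
        )
    return OAJointState(joint.tau, wt / marginal, wf / marginal)


def oa_from_bh(state: BHState) -> OAJointState:
    """Embed a binary-reliability state as a two-point profile prior.

    A reliable source (mass rho) maps to tau = 1; an unreliable, unbiased
    coin-flipper (mass 1 - rho) maps to tau = 0.5.  After this embedding,
    :func:`oa_update` reproduces :func:`bh_update`: the posterior belief
    matches h', and the posterior mass on tau = 1 matches rho'.  The
    equivalence only holds for ``a = 0.5``.
    """
    if state.a != 0.5:
        raise ValueError(
            "the two-point embedding requires unbiased randomization (a = 0.5); "
            f"got a = {state.a}"
        )
    grid = ReliabilityGrid.two_point(0.5, 1.0, mass_hi=state.rho)
    return OAJointState.from_prior(state.h, grid)


def sequence_update(
    joint: OAJointState, reports: Sequence[BinaryReport]
) -> list[OAJointState]:
    """Fold :func:`oa_update` over a report sequence, left to right.

    Returns one posterior state per report (so the trajectory has exactly
    ``len(reports)`` entries); the last entry equals single-shot conditioning
    on the whole sequence, since per-report likelihoods multiply.
    """
    if len(reports) == 0:
        raise ValueError("report sequence must be nonempty")
    states: list[OAJointState] = []
    current = joint
    for report in reports:
        current = oa_update(current, report)
        states.append(current)
    return states


def second_claim_posterior(
    prior_first: float,
    prior_second: float,
    grid: ReliabilityGrid,
) -> tuple[float, float]:
    """Belief in a fresh second claim after the source positively asserted both.

    Two propositions with independent priors share a single source whose
    profile tau applies to both assertions.  The first assertion moves the
    tau-distribution (up if the first claim was expected, down — possibly
    into the anti-reliable region — if unexpected), and that revised
    distribution then weighs the second assertion.

    Returns
    -------
    (posterior_second, expected_reliability_after_first)
        Posterior P(second claim) given both positive assertions, and the
        E[tau] after conditioning on the first assertion alone.
    """
    _check_prob("prior_first", prior_first)
    _check_prob("prior_second", prior_second)
    tau, w = grid.tau, grid.weights
    # Joint over (H1, H2, tau); condition on two positive assertions.
    lik_first = prior_first * tau + (1 - prior_first) * (1 - tau)
    post_tau_first = w * lik_first
    z1 = post_tau_first.sum()
    if z1 <= _EPS:
        raise ImpossibleEvidenceError("first assertion has zero marginal likelihood")
    exp_rel_after_first = float(tau @ post_tau_first / z1)
    num = post_tau_first * prior_second * tau
    den = post_tau_first * (prior_second * tau + (1 - prior_second) * (1 - tau))
    z2 = den.sum()
    if z2 <= _EPS:
        raise ImpossibleEvidenceError("second assertion has zero marginal likelihood")
    return float(num.sum() / z2), exp_rel_after_first


@dataclass(frozen=True)
class PredictionRecord:
    """Signed qualitative prediction for one condition under one model."""

    model: str  # "bh" | "oa"
    quantity: str  # "belief_change" | "reliability_change"
    direction: str  # "increase" | "decrease" | "none"
    condition: str
    delta: float = 0.0


def _direction(delta: float) -> str:
    if abs(delta) < _DIRECTION_TOL:
        return "none"
    return "increase" if delta > 0 else "decrease"


@dataclass(frozen=True)
class Scenario:
    """Condition priors for deriving model predictions.

    claim_priors maps an expectedness label to the recipient's prior in the
    claim (expected > 0.5, unexpected < 0.5).  bh_source_priors maps a
    reliability label to P(REL); oa_source_grids maps it to a tau-prior.

    The defaults pit the models against each other where they actually
    differ: the high-reliability source uses the exact two-point embedding
    of P(REL) = 0.8 (so both models agree there), while the low-reliability
    source is a maximally unreliable coin-flipper under the binary model
    (P(REL) = 0) versus an anti-reliable point profile tau = 0.2 under the
    profile model.
    """

    claim_priors: dict[str, float] = field(
        default_factory=lambda: {"expected": 0.8, "unexpected": 0.2}
    )
    bh_source_priors: dict[str, float] = field(
        default_factory=lambda: {"high": 0.8, "low": 0.0}
    )
    oa_source_grids: dict[str, ReliabilityGrid] = field(
        default_factory=lambda: {
            "high": ReliabilityGrid.two_point(0.5, 1.0, mass_hi=0.8),
            "low": ReliabilityGrid.point_mass(0.2),
        }
    )


def predict_experiment(model: str, scenario: Scenario | None = None) -> list[PredictionRecord]:
    """Qualitative belief/reliability-change predictions across all conditions.

    For every (expectedness x source-reliability) cell the source asserts the
    claim positively; the record captures the sign of the induced change in
    belief and in perceived reliability.  The binary model with P(REL) = 0
    yields no belief change (an unreliable source is merely uninformative);
    the profile model with anti-reliable mass yields a decrease.
    """
    if scenario is None:
        scenario = Scenario()
    model = model.lower()
    if model not in ("bh", "oa"):
        raise ValueError(f"unknown model {model!r}")
    records: list[PredictionRecord] = []
    for exp_label, h in scenario.claim_priors.items():
        for rel_label in (
            scenario.bh_source_priors if model == "bh" else scenario.oa_source_grids
        ):
            condition = f"{exp_label}/{rel_label}"
            if model == "bh":
                state = BHState(h=h, rho=scenario.bh_source_priors[rel_label], a=0.5)
                post = bh_update(state, POSITIVE)
                d_belief = post.h - state.h
                d_rel = post.rho - state.rho
            else:
                grid = scenario.oa_source_grids[rel_label]
                joint = OAJointState.from_prior(h, grid)
                post_j = oa_update(joint, POSITIVE)
                d_belief = post_j.belief - joint.belief
                d_rel = post_j.expected_reliability - joint.expected_reliability
            records.append(
                PredictionRecord(model, "belief_change", _direction(d_belief), condition, d_belief)
            )
            records.append(
                PredictionRecord(model, "reliability_change", _direction(d_rel), condition, d_rel)
            )
    return records


# ---------------------------------------------------------------------------
# Scenario / trajectory file formats
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> tuple[BHState | OAJointState, list[BinaryReport]]:
    """Read a model scenario from YAML.

    Keys: ``model`` ("bh" or "oa"), ``h``, ``rho``, ``a`` (bh), ``tau_grid``
    with ``points`` (count, uniform) or explicit ``tau``/``prior`` vectors
    (oa), and ``reports``: a list of ``{polarity: positive|negative}``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    reports = [BinaryReport(Polarity(r["polarity"])) for r in cfg.get("reports", [])]
    model = cfg["model"].lower()
    if model == "bh":
        state: BHState | OAJointState = BHState(
            h=float(cfg["h"]), rho=float(cfg["rho"]), a=float(cfg.get("a", 0.5))
        )
    elif model == "oa":
        gcfg = cfg.get("tau_grid", {})
        if "tau" in gcfg:
            grid = ReliabilityGrid(np.asarray(gcfg["tau"]), np.asarray(gcfg["prior"]))
        else:
            grid = ReliabilityGrid.uniform(int(gcfg.get("points", 101)))
        state = OAJointState.from_prior(float(cfg["h"]), grid)
    else:
        raise ValueError(f"unknown model {cfg['model']!r}")
    return state, reports


def trajectory_to_csv(states: Iterable[OAJointState], path: str | Path) -> None:
    """Write a belief / expected-reliability trajectory as CSV (step, belief, expected_reliability)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "belief", "expected_reliability"])
        for step, st in enumerate(states, start=1):
            writer.writerow([step, repr(st.belief), repr(st.expected_reliability)])
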