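"""Multi-agent opinion dynamics with content-based trust updating.

A stylized society of agents who all hold a degree of belief in one shared
hypothesis and maintain, for every peer, a distribution over that peer's
truth-telling propensity tau.  Each round, agents whose belief is extreme
enough assert the hypothesis (or its negation); every listener treats the
assertion as testimony and conditions the joint (own belief x trust in the
speaker) exactly as in :func:`tlab.models.oa_update`.

When trust grids admit anti-reliable profiles (tau < 0.5), an agent who has
come to distrust a peer reads that peer's assertions as evidence for the
opposite — the mechanism by which initially mixed populations can split into
extreme, opposed camps rather than converge.  Truncating trust to
[0.5, 1] removes this route and every assertion pulls listeners toward the
asserted polarity.

This simulator demonstrates the qualitative mechanism only; it makes no
claim of quantitative correspondence with any published agent-based study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .models import (
    NEGATIVE,
    POSITIVE,
    BinaryReport,
    ImpossibleEvidenceError,
    OAJointState,
    ReliabilityGrid,
    oa_update,
)

__all__ = ["Agent", "SocietyConfig", "Society", "PolarizationSummary", "step", "run"]

logger = logging.getLogger(__name__)


@dataclass
class Agent:
    """One agent: a belief in the shared hypothesis and per-peer trust grids."""

    belief: float
    trust: dict[int, ReliabilityGrid]

    def __post_init__(self) -> None:
        if not (0.0 <= self.belief <= 1.0):
            raise ValueError(f"belief must lie in [0, 1], got {self.belief}")


@dataclass(frozen=True)
class SocietyConfig:
    """Simulation parameters.

    assertion_threshold
        An agent asserts the positive polarity when belief > threshold, the
        negative polarity when belief < 1 - threshold, and stays silent in
        between.  Must lie in [0.5, 1).
    allow_anti_reliability
        If False, every trust grid is truncated to tau in [0.5, 1], so no
        agent can read a peer as negatively correlated with the truth.
    initial_belief_spread
        Parameters of a two-component Beta mixture for initial beliefs:
        (alpha1, beta1, alpha2, beta2, weight_of_component_1).  The default
        is a bimodal split emulating a population already divided on the
        issue; (a, b, a, b, 1.0) gives a unimodal population.
    """

    n_agents: int = 20
    topology: Literal["complete", "ring", "random"] = "complete"
    edge_probability: float = 0.3  # only for topology="random"
    rounds: int = 50
    assertion_threshold: float = 0.75
    allow_anti_reliability: bool = True
    initial_belief_spread: tuple[float, float, float, float, float] = (8.0, 2.0, 2.0, 8.0, 0.5)
    trust_grid_points: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least two agents")
        if self.rounds < 1:
            raise ValueError("need at least one round")
        if not (0.5 <= self.assertion_threshold < 1.0):
            raise ValueError("assertion_threshold must lie in [0.5, 1)")
        if self.topology == "random" and not (0.0 < self.edge_probability <= 1.0):
            raise ValueError("edge_probability must lie in (0, 1] for random topology")


@dataclass
class Society:
    """Mutable simulation state: agents plus the (directed) listening graph."""

    agents: list[Agent]
    neighbors: dict[int, list[int]]  # speaker -> listeners
    config: SocietyConfig

    def beliefs(self) -> np.ndarray:
        return np.array([a.belief for a in self.agents])


@dataclass(frozen=True)
class PolarizationSummary:
    """Per-round dispersion metrics of the belief distribution."""

    belief_variance: np.ndarray  # length rounds + 1 (includes the initial state)
    extremity_fraction: np.ndarray  # fraction with belief > 0.9 or < 0.1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(len(self.belief_variance)),
                "belief_variance": self.belief_variance,
                "extremity_fraction": self.extremity_fraction,
            }
        )


def _build_neighbors(config: SocietyConfig, rng: np.random.Generator) -> dict[int, list[int]]:
    n = config.n_agents
    if config.topology == "complete":
        return {i: [j for j in range(n) if j != i] for i in range(n)}
    if config.topology == "ring":
        return {i: [(i - 1) % n, (i + 1) % n] for i in range(n)}
    if config.topology == "random":
        # undirected Erdos-Renyi; keep at least a ring so nobody is isolated
        listeners: dict[int, set[int]] = {i: {(i - 1) % n, (i + 1) % n} for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < config.edge_probability:
                    listeners[i].add(j)
                    listeners[j].add(i)
        return {i: sorted(listeners[i]) for i in range(n)}
    raise ValueError(f"unknown topology {config.topology!r}")


def _initial_beliefs(config: SocietyConfig, rng: np.random.Generator) -> np.ndarray:
    a1, b1, a2, b2, w1 = config.initial_belief_spread
    component = rng.random(config.n_agents) < w1
    draws = np.where(
        component,
        rng.beta(a1, b1, size=config.n_agents),
        rng.beta(a2, b2, size=config.n_agents),
    )
    return np.clip(draws, 1e-6, 1.0 - 1e-6)


def init_society(config: SocietyConfig, rng: np.random.Generator | None = None) -> Society:
    """Build the initial society: beliefs from the configured mixture, uniform trust."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base_grid = ReliabilityGrid.uniform(config.trust_grid_points)
    if not config.allow_anti_reliability:
        base_grid = base_grid.truncated(0.5, 1.0)
    beliefs = _initial_beliefs(config, rng)
    agents = [
        Agent(
            belief=float(b),
            trust={j: base_grid for j in range(config.n_agents) if j != i},
        )
        for i, b in enumerate(beliefs)
    ]
    return Society(agents=agents, neighbors=_build_neighbors(config, rng), config=config)


def _assertion(belief: float, threshold: float) -> BinaryReport | None:
    if belief > threshold:
        return POSITIVE
    if belief < 1.0 - threshold:
        return NEGATIVE
    return None


def step(society: Society, rng: np.random.Generator) -> Society:
    """Advance the society by one communication round (in place; returns it).

    Speakers take the floor in a random order drawn from ``rng``; each
    broadcast reaches every graph neighbor once, and listeners immediately
    condition their (belief x trust-in-speaker) joint on the assertion.
    A listener for whom the assertion is impossible evidence (all joint mass
    annihilated, only reachable with degenerate trust grids) is left
    unchanged and the event is logged.
    """
    order = rng.permutation(len(society.agents))
    threshold = society.config.assertion_threshold
    for speaker_id in order:
        speaker = society.agents[speaker_id]
        report = _assertion(speaker.belief, threshold)
        if report is None:
            continue
        for listener_id in society.neighbors[speaker_id]:
            listener = society.agents[listener_id]
            grid = listener.trust[speaker_id]
            joint = OAJointState.from_prior(listener.belief, grid)
            try:
                post = oa_update(joint, report)
            except ImpossibleEvidenceError:
                logger.warning(
                    "agent %d could not update on %s assertion by agent %d "
                    "(zero marginal likelihood); state unchanged",
                    listener_id,
                    report.polarity.value,
                    speaker_id,
                )
                continue
            listener.belief = min(1.0, max(0.0, post.belief))  # guard fp drift
            listener.trust[speaker_id] = post.reliability_marginal()
    return society


def run(config: SocietyConfig) -> tuple[pd.DataFrame, PolarizationSummary]:
    """Run a full simulation; reproducible given ``config.seed``.

    Returns
    -------
    trajectories
        Long-format frame with columns (round, agent_id, belief); round 0 is
        the initial state.
    summary
        Per-round :class:`PolarizationSummary`.
    """
    rng = np.random.default_rng(config.seed)
    society = init_society(config, rng)
    rows = []
    variances, extremities = [], []

    def record(round_idx: int) -> None:
        beliefs = society.beliefs()
        variances.append(float(beliefs.var()))
        extremities.append(float(np.mean((beliefs > 0.9) | (beliefs < 0.1))))
        for agent_id, b in enumerate(beliefs):
            rows.append((round_idx, agent_id, float(b)))

    record(0)
    for round_idx in range(1, config.rounds + 1):
        step(society, rng)
        record(round_idx)

    trajectories = pd.DataFrame(rows, columns=["round", "agent_id", "belief"])
    summary = PolarizationSummary(np.array(variances), np.array(extremities))
    return trajectories, summary


def plot_trajectories(trajectories: pd.DataFrame, path: str | Path) -> None:
    """Save a belief-trajectory plot (one line per agent) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for agent_id, grp in trajectories.groupby("agent_id"):
        ax.plot(grp["round"], grp["belief"], alpha=0.6, lw=1)
    ax.set_xlabel("round")
    ax.set_ylabel("belief in hypothesis")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
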