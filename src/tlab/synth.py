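"""Synthetic Likert-rating experiments: testimony-paradigm data generators.

The experiments this module emulates were simple vignette studies: a
participant rates how convincing a claim is (or how reliable a source is) on
a 0-10 integer scale, hears the source assert the claim, and re-rates.  Four
designs cross Claim Expectedness (expected / unexpected) with Source
Reliability (high / low) between subjects over 5-6 vignette items; a fifth
uses a two-claim paradigm with a single rating of a neutral second claim
after an expected, unexpected, or absent first claim.

Two generation modes are provided:

* **distributional** — participant-level latent change scores (or endorsement
  levels) drawn from a t-distribution with per-condition (mu, sigma, nu),
  matching the assumptions of the robust analysis model so that parameter
  recovery is well-posed;
* **model-driven** (:func:`model_driven_generate`) — latent pre/post beliefs
  computed by the reliability-profile testimony model and mapped onto the
  0-10 scale, so the *direction* structure of the data is mathematically
  guaranteed rather than assumed.

All ratings are clipped to the scale bounds before rounding; rounding is
half-away-from-zero, yielding integers only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models import (
    POSITIVE,
    OAJointState,
    ReliabilityGrid,
    oa_update,
    second_claim_posterior,
)

__all__ = [
    "CHANGE_COLUMNS",
    "EXP3_COLUMNS",
    "ExperimentDesign",
    "GenerationParams",
    "OAScenario",
    "RatingTable",
    "generate_change_design",
    "generate_exp3_design",
    "model_driven_generate",
    "default_design",
    "default_params",
]

CHANGE_EXPERIMENTS = ("exp1a", "exp1b", "exp2a", "exp2b")
EXPERIMENTS = CHANGE_EXPERIMENTS + ("exp3",)

CHANGE_COLUMNS = [
    "participant_id",
    "experiment",
    "claim_expectedness",
    "source_reliability",
    "item_id",
    "initial_rating",
    "final_rating",
]
EXP3_COLUMNS = ["participant_id", "experiment", "first_claim_condition", "item_id", "rating"]

# The factor whose levels carry the latent effect in each design: the a-series
# measures belief change by source reliability, the b-series reliability change
# by claim expectedness, and the two-claim design varies the first claim.
PRIMARY_FACTOR = {
    "exp1a": "source_reliability",
    "exp1b": "claim_expectedness",
    "exp2a": "source_reliability",
    "exp2b": "claim_expectedness",
    "exp3": "first_claim_condition",
}

EXPECTEDNESS_LEVELS = ("expected", "unexpected")
RELIABILITY_LEVELS = ("high", "low")
EXP3_CONDITIONS = ("expected", "unexpected", "null")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural description of one experiment."""

    experiment: str
    n_per_condition: int = 25
    n_items: int | None = None
    scale: tuple[int, int] = (0, 10)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be positive")
        if self.n_items is None:
            default_items = 6 if self.experiment in ("exp1a", "exp1b") else 5
            object.__setattr__(self, "n_items", default_items)
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        lo, hi = self.scale
        if not (0 <= lo < hi):
            raise ValueError("scale bounds must satisfy 0 <= lo < hi")

    @property
    def is_change_design(self) -> bool:
        return self.experiment in CHANGE_EXPERIMENTS

    @property
    def conditions(self) -> list[tuple[str, ...]]:
        """Condition cells: 2x2 factorial for pre/post designs, three cells for exp3."""
        if self.is_change_design:
            return [(e, r) for e in EXPECTEDNESS_LEVELS for r in RELIABILITY_LEVELS]
        return [(c,) for c in EXP3_CONDITIONS]


@dataclass(frozen=True)
class GenerationParams:
    """Latent-effect parameters for the distributional generator.

    ``effects`` maps each level of the design's primary factor to a
    (mu, sigma, nu) triple of the t-distributed participant-level latent:
    the *change score* for the pre/post designs, the *endorsement level*
    for the two-claim design.  ``initial_mean`` maps expectedness to the
    mean pre-rating (the rated quantity starts high for expected claims /
    reliable-sounding sources and low otherwise).
    """

    effects: Mapping[str, tuple[float, float, float]]
    initial_mean: Mapping[str, float] = field(
        default_factory=lambda: {"expected": 7.0, "unexpected": 3.0}
    )
    item_spread: float = 0.5
    rating_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for level, (mu, sigma, nu) in self.effects.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive for level {level!r}")
            if nu <= 1:
                raise ValueError(f"nu must exceed 1 for level {level!r}")
        if self.item_spread < 0 or self.rating_noise_sd < 0:
            raise ValueError("spread/noise parameters must be nonnegative")


@dataclass(frozen=True)
class RatingTable:
    """Tidy per-participant, per-item ratings plus the design they realize."""

    data: pd.DataFrame
    design: ExperimentDesign

    def __post_init__(self) -> None:
        expected_cols = CHANGE_COLUMNS if self.design.is_change_design else EXP3_COLUMNS
        if list(self.data.columns) != expected_cols:
            raise ValueError(
                f"rating table for {self.design.experiment} must have columns {expected_cols}"
            )
        dup = self.data.duplicated(subset=["participant_id", "item_id"])
        if dup.any():
            raise ValueError("duplicate (participant, item) pairs in rating table")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, design: ExperimentDesign) -> "RatingTable":
        # keep_default_na: the exp3 condition label "null" is a real label
        return cls(pd.read_csv(path, keep_default_na=False), design)


def _draw_t(rng: np.random.Generator, mu: float, sigma: float, nu: float, size: int) -> np.ndarray:
    return mu + sigma * rng.standard_t(nu, size=size)


def _finalize_ratings(latent: np.ndarray, design: ExperimentDesign) -> np.ndarray:
    lo, hi = design.scale
    return _round_half_away(np.clip(latent, lo, hi)).astype(int)


def generate_change_design(design: ExperimentDesign, params: GenerationParams) -> RatingTable:
    """Generate a pre/post rating table for one of the 2x2 factorial designs.

    Per participant in condition (expectedness, reliability): a latent change
    delta is drawn from the t-distribution attached to the primary-factor
    level; per item, the initial rating is the expectedness-specific baseline
    plus a fixed item offset plus noise, and the final rating adds delta and
    fresh item noise.  Clip-then-round yields integer ratings on the scale.
    """
    if not design.is_change_design:
        raise ValueError(f"{design.experiment} is not a pre/post change design")
    factor = PRIMARY_FACTOR[design.experiment]
    rng = np.random.default_rng(params.seed)
    item_offsets = rng.normal(0.0, params.item_spread, size=design.n_items)
    rows: list[tuple] = []
    pid = 0
    for expectedness, reliability in design.conditions:
        level = reliability if factor == "source_reliability" else expectedness
        try:
            mu, sigma, nu = params.effects[level]
        except KeyError:
            raise ValueError(f"no effect parameters for {factor} level {level!r}") from None
        base = params.initial_mean[expectedness]
        delta = _draw_t(rng, mu, sigma, nu, design.n_per_condition)
        for i in range(design.n_per_condition):
            pid += 1
            init_latent = (
                base
                + item_offsets
                + rng.normal(0.0, params.rating_noise_sd, size=design.n_items)
            )
            final_latent = (
                init_latent
                + delta[i]
                + rng.normal(0.0, params.rating_noise_sd, size=design.n_items)
            )
            initial = _finalize_ratings(init_latent, design)
            final = _finalize_ratings(final_latent, design)
            for item in range(design.n_items):
                rows.append(
                    (
                        f"p{pid:04d}",
                        design.experiment,
                        expectedness,
                        reliability,
                        f"item{item + 1}",
                        initial[item],
                        final[item],
                    )
                )
    return RatingTable(pd.DataFrame(rows, columns=CHANGE_COLUMNS), design)


def generate_exp3_design(design: ExperimentDesign, params: GenerationParams) -> RatingTable:
    """Generate single-rating endorsement data for the two-claim design.

    Per participant in each first-claim condition, a latent endorsement level
    is drawn from the condition's t-distribution; each item's rating is that
    level plus a fixed item offset plus noise, clipped and rounded.  The
    'null' condition is the unconditioned baseline: participants who saw only
    the neutral second claim.
    """
    if design.is_change_design:
        raise ValueError(f"{design.experiment} is not the two-claim design")
    rng = np.random.default_rng(params.seed)
    item_offsets = rng.normal(0.0, params.item_spread, size=design.n_items)
    rows: list[tuple] = []
    pid = 0
    for (condition,) in design.conditions:
        mu, sigma, nu = params.effects[condition]
        level = _draw_t(rng, mu, sigma, nu, design.n_per_condition)
        for i in range(design.n_per_condition):
            pid += 1
            latent = (
                level[i]
                + item_offsets
                + rng.normal(0.0, params.rating_noise_sd, size=design.n_items)
            )
            ratings = _finalize_ratings(latent, design)
            for item in range(design.n_items):
                rows.append(
                    (
                        f"p{pid:04d}",
                        design.experiment,
                        condition,
                        f"item{item + 1}",
                        ratings[item],
                    )
                )
    return RatingTable(pd.DataFrame(rows, columns=EXP3_COLUMNS), design)


@dataclass(frozen=True)
class OAScenario:
    """Per-condition priors for model-driven generation.

    claim_priors: recipient's prior in the asserted claim by expectedness.
    tau_grids: tau-prior by source-reliability level (high-reliability mass
    above 0.5, low-reliability mass below 0.5 for an anti-reliable source).
    neutral_prior: prior of the fresh second claim in the two-claim design.
    """

    claim_priors: Mapping[str, float] = field(
        default_factory=lambda: {"expected": 0.8, "unexpected": 0.2}
    )
    tau_grids: Mapping[str, ReliabilityGrid] = field(
        default_factory=lambda: {
            # dispersed two-point grids so reliability itself can be learned:
            # the high source is net reliable (E[tau] = 0.9), the low source
            # net anti-reliable (E[tau] = 0.26)
            "high": ReliabilityGrid.two_point(0.5, 1.0, mass_hi=0.8),
            "low": ReliabilityGrid.two_point(0.2, 0.5, mass_hi=0.2),
        }
    )
    exp3_grid: ReliabilityGrid = field(default_factory=lambda: ReliabilityGrid.uniform(101))
    neutral_prior: float = 0.5


def model_driven_generate(
    design: ExperimentDesign,
    scenario: OAScenario,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> RatingTable:
    """Generate ratings whose latent structure comes from the testimony model.

    Pre/post designs: the latent initial value is 10x the model prior (the
    claim prior for belief ratings, E[tau] for reliability ratings) and the
    latent final value is 10x the corresponding posterior after a positive
    assertion.  Two-claim design: the latent endorsement is 10x the posterior
    of the neutral second claim given the condition's first assertion (or the
    raw neutral prior in the null condition).  Gaussian noise is added per
    rating before clip-and-round.
    """
    rng = np.random.default_rng(seed)
    measures_reliability = design.experiment in ("exp1b", "exp2b")
    rows: list[tuple] = []
    pid = 0
    if design.is_change_design:
        for expectedness, reliability in design.conditions:
            h = scenario.claim_priors[expectedness]
            grid = scenario.tau_grids[reliability]
            prior_joint = OAJointState.from_prior(h, grid)
            post_joint = oa_update(prior_joint, POSITIVE)
            if measures_reliability:
                latent_init = 10.0 * prior_joint.expected_reliability
                latent_final = 10.0 * post_joint.expected_reliability
            else:
                latent_init = 10.0 * prior_joint.belief
                latent_final = 10.0 * post_joint.belief
            for _ in range(design.n_per_condition):
                pid += 1
                init = _finalize_ratings(
                    latent_init + rng.normal(0.0, noise_sd, size=design.n_items), design
                )
                final = _finalize_ratings(
                    latent_final + rng.normal(0.0, noise_sd, size=design.n_items), design
                )
                for item in range(design.n_items):
                    rows.append(
                        (
                            f"p{pid:04d}",
                            design.experiment,
                            expectedness,
                            reliability,
                            f"item{item + 1}",
                            init[item],
                            final[item],
                        )
                    )
        return RatingTable(pd.DataFrame(rows, columns=CHANGE_COLUMNS), design)

    for (condition,) in design.conditions:
        if condition == "null":
            latent = 10.0 * scenario.neutral_prior
        else:
            posterior, _ = second_claim_posterior(
                scenario.claim_priors[condition], scenario.neutral_prior, scenario.exp3_grid
            )
            latent = 10.0 * posterior
        for _ in range(design.n_per_condition):
            pid += 1
            ratings = _finalize_ratings(
                latent + rng.normal(0.0, noise_sd, size=design.n_items), design
            )
            for item in range(design.n_items):
                rows.append(
                    (f"p{pid:04d}", design.experiment, condition, f"item{item + 1}", ratings[item])
                )
    return RatingTable(pd.DataFrame(rows, columns=EXP3_COLUMNS), design)


# ---------------------------------------------------------------------------
# Stated-world defaults: sample sizes match the reported studies (total N
# divided over conditions); latent effects match the reported posterior
# location/scale estimates for each primary-factor level, with nu = 30
# (near-normal change scores).  The two-claim endorsement means reproduce the
# reported between-condition mean differences around a neutral baseline of 5.
# ---------------------------------------------------------------------------

_DEFAULT_N = {"exp1a": 25, "exp1b": 33, "exp2a": 20, "exp2b": 20, "exp3": 139}

_DEFAULT_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "exp1a": {"high": (1.84, 1.39, 30.0), "low": (-0.72, 1.46, 30.0)},
    "exp1b": {"expected": (0.45, 0.93, 30.0), "unexpected": (-1.12, 1.37, 30.0)},
    "exp2a": {"high": (2.23, 1.39, 30.0), "low": (-1.73, 1.58, 30.0)},
    "exp2b": {"expected": (0.51, 0.89, 30.0), "unexpected": (-0.20, 1.16, 30.0)},
    "exp3": {
        "expected": (5.09, 2.0, 30.0),
        "unexpected": (4.44, 2.0, 30.0),
        "null": (5.0, 2.0, 30.0),
    },
}


def default_design(experiment: str, n_per_condition: int | None = None) -> ExperimentDesign:
    """Design with the emulated study's per-condition sample size."""
    return ExperimentDesign(
        experiment=experiment,
        n_per_condition=n_per_condition or _DEFAULT_N[experiment],
    )


def default_params(experiment: str, seed: int = 0) -> GenerationParams:
    """Stated-world latent effects for one experiment."""
    return GenerationParams(effects=_DEFAULT_EFFECTS[experiment], seed=seed)
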