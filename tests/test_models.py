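"""Unit and property tests for the testimony-updating models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlab.models import (
    NEGATIVE,
    POSITIVE,
    BHState,
    BinaryReport,
    ImpossibleEvidenceError,
    OAJointState,
    Polarity,
    ReliabilityGrid,
    Scenario,
    bh_enumeration_oracle,
    bh_update,
    load_scenario,
    oa_from_bh,
    oa_update,
    predict_experiment,
    second_claim_posterior,
    sequence_update,
    trajectory_to_csv,
)

GRID_PROBS = np.linspace(0.05, 0.95, 10)


class TestBinaryReliabilityUpdate:
    def test_neutral_claim_leaves_reliability_unchanged(self):
        # P(report | REL) = P(report | not REL) when the claim is a coin flip
        for rho in (0.1, 0.5, 0.9):
            post = bh_update(BHState(0.5, rho, 0.5), POSITIVE)
            assert post.rho == pytest.approx(rho, abs=1e-12)

    def test_fully_reliable_source_reveals_truth(self):
        for h in (0.1, 0.5, 0.9):
            assert bh_update(BHState(h, 1.0, 0.5), POSITIVE).h == pytest.approx(1.0)
            assert bh_update(BHState(h, 1.0, 0.5), NEGATIVE).h == pytest.approx(0.0)

    def test_bidirectional_revision(self):
        # unexpected claim: belief rises toward the report, reliability drops
        post = bh_update(BHState(0.3, 0.6, 0.5), POSITIVE)
        assert post.h == pytest.approx(0.631578947368421, abs=1e-12)
        assert post.rho == pytest.approx(0.47368421052631576, abs=1e-12)

    def test_hand_enumerated_case(self):
        post = bh_enumeration_oracle(BHState(0.5, 0.5, 0.5), POSITIVE)
        assert post.h == pytest.approx(0.75, abs=1e-12)
        assert post.rho == pytest.approx(0.5, abs=1e-12)

    def test_impossible_evidence_raises(self):
        # certain-false hypothesis, fully reliable source, positive assertion
        state = BHState(h=0.0, rho=1.0, a=0.5)
        with pytest.raises(ImpossibleEvidenceError):
            bh_update(state, POSITIVE)
        with pytest.raises(ImpossibleEvidenceError):
            bh_enumeration_oracle(state, POSITIVE)

    @pytest.mark.parametrize("polarity", [POSITIVE, NEGATIVE])
    def test_matches_enumeration_oracle_on_sweep(self, polarity):
        for h in GRID_PROBS:
            for rho in GRID_PROBS:
                for a in (0.2, 0.5, 0.8):
                    state = BHState(h, rho, a)
                    fast = bh_update(state, polarity)
                    slow = bh_enumeration_oracle(state, polarity)
                    assert fast.h == pytest.approx(slow.h, abs=1e-12)
                    assert fast.rho == pytest.approx(slow.rho, abs=1e-12)

    def test_random_states_match_oracle(self, rng):
        for _ in range(1000):
            state = BHState(*rng.random(3))
            report = POSITIVE if rng.random() < 0.5 else NEGATIVE
            try:
                fast = bh_update(state, report)
            except ImpossibleEvidenceError:
                with pytest.raises(ImpossibleEvidenceError):
                    bh_enumeration_oracle(state, report)
                continue
            slow = bh_enumeration_oracle(state, report)
            assert abs(fast.h - slow.h) <= 1e-12
            assert abs(fast.rho - slow.rho) <= 1e-12

    def test_monotone_reliability_revision(self):
        # with unbiased randomization, a positive report raises perceived
        # reliability exactly when the claim was expected (h > 0.5)
        for h in GRID_PROBS:
            for rho in GRID_PROBS:
                post = bh_update(BHState(h, rho, 0.5), POSITIVE)
                if h > 0.5:
                    assert post.rho > rho
                elif h < 0.5:
                    assert post.rho < rho


class TestProfileUpdate:
    def test_coin_flip_profile_is_uninformative(self):
        joint = OAJointState.from_prior(0.42, ReliabilityGrid.point_mass(0.5))
        post = oa_update(joint, POSITIVE)
        assert post.belief == pytest.approx(0.42, abs=1e-12)

    def test_anti_reliable_point_profile_lowers_belief(self):
        joint = OAJointState.from_prior(0.5, ReliabilityGrid.point_mass(0.2))
        post = oa_update(joint, POSITIVE)
        assert post.belief == pytest.approx(0.2, abs=1e-12)

    def test_uniform_prior_continuum_limit(self):
        # closed form: belief stays at h, E[tau | positive report] =
        # (h/3 + (1-h)/6) / (1/2) for a flat profile prior
        h = 0.7
        joint = OAJointState.from_prior(h, ReliabilityGrid.uniform(1001))
        post = oa_update(joint, POSITIVE)
        exact = (h / 3 + (1 - h) / 6) / 0.5
        assert post.belief == pytest.approx(h, abs=1e-9)
        assert post.expected_reliability == pytest.approx(exact, abs=1e-3)

    def test_marginal_readouts(self):
        grid = ReliabilityGrid.uniform(101)
        sym = OAJointState.from_prior(0.5, grid)
        assert sym.belief == pytest.approx(0.5, abs=1e-12)
        assert sym.expected_reliability == pytest.approx(0.5, abs=1e-12)
        point = OAJointState.from_prior(0.3, ReliabilityGrid.point_mass(1.0))
        assert point.expected_reliability == pytest.approx(1.0)

    def test_impossible_evidence(self):
        # belief 1 with a perfectly anti-reliable source cannot assert positive
        joint = OAJointState.from_prior(1.0, ReliabilityGrid.point_mass(0.0))
        with pytest.raises(ImpossibleEvidenceError):
            oa_update(joint, POSITIVE)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.01, 0.99),
        lo=st.floats(0.01, 0.48),
        hi=st.floats(0.02, 0.49),
    )
    def test_anti_reliability_sign_rule(self, h, lo, hi):
        # all profile mass below 0.5: a positive report strictly lowers belief
        tau = np.sort(np.unique([lo, min(lo + hi, 0.49)]))
        grid = ReliabilityGrid(tau, np.full(tau.size, 1.0 / tau.size))
        post = oa_update(OAJointState.from_prior(h, grid), POSITIVE)
        assert post.belief < h
        mirrored = ReliabilityGrid((1 - tau)[::-1], np.full(tau.size, 1.0 / tau.size))
        post_hi = oa_update(OAJointState.from_prior(h, mirrored), POSITIVE)
        assert post_hi.belief > h

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(h=st.floats(0.05, 0.95), seed=st.integers(0, 10_000))
    def test_mirror_symmetry(self, h, seed):
        # reflecting the profile about 0.5 and negating the report gives the
        # same belief and the reflected profile posterior
        rng = np.random.default_rng(seed)
        tau = np.linspace(0.0, 1.0, 21)
        w = rng.random(21)
        w /= w.sum()
        grid = ReliabilityGrid(tau, w)
        mirror = ReliabilityGrid(np.sort(1 - tau), w[::-1])
        post = oa_update(OAJointState.from_prior(h, grid), POSITIVE)
        post_m = oa_update(OAJointState.from_prior(h, mirror), NEGATIVE)
        assert post_m.belief == pytest.approx(post.belief, abs=1e-12)
        marg = post.reliability_marginal().weights
        marg_m = post_m.reliability_marginal().weights
        np.testing.assert_allclose(marg_m, marg[::-1], atol=1e-12)


class TestEmbedding:
    def test_two_point_embedding_reproduces_binary_model(self):
        state = BHState(0.3, 0.6, 0.5)
        post_bh = bh_update(state, POSITIVE)
        post_oa = oa_update(oa_from_bh(state), POSITIVE)
        assert post_oa.belief == pytest.approx(post_bh.h, abs=1e-12)
        mass_on_one = (post_oa.w_true + post_oa.w_false)[post_oa.tau == 1.0].sum()
        assert mass_on_one == pytest.approx(post_bh.rho, abs=1e-12)

    def test_degenerate_reliability_endpoints(self):
        # rho = 0: all mass on the coin flipper, belief inert
        inert = oa_update(oa_from_bh(BHState(0.4, 0.0, 0.5)), POSITIVE)
        assert inert.belief == pytest.approx(0.4, abs=1e-12)
        # rho = 1: truth-teller, positive report is conclusive
        sure = oa_update(oa_from_bh(BHState(0.4, 1.0, 0.5)), POSITIVE)
        assert sure.belief == pytest.approx(1.0, abs=1e-12)

    def test_biased_randomization_unsupported(self):
        with pytest.raises(ValueError, match="a = 0.5"):
            oa_from_bh(BHState(0.5, 0.5, 0.7))

    @pytest.mark.parametrize("polarity", [POSITIVE, NEGATIVE])
    def test_equivalence_over_grid(self, polarity):
        for h in GRID_PROBS:
            for rho in GRID_PROBS:
                state = BHState(h, rho, 0.5)
                post_bh = bh_update(state, polarity)
                post_oa = oa_update(oa_from_bh(state), polarity)
                assert abs(post_oa.belief - post_bh.h) <= 1e-10
                mass_one = (post_oa.w_true + post_oa.w_false)[post_oa.tau == 1.0].sum()
                assert abs(mass_one - post_bh.rho) <= 1e-10


def _single_shot(joint, reports):
    """Oracle: condition on a whole report sequence at once via likelihood products."""
    n_pos = sum(r.polarity is Polarity.POSITIVE for r in reports)
    n_neg = len(reports) - n_pos
    tau = joint.tau
    wt = joint.w_true * tau**n_pos * (1 - tau) ** n_neg
    wf = joint.w_false * (1 - tau) ** n_pos * tau**n_neg
    z = wt.sum() + wf.sum()
    return OAJointState(tau, wt / z, wf / z)


class TestSequences:
    def test_empty_sequence_rejected(self):
        joint = OAJointState.from_prior(0.5, ReliabilityGrid.uniform(11))
        with pytest.raises(ValueError):
            sequence_update(joint, [])

    def test_uninformative_profile_flat_trajectory(self):
        joint = OAJointState.from_prior(0.37, ReliabilityGrid.point_mass(0.5))
        states = sequence_update(joint, [POSITIVE, NEGATIVE])
        assert len(states) == 2
        for st_ in states:
            assert st_.belief == pytest.approx(0.37, abs=1e-12)

    def test_order_invariance(self):
        joint = OAJointState.from_prior(0.6, ReliabilityGrid.uniform(101))
        end_a = sequence_update(joint, [POSITIVE, POSITIVE, NEGATIVE])[-1]
        end_b = sequence_update(joint, [NEGATIVE, POSITIVE, POSITIVE])[-1]
        np.testing.assert_allclose(end_a.w_true, end_b.w_true, atol=1e-12)
        np.testing.assert_allclose(end_a.w_false, end_b.w_false, atol=1e-12)

    def test_matches_single_shot_conditioning(self, rng):
        grid = ReliabilityGrid.uniform(101)
        for length in range(1, 6):
            for _ in range(5):
                reports = [POSITIVE if rng.random() < 0.5 else NEGATIVE for _ in range(length)]
                joint = OAJointState.from_prior(float(rng.uniform(0.1, 0.9)), grid)
                folded = sequence_update(joint, reports)[-1]
                oracle = _single_shot(joint, reports)
                np.testing.assert_allclose(folded.w_true, oracle.w_true, atol=1e-10)
                np.testing.assert_allclose(folded.w_false, oracle.w_false, atol=1e-10)

    def test_second_claim_carry_over_direction(self):
        grid = ReliabilityGrid.uniform(101)
        after_expected, _ = second_claim_posterior(0.8, 0.5, grid)
        after_unexpected, _ = second_claim_posterior(0.2, 0.5, grid)
        assert after_expected > 0.5 > after_unexpected
        assert after_expected > after_unexpected


class TestPredictions:
    def test_maximally_unreliable_binary_source_is_uninformative(self):
        scenario = Scenario(bh_source_priors={"high": 0.8, "low": 0.0})
        records = predict_experiment("bh", scenario)
        low_belief = [
            r for r in records if r.quantity == "belief_change" and r.condition.endswith("/low")
        ]
        assert low_belief and all(r.direction == "none" for r in low_belief)

    def test_anti_reliable_profile_source_decreases_belief(self):
        records = predict_experiment("oa")
        low_belief = [
            r for r in records if r.quantity == "belief_change" and r.condition.endswith("/low")
        ]
        assert low_belief and all(r.direction == "decrease" for r in low_belief)

    def test_unexpected_claims_lower_perceived_reliability(self):
        records = predict_experiment("bh")
        rows = [
            r
            for r in records
            if r.quantity == "reliability_change" and r.condition.startswith("unexpected/high")
        ]
        assert rows and all(r.direction == "decrease" for r in rows)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            predict_experiment("elm")


class TestScenarioIO:
    def test_yaml_roundtrip_and_csv_export(self, tmp_path):
        scenario = tmp_path / "scenario.yaml"
        scenario.write_text(
            "model: oa\nh: 0.6\ntau_grid:\n  points: 51\n"
            "reports:\n  - polarity: positive\n  - polarity: negative\n"
        )
        state, reports = load_scenario(scenario)
        assert isinstance(state, OAJointState)
        assert [r.polarity.value for r in reports] == ["positive", "negative"]
        states = sequence_update(state, reports)
        out = tmp_path / "trajectory.csv"
        trajectory_to_csv(states, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "step,belief,expected_reliability"
        assert len(lines) == 3

    def test_bh_scenario(self, tmp_path):
        scenario = tmp_path / "scenario.yaml"
        scenario.write_text("model: bh\nh: 0.3\nrho: 0.6\nreports: [{polarity: positive}]\n")
        state, reports = load_scenario(scenario)
        assert isinstance(state, BHState)
        assert bh_update(state, reports[0]).h == pytest.approx(0.631578947368421)

    def test_report_negation(self):
        assert BinaryReport("positive").negate().polarity is Polarity.NEGATIVE
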