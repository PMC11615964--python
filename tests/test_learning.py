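"""Discounting, the WER combination, social/self-learning and forgetting.

The combination rule is cross-checked against an independent brute-force
implementation that works on frozensets of element labels and shares no code
with the package.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beliefgame import (
    BeliefFunction,
    DiscountedBelief,
    TotalConflictError,
    discount,
    forget,
    make_frame,
    self_learn,
    social_learn,
    wer_combine_step,
)
from conftest import bf
from test_belief import _random_belief

UNASSIGNED = "__unassigned__"


def naive_discount(masses: dict, c: float) -> dict:
    out = {k: c * v for k, v in masses.items()}
    out[UNASSIGNED] = 1.0 - c
    return out


def naive_combine(acc: dict, nxt: dict) -> dict:
    """Brute-force pairwise combination over frozenset-labelled masses.

    Cross terms with the unassigned slot keep each operand's masses; subset
    pairs contribute to their intersection; empty intersections are dropped
    and everything is renormalized.
    """
    u_a, u_b = acc.get(UNASSIGNED, 0.0), nxt.get(UNASSIGNED, 0.0)
    a = {k: v for k, v in acc.items() if k != UNASSIGNED}
    b = {k: v for k, v in nxt.items() if k != UNASSIGNED}
    out: dict = {}
    for s, m in a.items():
        out[s] = out.get(s, 0.0) + u_b * m
    for s, m in b.items():
        out[s] = out.get(s, 0.0) + u_a * m
    for s1, m1 in a.items():
        for s2, m2 in b.items():
            inter = s1 & s2
            if inter:
                out[inter] = out.get(inter, 0.0) + m1 * m2
    u = u_a * u_b
    z = sum(out.values()) + u
    if z <= 1e-9:
        raise ZeroDivisionError("total conflict")
    out = {k: v / z for k, v in out.items()}
    out[UNASSIGNED] = u / z
    return out


def to_sets(m: BeliefFunction) -> dict:
    return {frozenset(m.frame.labels_of(s)): m.mass[s] for s in m.focal_elements()}


def from_result(frame, d: DiscountedBelief) -> dict:
    out = {
        frozenset(frame.labels_of(int(s))): d.mass[s]
        for s in np.flatnonzero(d.mass)
    }
    out[UNASSIGNED] = d.unassigned
    return out


class TestDiscount:
    def test_full_trust_is_identity(self, frame1):
        m = bf(frame1, R1=0.4, R1_I1=0.6)
        d = discount(m, 1.0)
        np.testing.assert_allclose(d.mass, m.mass)
        assert d.unassigned == 0.0

    def test_zero_trust_moves_all_mass(self, frame1):
        d = discount(bf(frame1, R1=1.0), 0.0)
        assert d.mass.sum() == 0.0
        assert d.unassigned == 1.0

    def test_partial(self, frame1):
        d = discount(bf(frame1, I1=1.0), 1 / 3)
        assert d.mass[frame1.irregular(0)] == pytest.approx(1 / 3)
        assert d.unassigned == pytest.approx(2 / 3)

    def test_out_of_range_rejected(self, frame1):
        with pytest.raises(ValueError):
            discount(bf(frame1, R1=1.0), 1.1)


class TestWerCombineStep:
    def test_fully_discounted_source_is_identity(self, frame1):
        acc = discount(bf(frame1, R1=1.0), 1.0)
        out = wer_combine_step(acc, discount(bf(frame1, I1=1.0), 0.0))
        assert out.mass[frame1.regular(0)] == pytest.approx(1.0)
        assert out.unassigned == pytest.approx(0.0)

    def test_committed_ego_resists_conflicting_source(self, frame1):
        acc = discount(bf(frame1, R1=1.0), 1.0)
        out = wer_combine_step(acc, discount(bf(frame1, I1=1.0), 1 / 3))
        # the 1/3 conflicting product lands on the empty set and is dropped
        assert out.mass[frame1.regular(0)] == pytest.approx(1.0)

    def test_vacuous_ego_adopts_half_of_committed_source(self, frame1):
        acc = discount(bf(frame1, R1_I1=1.0), 1.0)
        out = wer_combine_step(acc, discount(bf(frame1, R1=1.0), 0.5))
        assert out.mass[frame1.regular(0)] == pytest.approx(0.5)
        assert out.mass[frame1.theta] == pytest.approx(0.5)

    def test_total_conflict_signalled(self, frame1):
        with pytest.raises(TotalConflictError):
            wer_combine_step(
                discount(bf(frame1, R1=1.0), 1.0),
                discount(bf(frame1, I1=1.0), 1.0),
            )

    def test_frame_mismatch_rejected(self, frame1, frame2):
        with pytest.raises(ValueError):
            wer_combine_step(
                discount(bf(frame1, R1=1.0), 1.0),
                discount(bf(frame2, R1=1.0), 1.0),
            )

    @pytest.mark.parametrize("n_verbs", [1, 2])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, n_verbs, seed):
        frame = make_frame(n_verbs)
        rng = np.random.default_rng(seed)
        m_a, m_b = _random_belief(frame, rng), _random_belief(frame, rng)
        c_a, c_b = rng.uniform(0.1, 1.0, size=2)
        ours = wer_combine_step(discount(m_a, c_a), discount(m_b, c_b))
        naive = naive_combine(
            naive_discount(to_sets(m_a), c_a), naive_discount(to_sets(m_b), c_b)
        )
        got = from_result(frame, ours)
        assert set(naive) >= {k for k, v in got.items() if v > 1e-12}
        for key, val in naive.items():
            assert got.get(key, 0.0) == pytest.approx(val, abs=1e-12)


class TestSocialLearn:
    def test_no_sources_is_identity(self, frame2, rng):
        ego = _random_belief(frame2, rng)
        out = social_learn(ego, [])
        np.testing.assert_allclose(out.mass, ego.mass)

    @pytest.mark.parametrize("seed", range(6))
    def test_fold_matches_oracle_for_three_sources(self, seed):
        """End-to-end fold (ego at c=1, then sources) against the naive path."""
        frame = make_frame(2)
        rng = np.random.default_rng(100 + seed)
        ego = _random_belief(frame, rng)
        sources = []
        naive = naive_discount(to_sets(ego), 1.0)
        for _ in range(3):
            m = _random_belief(frame, rng)
            w, r = rng.uniform(0.05, 1.0), rng.uniform(0.0, 0.95)
            c = w / (1 + w - r)
            naive = naive_combine(naive, naive_discount(to_sets(m), c))
            sources.append((m, w, r))
        out = social_learn(ego, sources)
        u = naive.pop(UNASSIGNED)
        for key, val in naive.items():
            mask = frame.subset_from_labels(key)
            assert out.mass[mask] == pytest.approx(val / (1 - u), abs=1e-12)

    def test_order_dependence(self, frame1):
        """Combining a conflicting pair in the two directions disagrees."""
        m5 = bf(frame1, R1=0.8, I1=0.2)
        m7 = bf(frame1, I1=0.9, R1_I1=0.1)
        a = social_learn(m5, [(m7, 0.6, 0.4)])
        b = social_learn(m7, [(m5, 0.6, 0.4)])
        assert not np.allclose(a.mass, b.mass)

    def test_fold_with_fixed_discounts_is_order_invariant(self, frame2, rng):
        """With the ego first at c=1, each WER step equals Dempster's rule on
        the classically discounted source, so for *fixed* (w, r) the fold
        commutes; sequence matters only through position-dependent
        reliability (next test)."""
        ego = _random_belief(frame2, rng)
        srcs = [
            (_random_belief(frame2, rng), rng.uniform(0.2, 1), rng.uniform(0, 0.9))
            for _ in range(3)
        ]
        a = social_learn(ego, srcs)
        b = social_learn(ego, srcs[::-1])
        np.testing.assert_allclose(a.mass, b.mass, atol=1e-12)

    def test_sequence_matters_through_recursive_reliability(self, frame1):
        """Recomputing each source's reliability at its position in the
        sequence (the in-group recursion) makes the order of sources matter."""
        from beliefgame import map_reliability, recursive_reliability

        ego = bf(frame1, R1=0.9, I1=0.1)
        j1 = bf(frame1, I1=1.0)
        j2 = bf(frame1, R1=0.5, I1=0.5)
        results = {}
        for order, key in (((j1, j2), "a"), ((j2, j1), "b")):
            srcs = []
            for k, m in enumerate(order, start=1):
                r = map_reliability(min(recursive_reliability(ego, list(order[:k]), k), 1.0))
                srcs.append((m, 0.5, r))
            results[key] = social_learn(ego, srcs)
        assert not np.allclose(results["a"].mass, results["b"].mass)

    def test_committed_ego_absorbs_any_single_conflicting_source(self, frame2, rng):
        ego = bf(frame2, I2=1.0)
        for _ in range(10):
            src = _random_belief(frame2, rng)
            out = social_learn(ego, [(src, 0.7, 0.9)])
            assert out.mass[frame2.irregular(1)] == pytest.approx(1.0)

    def test_mass_conservation(self, frame2, rng):
        for _ in range(20):
            ego = _random_belief(frame2, rng)
            srcs = [
                (_random_belief(frame2, rng), rng.uniform(0, 1), rng.uniform(0, 0.95))
                for _ in range(rng.integers(1, 4))
            ]
            out = social_learn(ego, srcs)
            assert out.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestSelfLearn:
    def test_zero_rate_is_identity(self, frame1):
        m = bf(frame1, R1=0.3, I1=0.7)
        np.testing.assert_allclose(self_learn(m, 0, 0.0).mass, m.mass)

    def test_committed_irregular_is_exempt(self, frame1):
        m = bf(frame1, I1=1.0)
        np.testing.assert_allclose(self_learn(m, 0, 0.05).mass, m.mass)

    def test_transfer_arithmetic(self, frame1):
        out = self_learn(bf(frame1, R1=0.3, I1=0.7), 0, 0.05)
        assert out.mass[frame1.regular(0)] == pytest.approx(0.335)
        assert out.mass[frame1.irregular(0)] == pytest.approx(0.665)

    def test_other_verbs_untouched(self, frame2):
        m = bf(frame2, R1=0.2, I1=0.3, R2=0.1, I2=0.4)
        out = self_learn(m, 0, 0.5)
        assert out.mass[frame2.regular(1)] == pytest.approx(0.1)
        assert out.mass[frame2.irregular(1)] == pytest.approx(0.4)

    def test_geometric_decay_of_irregular_mass(self, frame1):
        m = bf(frame1, R1=0.3, I1=0.7)
        alpha = 0.1
        for k in range(1, 30):
            m = self_learn(m, 0, alpha)
            assert m.mass[frame1.irregular(0)] == pytest.approx(
                0.7 * (1 - alpha) ** k
            )
            assert m.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestForget:
    def test_zero_rate_is_identity(self, frame1):
        m = bf(frame1, R1=0.6, R1_I1=0.4)
        np.testing.assert_allclose(forget(m, 0.0).mass, m.mass)

    def test_transfer_arithmetic(self, frame1):
        out = forget(bf(frame1, R1=0.6, R1_I1=0.4), 0.04)
        assert out.mass[frame1.regular(0)] == pytest.approx(0.576)
        assert out.mass[frame1.theta] == pytest.approx(0.424)

    def test_all_ignorance_is_noop(self, frame2):
        m = bf(frame2, R1_R2_I1_I2=1.0)
        np.testing.assert_allclose(forget(m, 0.5).mass, m.mass)

    def test_strongest_non_theta_focal_chosen_with_low_bitmask_ties(self, frame2):
        m = bf(frame2, R1=0.4, I1=0.4, R1_R2_I1_I2=0.2)
        out = forget(m, 0.1)
        # R1 (bitmask 1) loses mass, the tied I1 (bitmask 4) does not
        assert out.mass[frame2.regular(0)] == pytest.approx(0.36)
        assert out.mass[frame2.irregular(0)] == pytest.approx(0.4)
        assert out.mass[frame2.theta] == pytest.approx(0.24)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**16), c=st.floats(0.0, 1.0))
def test_discount_then_combine_conserves_mass(seed, c):
    frame = make_frame(2)
    rng = np.random.default_rng(seed)
    acc = discount(_random_belief(frame, rng), 1.0)
    try:
        out = wer_combine_step(acc, discount(_random_belief(frame, rng), c))
    except TotalConflictError:
        assert c == 1.0
        return
    assert out.mass.sum() + out.unassigned == pytest.approx(1.0, abs=1e-9)
    assert out.mass[0] == 0.0
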