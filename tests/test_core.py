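"""Unit and property tests for the core dynamic equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdfasart import (
    FuzzyCategory,
    InputPattern,
    NetworkParams,
    SdFasArtModel,
    activation,
    category_size,
    fast_commit,
    membership,
    reset_level,
    select_winner,
    slow_recode,
)
from sdfasart.core import (
    InvalidCategoryError,
    ShapeError,
    SupervisionRequiredError,
    fallback_membership,
)

from conftest import random_category_triple


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def _membership_reference(x, w, v, sigma):
    """Independent piecewise evaluation of the trapezoid."""
    if w <= x <= v:
        return 1.0
    if x < w - sigma or x > v + sigma:
        return 0.0
    if x < w:
        return (x - (w - sigma)) / sigma
    return ((v + sigma) - x) / sigma


class TestMembership:
    def test_plateau_contains_center(self):
        assert membership(0.5, 0.4, 0.5, 0.6, 0.1) == 1.0
        assert membership(0.4, 0.4, 0.5, 0.6, 0.1) == 1.0

    def test_outside_support_is_zero(self):
        assert membership(0.4 - 0.1 - 0.01, 0.4, 0.5, 0.6, 0.1) == 0.0

    def test_linear_flank_value(self):
        # halfway up the left flank: (x - (w - sigma)) / sigma = 0.5
        assert membership(0.35, 0.4, 0.5, 0.6, 0.1) == pytest.approx(0.5)

    def test_matches_dense_piecewise_reference(self):
        w, c, v, sigma = 0.3, 0.45, 0.6, 0.07
        for x in np.linspace(-0.2, 1.2, 561):
            assert membership(x, w, c, v, sigma) == pytest.approx(
                _membership_reference(x, w, v, sigma), abs=1e-12
            )

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InvalidCategoryError):
            membership(0.5, 0.6, 0.5, 0.4, 0.1)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        x=st.floats(-0.5, 1.5),
        a=st.floats(0, 1),
        b=st.floats(0, 1),
        c=st.floats(0, 1),
        sigma=st.floats(0.001, 1.0),
    )
    def test_range_and_support_width(self, x, a, b, c, sigma):
        """Membership lies in [0, 1]; 1 exactly on [w, v]; support [w-s, v+s]."""
        w, cc, v = sorted([a, b, c])
        eta = membership(x, w, cc, v, sigma)
        assert 0.0 <= eta <= 1.0
        if w <= x <= v:
            assert eta == 1.0
        if x < w - sigma or x > v + sigma:
            assert eta == 0.0

    def test_fallback_membership_extends_to_boundaries(self):
        # plateau [0.4, 0.6]: flank hits 0 exactly at the domain edges
        assert fallback_membership(0.0, 0.4, 0.6) == 0.0
        assert fallback_membership(0.2, 0.4, 0.6) == pytest.approx(0.5)
        assert fallback_membership(0.5, 0.4, 0.6) == 1.0
        assert fallback_membership(0.8, 0.4, 0.6) == pytest.approx(0.5)
        assert fallback_membership(1.0, 0.4, 0.6) == 0.0


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

class TestActivation:
    def test_full_membership_fixed_point(self, params):
        cat = FuzzyCategory(W=[0.2, 0.2], C=[0.5, 0.5], V=[0.8, 0.8], label="a")
        pat = InputPattern([0.5, 0.5])
        assert activation(pat, cat, params) == pytest.approx(100.0)

    def test_zero_membership_annihilates(self, params):
        cat = FuzzyCategory(W=[0.2], C=[0.2], V=[0.2], label="a")
        pat = InputPattern([0.9])
        assert activation(pat, cat, params) == 0.0

    def test_euler_mode_agrees_with_equilibrium(self):
        # eta product 0.5 via one half-flank feature among full ones
        params = NetworkParams(sigma=0.1)
        cat = FuzzyCategory(
            W=[0.4] + [0.0] * 4, C=[0.5] * 5, V=[0.6] + [1.0] * 4, label="a"
        )
        pat = InputPattern([0.35, 0.5, 0.5, 0.5, 0.5])
        eq = activation(pat, cat, params)
        assert eq == pytest.approx(50.0)
        eu = activation(pat, cat, params, method="euler", tol=1e-9)
        assert abs(eu - eq) < 1e-6

    def test_dimension_mismatch(self, params):
        cat = FuzzyCategory(W=[0.2], C=[0.5], V=[0.8], label="a")
        with pytest.raises(ShapeError):
            activation(InputPattern([0.5, 0.5]), cat, params)


# ---------------------------------------------------------------------------
# category size
# ---------------------------------------------------------------------------

class TestCategorySize:
    def test_point_category_exact_match_is_zero(self, params):
        x = np.array([0.3, 0.7, 0.5])
        cat = FuzzyCategory(W=x, C=x, V=x, label="a")
        assert category_size(InputPattern(x), cat, params) == 0.0

    def test_hand_evaluated_example(self, params):
        cat = FuzzyCategory(W=[0.2, 0.2], C=[0.3, 0.3], V=[0.4, 0.4], label="a")
        pat = InputPattern([0.5, 0.1])
        # l = [0.5-0.2, 0.4-0.1] = [0.3, 0.3]; denom = 0.6 + 0.001
        assert category_size(pat, cat, params) == pytest.approx(0.6 / 0.601)

    def test_inside_plateau_is_pattern_independent(self, params, rng):
        W, C, V = random_category_triple(rng, 4)
        expected = float(np.sum((V - W) / (np.abs(2 * C) + params.epsilon)))
        for _ in range(10):
            x = rng.uniform(W, V)
            cat = FuzzyCategory(W=W, C=C, V=V, label="a")
            assert category_size(InputPattern(x), cat, params) == pytest.approx(expected)

    def test_never_decreases_moving_outward(self, params, rng):
        W, C, V = random_category_triple(rng, 3)
        cat = FuzzyCategory(W=W, C=C, V=V, label="a")
        x = rng.uniform(0, 1, 3)
        base = category_size(InputPattern(x), cat, params)
        x2 = x.copy()
        x2[0] = min(1.0, max(x2[0], V[0]) + 0.1)  # push further outside
        assert category_size(InputPattern(x2), cat, params) >= base


# ---------------------------------------------------------------------------
# reset level
# ---------------------------------------------------------------------------

class TestResetLevel:
    def test_zero_size_gives_zero_for_every_law(self):
        for law in ("printed_steady_state", "printed_finite_horizon", "factored_rate"):
            params = NetworkParams(reset_law=law)
            assert reset_level(0.0, params) == 0.0

    def test_steady_state_cap(self):
        params = NetworkParams(reset_law="printed_steady_state", a_r=1.0)
        assert reset_level(10.0, params) == pytest.approx(0.2)

    def test_steady_state_interior_value(self):
        params = NetworkParams(reset_law="printed_steady_state", a_r=1.0)
        assert reset_level(0.1, params) == pytest.approx(0.1)

    def test_steady_state_matches_euler_integration(self):
        """Closed-form equilibrium equals explicit Euler of the printed law."""
        params = NetworkParams(reset_law="printed_steady_state", a_r=1.0)
        for d in (0.05, 0.1, 0.15, 0.5, 3.0):
            R, dt = 0.0, 0.001
            for _ in range(2_000_000):
                slope = (-params.a_r * R + params.b_r * d) * (params.r_max - R)
                R += dt * slope
                if abs(slope) < 1e-12:
                    break
            assert abs(reset_level(d, params) - R) < 1e-6

    def test_negative_size_rejected(self, params):
        with pytest.raises(ValueError):
            reset_level(-0.1, params)

    @pytest.mark.parametrize(
        "law", ["printed_steady_state", "printed_finite_horizon", "factored_rate"]
    )
    def test_monotone_in_size_and_bounded(self, law):
        params = NetworkParams(reset_law=law, a_r=0.87)
        grid = np.linspace(0, 5, 200)
        R = np.asarray(reset_level(grid, params))
        assert np.all(np.diff(R) >= -1e-15)
        assert np.all(R <= params.r_max + 1e-15)
        assert np.all(R >= 0)

    def test_factored_rate_grows_with_a_r(self):
        """The default law's finite-horizon reset increases with A_R."""
        levels = [
            reset_level(0.5, NetworkParams(reset_law="factored_rate", a_r=a))
            for a in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(b > a for a, b in zip(levels, levels[1:]))

    def test_printed_steady_state_decreases_with_a_r(self):
        """The printed equilibrium law moves the other way (kept selectable)."""
        levels = [
            reset_level(0.1, NetworkParams(reset_law="printed_steady_state", a_r=a))
            for a in (1.0, 2.0, 4.0)
        ]
        assert all(b < a for a, b in zip(levels, levels[1:]))


# ---------------------------------------------------------------------------
# winner selection, commit, recode
# ---------------------------------------------------------------------------

class TestWinnerSelection:
    def test_argmax(self, params):
        model = SdFasArtModel(params)
        assert select_winner(model, [0.2, 0.9, 0.4]) == 1

    def test_tie_breaks_to_oldest(self, params):
        model = SdFasArtModel(params)
        assert select_winner(model, [0.9, 0.9]) == 0

    def test_all_null_returns_none(self, params):
        model = SdFasArtModel(params)
        assert select_winner(model, [0.0, 0.0]) is None
        assert select_winner(model, []) is None


class TestFastCommit:
    def test_point_category_from_pattern(self, params):
        model = SdFasArtModel(params)
        x = [0.1, 0.9, 0.5, 0.5, 0.5]
        cat = fast_commit(InputPattern(x, label="stress"), model)
        assert np.array_equal(cat.W, x) and np.array_equal(cat.C, x)
        assert np.array_equal(cat.V, x)
        assert cat.label == "stress" and cat.T == 1.0 and cat.R == 0.0
        assert model.n_categories == 1

    def test_committed_pattern_has_full_membership(self, params):
        model = SdFasArtModel(params)
        x = np.array([0.3, 0.6])
        cat = fast_commit(InputPattern(x, label="a"), model)
        eta = membership(x, cat.W, cat.C, cat.V, params.sigma)
        assert np.all(eta == 1.0)

    def test_k_commits_give_k_categories(self, params, rng):
        model = SdFasArtModel(params)
        for k in range(7):
            fast_commit(InputPattern(rng.uniform(0, 1, 3), label=k % 2), model)
        assert model.n_categories == 7

    def test_unlabeled_pattern_rejected(self, params):
        model = SdFasArtModel(params)
        with pytest.raises(SupervisionRequiredError):
            fast_commit(InputPattern([0.5]), model)


class TestSlowRecode:
    def test_hand_evaluated_update(self, params):
        cat = FuzzyCategory(W=[0.4], C=[0.5], V=[0.6], label="a")
        out = slow_recode(InputPattern([0.2]), cat, params)
        assert out.W[0] == pytest.approx(0.24)
        assert out.C[0] == pytest.approx(0.26)
        assert out.V[0] == pytest.approx(0.6)

    def test_pattern_inside_plateau_only_moves_center(self, params):
        cat = FuzzyCategory(W=[0.2], C=[0.5], V=[0.8], label="a")
        out = slow_recode(InputPattern([0.4]), cat, params)
        assert out.W[0] == 0.2 and out.V[0] == 0.8
        assert out.C[0] == pytest.approx(0.5 + params.a_c * (0.4 - 0.5))

    def test_repeated_presentation_converges_to_fixed_point(self, params, rng):
        W0, C0, V0 = random_category_triple(rng, 4)
        cat = FuzzyCategory(W=W0, C=C0, V=V0, label="a")
        x = rng.uniform(0, 1, 4)
        for _ in range(300):
            cat = slow_recode(InputPattern(x), cat, params)
        np.testing.assert_allclose(cat.W, np.minimum(x, W0), atol=1e-9)
        np.testing.assert_allclose(cat.C, x, atol=1e-9)
        np.testing.assert_allclose(cat.V, np.maximum(x, V0), atol=1e-9)

    def test_ordering_survives_unequal_rates_transient(self, params):
        # A_C > A_V would push C past V without the plateau-widening guard
        cat = FuzzyCategory(W=[0.5], C=[0.5], V=[0.5], label="a")
        out = slow_recode(InputPattern([1.0]), cat, params)
        assert out.W[0] <= out.C[0] <= out.V[0]

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_preserves_ordering_and_unit_interval(self, data):
        vals = data.draw(
            st.lists(st.floats(0, 1), min_size=9, max_size=9).map(np.asarray)
        )
        triple = np.sort(vals[:9].reshape(3, 3), axis=0)
        x = data.draw(st.lists(st.floats(0, 1), min_size=3, max_size=3).map(np.asarray))
        cat = FuzzyCategory(W=triple[0], C=triple[1], V=triple[2], label="a")
        out = slow_recode(InputPattern(x), cat, NetworkParams())
        assert np.all(out.W <= out.C) and np.all(out.C <= out.V)
        assert np.all(out.W >= 0) and np.all(out.V <= 1)


# ---------------------------------------------------------------------------
# model container and serialization
# ---------------------------------------------------------------------------

class TestModelSerialization:
    def test_round_trip_exact(self, params, rng):
        model = SdFasArtModel(params)
        for k in range(5):
            fast_commit(InputPattern(rng.uniform(0, 1, 4), label=f"c{k % 3}"), model)
        clone = SdFasArtModel.from_dict(model.to_dict())
        assert clone.labels == model.labels
        assert clone.n_categories == model.n_categories
        for a, b in zip(model.categories, clone.categories):
            assert np.array_equal(a.W, b.W)
            assert np.array_equal(a.C, b.C)
            assert np.array_equal(a.V, b.V)
            assert a.label == b.label

    def test_file_round_trip_exact(self, params, rng, tmp_path):
        model = SdFasArtModel(params)
        for _ in range(3):
            fast_commit(InputPattern(rng.uniform(0, 1, 2), label="x"), model)
        path = tmp_path / "model.json"
        model.save(path)
        clone = SdFasArtModel.load(path)
        assert clone.to_dict() == model.to_dict()

    def test_invalid_ordering_rejected_on_construction(self):
        with pytest.raises(InvalidCategoryError):
            FuzzyCategory(W=[0.5], C=[0.4], V=[0.6], label="a")

    def test_pattern_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            InputPattern([1.2, 0.5])
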