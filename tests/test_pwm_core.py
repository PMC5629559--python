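import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unlogo import (
    PWM,
    ValidationError,
    build_lookup,
    estimate_column,
    information_content,
    solve_single_strong,
    solve_two_strong,
)
from unlogo.pwm_core import _ic_single

from conftest import grid_invert_single, grid_invert_two, ic_two_oracle


class TestInformationContent:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((1, 0, 0, 0), 2.0),
            ((0.5, 0.5, 0, 0), 1.0),
        ],
    )
    def test_known_columns(self, col, expected):
        assert information_content(col) == pytest.approx(expected, abs=1e-12)

    def test_rejects_unnormalized_column(self):
        with pytest.raises(ValidationError):
            information_content((0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            information_content((1.2, -0.2, 0, 0))


class TestPWMType:
    def test_valid_matrix_and_metadata(self):
        pwm = PWM(probs=np.tile([[0.7], [0.1], [0.1], [0.1]], (1, 3)))
        assert pwm.length == 3
        assert pwm.alphabet == ("A", "C", "G", "T")
        assert not pwm.probs.flags.writeable

    @pytest.mark.parametrize(
        "bad",
        [
            np.ones((4, 0)),
            np.ones((3, 2)) / 3,
            np.full((4, 2), 0.3),
            np.array([[1.1], [-0.1], [0.0], [0.0]]),
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValidationError):
            PWM(probs=bad)


class TestLookupTable:
    def test_default_grid(self):
        table = build_lookup(0.01)
        assert len(table.entries) == 76
        assert table.p[0] == pytest.approx(0.25)
        assert table.p[-1] == pytest.approx(1.0)
        assert table.info[0] == pytest.approx(0.0, abs=1e-12)
        assert table.info[-1] == pytest.approx(2.0, abs=1e-12)
        assert np.all(np.diff(table.info) > 0)

    def test_step_validation(self):
        with pytest.raises(ValidationError):
            build_lookup(0.0)
        with pytest.raises(ValidationError):
            build_lookup(0.3)


class TestSingleStrongSolver:
    def test_endpoints(self):
        assert solve_single_strong(2.0) == pytest.approx(1.0)
        assert solve_single_strong(0.0) == pytest.approx(0.25)

    def test_one_bit_matches_brute_force(self):
        expected = grid_invert_single(1.0)
        assert expected == pytest.approx(0.81, abs=0.005)
        assert solve_single_strong(1.0) == pytest.approx(expected, abs=1e-3)

    def test_small_overshoot_clamped_large_rejected(self):
        assert solve_single_strong(2.04) == pytest.approx(1.0)
        assert solve_single_strong(-0.04) == pytest.approx(0.25)
        with pytest.raises(ValidationError):
            solve_single_strong(2.2)

    def test_inversion_recovers_probability_grid(self):
        """Round trip p -> I -> p across [0.25, 1] at step 0.005."""
        for p in np.arange(0.25, 1.0 + 1e-9, 0.005):
            q = (1.0 - p) / 3.0
            info = information_content((p, q, q, q))
            assert solve_single_strong(info) == pytest.approx(p, abs=0.01)

    @given(
        st.tuples(
            st.floats(min_value=0.0, max_value=2.0),
            st.floats(min_value=0.0, max_value=2.0),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_information(self, pair):
        lo, hi = sorted(pair)
        assert solve_single_strong(lo) <= solve_single_strong(hi) + 1e-9


class TestTwoStrongSolver:
    def test_equal_heights_one_bit(self):
        p1, p2 = solve_two_strong(1.0, 1.0)
        assert (p1, p2) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_zero_information_uniform(self):
        p1, p2 = solve_two_strong(0.0, 1.0)
        assert (p1, p2) == (pytest.approx(0.25), pytest.approx(0.25))

    def test_half_bit_half_ratio(self):
        p1, p2 = solve_two_strong(0.5, 0.5)
        assert p2 == pytest.approx(p1 / 2, abs=1e-9)
        assert ic_two_oracle(p1, 0.5) == pytest.approx(0.5, abs=1e-4)
        assert p1 == pytest.approx(grid_invert_two(0.5, 0.5), abs=1e-3)

    def test_ratio_validation(self):
        with pytest.raises(ValidationError):
            solve_two_strong(1.0, 0.0)
        with pytest.raises(ValidationError):
            solve_two_strong(1.0, 1.5)

    def test_recovers_constructed_columns(self):
        """p1/p2 grids satisfying the strong-letter ordering round-trip."""
        for p1 in np.arange(0.3, 1.0, 0.05):
            for p2 in np.arange(0.05, p1 + 1e-9, 0.05):
                pw = (1.0 - p1 - p2) / 2.0
                if pw < 0 or p2 < pw:
                    continue
                info = information_content((p1, p2, pw, pw))
                q1, q2 = solve_two_strong(info, p2 / p1)
                assert q1 == pytest.approx(p1, abs=0.01)
                assert q2 == pytest.approx(p2, abs=0.01)


class TestEstimateColumn:
    def test_full_height_single_letter(self):
        est = estimate_column(100, {"A": 100}, 100)
        assert est.case_used == "single_strong"
        assert est.top_letter == "A"
        assert est.info_content == pytest.approx(2.0)
        assert est.probs[0] == pytest.approx(1.0)

    def test_two_pixel_secondary_stays_single_strong(self):
        """A 2-px secondary letter is below the 3-pixel-line threshold."""
        est = estimate_column(50, {"C": 30, "G": 2}, 100)
        assert est.case_used == "single_strong"
        assert est.top_letter == "C"
        assert est.second_letter is None
        expected = solve_single_strong(1.0)
        assert est.probs[1] == pytest.approx(expected, abs=1e-6)
        weak = (1 - expected) / 3
        np.testing.assert_allclose(est.probs[[0, 2, 3]], weak, atol=1e-9)

    def test_equal_tallest_letters_two_strong(self):
        est = estimate_column(50, {"C": 25, "T": 25}, 100)
        assert est.case_used == "two_strong"
        np.testing.assert_allclose(est.probs, [0, 0.5, 0, 0.5], atol=1e-6)

    def test_empty_column_rejected(self):
        with pytest.raises(ValidationError, match="empty column"):
            estimate_column(10, {"A": 0, "C": 0}, 100)

    def test_infeasible_two_strong_falls_back_with_warning(self):
        # nearly 2 bits with two equal strong letters is contradictory
        est = estimate_column(95, {"A": 40, "T": 40}, 100)
        assert est.case_used == "single_strong"
        assert est.warnings

    @given(
        st.integers(min_value=1, max_value=200),
        st.lists(st.integers(min_value=0, max_value=200), min_size=4, max_size=4),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_output_is_probability_simplex(self, stack, heights):
        hmap = dict(zip("ACGT", heights))
        if max(heights) == 0:
            return
        est = estimate_column(min(stack, 200), hmap, 200)
        assert est.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(est.probs >= 0)
        assert 0.0 <= est.info_content <= 2.0


class TestOracleEquivalence:
    def test_solvers_match_fine_grid_search(self):
        """Both solvers agree with 1e-6 brute force on random instances."""
        rng = np.random.default_rng(1234)
        for _ in range(25):
            info = float(rng.uniform(0.0, 2.0))
            assert solve_single_strong(info) == pytest.approx(
                grid_invert_single(info), abs=1e-3
            )
        for _ in range(25):
            r = float(rng.uniform(0.1, 1.0))
            lo, hi = 1 / (1 + 3 * r), 1 / (1 + r)
            info = float(ic_two_oracle(np.array(rng.uniform(lo, hi)), r))
            p1, _ = solve_two_strong(info, r)
            assert p1 == pytest.approx(grid_invert_two(info, r), abs=1e-3)
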