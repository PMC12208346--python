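"""Aitchison-geometry primitives: closure, ilr, SBP bases, zero handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepcoda.composition import (
    DEFAULT_SBP,
    SleepComposition,
    close,
    geometric_mean,
    ilr,
    ilr_basis,
    ilr_inv,
    replace_zeros,
    validate_sbp,
)

from conftest import ALT_SBP

# a spread of valid sequential binary partitions for D = 3, 4, 5
SBPS = [
    DEFAULT_SBP,
    ALT_SBP,
    np.array([[1, -1, -1, -1], [0, 1, -1, -1], [0, 0, 1, -1]], float)[:, ::-1] * -1,
    np.array([[1, 1, -1], [1, -1, 0]], float),
    np.array([[-1, 1, 1], [0, 1, -1]], float),
    np.array(
        [
            [1, 1, -1, -1, -1],
            [1, -1, 0, 0, 0],
            [0, 0, 1, 1, -1],
            [0, 0, 1, -1, 0],
        ],
        float,
    ),
]


def aitchison_distance(x, y):
    """Independent oracle via centred log-ratios."""
    cx = np.log(x) - np.log(x).mean()
    cy = np.log(y) - np.log(y).mean()
    return np.linalg.norm(cx - cy)


def random_composition(rng, d=4):
    return rng.dirichlet(np.full(d, 2.0))


class TestClose:
    def test_symmetry(self):
        assert np.allclose(close([1, 1, 1, 1]), [0.25] * 4)

    def test_normalisation_preserves_ratios(self):
        mins = np.array([71.77, 190.78, 86.58, 98.35])
        out = close(mins)
        assert np.isclose(out.sum(), 1.0)
        assert np.allclose(out, mins / mins.sum())
        assert np.allclose(out / out[0], mins / mins[0])

    def test_scale_invariance(self):
        x = np.array([0.2, 0.3, 0.1, 0.4])
        assert np.allclose(close(close(x), 448.66), 448.66 * close(x))

    def test_degenerate_and_negative_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            close([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="nonnegative"):
            close([-0.1, 0.5, 0.3, 0.3])


class TestGeometricMean:
    def test_identical_compositions(self):
        x = np.array([60.0, 200.0, 90.0, 100.0])
        out = geometric_mean(np.tile(x, (5, 1)))
        assert np.allclose(out, close(x))

    def test_two_compositions_brute_force(self):
        a = np.array([0.1, 0.4, 0.2, 0.3])
        b = np.array([0.4, 0.1, 0.3, 0.2])
        assert np.allclose(geometric_mean(np.stack([a, b])), close(np.sqrt(a * b)))

    def test_commutes_with_ilr(self):
        rng = np.random.default_rng(0)
        comps = np.stack([random_composition(rng) for _ in range(20)])
        v = ilr_basis()
        lhs = ilr(geometric_mean(comps), v)
        rhs = ilr(comps, v).mean(axis=0)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_zero_parts_direct_caller(self):
        with pytest.raises(ValueError, match="replace_zeros"):
            geometric_mean(np.array([[0.0, 0.4, 0.3, 0.3]]))


class TestSbpAndBasis:
    @pytest.mark.parametrize("sbp", SBPS, ids=range(len(SBPS)))
    def test_orthonormal_zero_sum(self, sbp):
        v = ilr_basis(sbp)
        d = sbp.shape[1]
        assert np.allclose(v @ v.T, np.eye(d - 1), atol=1e-12)
        assert np.allclose(v.sum(axis=1), 0.0, atol=1e-12)

    def test_closed_form_single_pair(self):
        # SWS vs REM balance: r = s = 1
        v = ilr_basis(DEFAULT_SBP)
        assert np.allclose(v[2], [0, 0, 1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_closed_form_one_vs_three(self):
        # wake vs all-sleep balance: r = 1, s = 3
        v = ilr_basis(DEFAULT_SBP)
        expected = [np.sqrt(3 / 4), -np.sqrt(1 / 12), -np.sqrt(1 / 12), -np.sqrt(1 / 12)]
        assert np.allclose(v[0], expected)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[1, 1, 1, 1], [0, 1, -1, -1], [0, 0, 1, -1]], float),
            np.array([[1, -1, -1, -1], [1, 1, -1, -1], [0, 0, 1, -1]], float),
            np.array([[1, -1, -1, -1], [0, 1, -1, -1]], float),
            np.array([[1, -1, 0, 0], [0, 0, 1, -1], [1, 1, -1, -1]], float)[
                [0, 1]
            ],  # no root row
        ],
        ids=["no-negative", "straddles", "too-few-rows", "no-root"],
    )
    def test_invalid_sbp_rejected(self, bad):
        with pytest.raises(ValueError):
            ilr_basis(bad)

    def test_basis_change_is_orthogonal_rotation(self):
        rng = np.random.default_rng(1)
        v1, v2 = ilr_basis(DEFAULT_SBP), ilr_basis(ALT_SBP)
        r = v2 @ v1.T
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        for _ in range(10):
            x = random_composition(rng)
            assert np.allclose(ilr(x, v2), r @ ilr(x, v1), atol=1e-12)


class TestIlr:
    def test_equal_composition_maps_to_origin(self):
        assert np.allclose(ilr([0.25] * 4), np.zeros(3), atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=4, max_size=4))
    def test_round_trip(self, parts):
        x = close(np.array(parts))
        assert np.max(np.abs(ilr_inv(ilr(x)) - x)) < 1e-12

    def test_scale_invariance(self):
        x = np.array([58.0, 193.0, 94.0, 103.0])
        assert np.allclose(ilr(x), ilr(x / x.sum()), atol=1e-13)

    def test_isometry_vs_clr_oracle(self):
        rng = np.random.default_rng(3)
        for sbp in (DEFAULT_SBP, ALT_SBP):
            v = ilr_basis(sbp)
            for _ in range(20):
                x, y = random_composition(rng), random_composition(rng)
                d_ilr = np.linalg.norm(ilr(x, v) - ilr(y, v))
                assert abs(d_ilr - aitchison_distance(x, y)) < 1e-10

    def test_matches_skbio_geometry(self):
        # independent library route: distances and round trips agree
        from skbio.stats.composition import clr

        rng = np.random.default_rng(4)
        x, y = random_composition(rng), random_composition(rng)
        d_skbio = np.linalg.norm(clr(x) - clr(y))
        assert abs(np.linalg.norm(ilr(x) - ilr(y)) - d_skbio) < 1e-10

    def test_zero_part_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ilr([0.0, 0.4, 0.3, 0.3])

    def test_inverse_of_origin_is_uniform(self):
        assert np.allclose(ilr_inv(np.zeros(3)), [0.25] * 4)

    def test_inverse_guards_overflow(self):
        out = ilr_inv(np.array([500.0, -400.0, 300.0]))
        assert np.isfinite(out).all() and np.isclose(out.sum(), 1.0)

    def test_inverse_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            ilr_inv(np.array([np.inf, 0.0, 0.0]))


class TestReplaceZeros:
    def test_identity_without_zeros(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        assert np.array_equal(replace_zeros(x, 100.0), x)

    def test_closed_form_single_zero(self):
        out = replace_zeros(np.array([0.0, 300.0, 100.0, 50.0]), 450.0, delta=0.5)
        scale = (450.0 - 0.5) / 450.0
        assert np.allclose(out, [0.5, 300 * scale, 100 * scale, 50 * scale])
        assert np.isclose(out.sum(), 450.0)

    def test_two_zeros_symmetric(self):
        out = replace_zeros(np.array([0.0, 200.0, 0.0, 200.0]), 400.0, delta=0.5)
        assert out[0] == out[2] == 0.5
        assert np.isclose(out[1], out[3])
        assert np.isclose(out.sum(), 400.0)

    def test_delta_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            replace_zeros(np.array([0.0, 0.0, 0.0, 1.0]), 1.2, delta=0.5)


class TestSleepComposition:
    def test_minutes_must_sum_to_tib(self):
        with pytest.raises(ValueError, match="sum"):
            SleepComposition(60, 200, 90, 100, 500.0)

    def test_proportions_and_roundtrip(self):
        c = SleepComposition(58, 193, 94, 103, 448.0)
        assert np.isclose(c.proportions.sum(), 1.0)
        c2 = SleepComposition.from_proportions(c.proportions, c.tib_min)
        assert np.allclose(c2.minutes, c.minutes)

    def test_zero_replacement_method(self):
        c = SleepComposition(0.0, 250.0, 100.0, 100.0, 450.0)
        r = c.replace_zeros()
        assert r.twt_min == 0.5 and np.isclose(r.minutes.sum(), 450.0)
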