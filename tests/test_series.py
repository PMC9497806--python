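"""Composite-series construction: resampling, normalization, shuffle/flip,
quantile reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirodyn import (
    ArgumentError,
    DancerTrial,
    DegenerateInputError,
    build_composite,
    generate_pirouette_cohort,
    normalize_by_max,
    prepare_trials,
    quantile_reduce,
    resample_to_fixed_length,
)
from pirodyn.series import NormalizedTrial


def _trial(frames, sid=1):
    return DancerTrial(subject_id=sid, landmark="LKNE", task="jazz", frames=np.asarray(frames))


class TestResample:
    def test_length_137_to_300(self):
        (t,) = generate_pirouette_cohort(1, "jazz", "LKNE", (137, 137), 0.0, seed=0)
        out = resample_to_fixed_length(t)
        assert out.n_frames == 300
        # endpoints preserved exactly
        np.testing.assert_array_equal(out.frames[0], t.frames[0])
        np.testing.assert_array_equal(out.frames[-1], t.frames[-1])

    def test_linear_ramp_is_fixed_point(self):
        ramp = np.linspace(0, 1, 300)
        t = _trial(np.column_stack([ramp, ramp, ramp]))
        out = resample_to_fixed_length(t)
        np.testing.assert_allclose(out.frames[:, 0], ramp, atol=1e-12)

    def test_constant_column_stays_constant(self):
        t = _trial(np.full((101, 3), 5.0))
        out = resample_to_fixed_length(t)
        assert out.n_frames == 300
        np.testing.assert_allclose(out.frames, 5.0)

    def test_too_short_errors(self):
        with pytest.raises(ArgumentError):
            resample_to_fixed_length(_trial(np.zeros((1, 3))))


class TestNormalize:
    def test_scales_to_unit_max_abs(self):
        frames = np.column_stack([
            np.linspace(-2, 2, 300), np.linspace(0.5, 1.0, 300), np.linspace(-1, 0.5, 300)
        ])
        out = normalize_by_max(_trial(frames))
        np.testing.assert_allclose(np.max(np.abs(out.values), axis=0), 1.0)
        np.testing.assert_allclose(out.scale_factors, [2.0, 1.0, 1.0])
        np.testing.assert_allclose(out.values[:, 0], frames[:, 0] / 2.0)

    def test_already_normalized_unchanged(self):
        frames = np.column_stack([np.sin(np.linspace(0, 3 * np.pi, 300))] * 3)
        frames[0] = [1.0, 1.0, 1.0]
        out = normalize_by_max(_trial(frames))
        np.testing.assert_array_equal(out.values, frames)

    def test_zero_column_rejected(self):
        frames = np.ones((300, 3))
        frames[:, 2] = 0.0
        with pytest.raises(DegenerateInputError):
            normalize_by_max(_trial(frames))


def _normalized(sid, values):
    v = np.asarray(values, dtype=float)
    scales = np.max(np.abs(v), axis=0)
    return NormalizedTrial(values=v / scales, subject_id=sid, landmark="LKNE",
                           task="jazz", scale_factors=scales)


class TestBuildComposite:
    def test_fifteen_trials_give_4500_points(self):
        trials = prepare_trials(
            generate_pirouette_cohort(15, "jazz", "LKNE", (101, 250), 0.002, seed=7)
        )
        comp = build_composite(trials, seed=11)
        assert set(comp) == {"x", "y", "z"}
        for series in comp.values():
            assert len(series) == 15 * 300
            assert sorted(series.permutation) == list(range(1, 16))

    def test_two_trials_identity_permutation_flips_second(self):
        rng = np.random.default_rng(0)
        a = _normalized(1, rng.normal(size=(300, 3)))
        b = _normalized(2, rng.normal(size=(300, 3)))
        # find a seed whose permutation of 2 elements is the identity
        seed = next(s for s in range(50)
                    if list(np.random.default_rng(s).permutation(2)) == [0, 1])
        comp = build_composite([a, b], seed=seed)
        np.testing.assert_array_equal(comp["x"].values[:300], a.values[:, 0])
        np.testing.assert_array_equal(comp["x"].values[300:], b.values[::-1, 0])
        assert comp["x"].flipped_positions == [2]

    def test_single_trial_nothing_flipped(self):
        a = _normalized(1, np.random.default_rng(1).normal(size=(300, 3)))
        comp = build_composite([a], seed=0)
        assert len(comp["y"]) == 300
        assert comp["y"].flipped_positions == []
        np.testing.assert_array_equal(comp["y"].values, a.values[:, 1])

    def test_mixed_landmarks_rejected(self):
        a = _normalized(1, np.random.default_rng(1).normal(size=(300, 3)))
        b = _normalized(2, np.random.default_rng(2).normal(size=(300, 3)))
        b.landmark = "CoM"
        with pytest.raises(ArgumentError):
            build_composite([a, b], seed=0)

    def test_shuffle_preserves_value_multiset(self, small_cohort):
        comp = build_composite(small_cohort, seed=99)
        pooled = np.sort(np.concatenate([t.values[:, 0] for t in small_cohort]))
        np.testing.assert_array_equal(np.sort(comp["x"].values), pooled)

    def test_flip_is_involution(self, small_cohort):
        """Reversing the even-position blocks of the composite restores the
        plain shuffled concatenation."""
        comp = build_composite(small_cohort, seed=5)
        x = comp["x"].values.copy()
        for pos in comp["x"].flipped_positions:
            block = slice((pos - 1) * 300, pos * 300)
            x[block] = x[block][::-1]
        order = {t.subject_id: t for t in small_cohort}
        plain = np.concatenate([order[sid].values[:, 0] for sid in comp["x"].permutation])
        np.testing.assert_array_equal(x, plain)


def _series(values):
    from pirodyn import CompositeSeries

    return CompositeSeries(coordinate="x", values=np.asarray(values, dtype=float),
                           n_trials=0, permutation=[], flipped_positions=[])


class TestQuantileReduce:
    def test_uniform_4500_keeps_4050(self):
        """Brute-force count: survivors are exactly the values >= the type-7
        empirical 0.1-quantile."""
        vals = np.random.default_rng(0).uniform(size=4500)
        reduced = quantile_reduce(_series(vals), 0.1)
        threshold = np.quantile(vals, 0.1)
        expected = int(np.sum(vals >= threshold))  # independent brute force
        assert len(reduced) == expected == 4050
        assert reduced.reduced

    def test_preserves_temporal_order(self, small_cohort):
        comp = build_composite(small_cohort, seed=1)["z"]
        reduced = quantile_reduce(comp, 0.1)
        kept = comp.values[comp.values >= np.quantile(comp.values, 0.1)]
        np.testing.assert_array_equal(reduced.values, kept)

    def test_all_equal_series_untouched(self):
        reduced = quantile_reduce(_series(np.full(1500, 3.14)), 0.1)
        assert len(reduced) == 1500

    def test_p_zero_is_identity(self, small_cohort):
        comp = build_composite(small_cohort, seed=1)["x"]
        reduced = quantile_reduce(comp, 0.0)
        np.testing.assert_array_equal(reduced.values, comp.values)

    def test_second_application_rejected_but_idempotent_by_value(self, small_cohort):
        comp = build_composite(small_cohort, seed=2)["y"]
        reduced = quantile_reduce(comp, 0.1)
        with pytest.raises(ArgumentError):
            quantile_reduce(reduced, 0.1)
        # value-level idempotence: re-running on the survivors removes nothing
        reduced.reduced = False
        again = quantile_reduce(reduced, 0.0)
        np.testing.assert_array_equal(again.values, reduced.values)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_survivor_fraction_bound(self, seed, p_low):
        """At least (1 - p_low) of the samples survive (ties at the threshold
        are kept, so the fraction can exceed the bound, never fall below),
        and the survivors are a subsequence of the input."""
        vals = np.random.default_rng(seed).normal(size=600)
        reduced = quantile_reduce(_series(vals), p_low)
        # discretization epsilon: the type-7 threshold sits between two order
        # statistics, so the count can undershoot by at most ~1/n
        assert len(reduced) / 600 >= (1.0 - p_low) - 2.0 / 600
        assert np.isin(reduced.values, vals).all()
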