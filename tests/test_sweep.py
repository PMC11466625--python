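"""Grid generation, transition detection and the sweep surrogate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elongsim.sweep import (
    PARAM_NAMES,
    SWEEP_RANGES,
    SweepPoint,
    aggregate_sweep,
    find_transition,
    fit_surrogate,
    generate_grid,
    run_sweep,
    scale_value,
    unscale_value,
)


class TestGrid:
    def test_slice_spans_the_stated_range(self):
        pts = generate_grid(mode="one_axis_slice", axis="psm_psm", points=9)
        vals = [p.psm_psm for p in pts]
        assert vals == pytest.approx(list(np.arange(5.0, 46.0, 5.0)))
        # others stay at range midpoints
        assert all(p.nc_nc == pytest.approx(8.5) for p in pts)

    def test_scaled_midrange_value(self):
        assert scale_value("psm_psm", 25.0) == pytest.approx(0.5)

    def test_full_grid_point_count(self):
        assert len(generate_grid(mode="full_grid", points_per_axis=3)) == 3**5

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            generate_grid(mode="one_axis_slice", points=1)

    def test_out_of_range_point_rejected(self):
        with pytest.raises(ValueError):
            SweepPoint(psm_psm=100.0, nc_nc=8.5, post_post=0.6,
                       psm_nc=50.0, psm_post=35.0)

    @given(st.sampled_from(PARAM_NAMES), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_bijection(self, name, scaled):
        raw = unscale_value(name, scaled)
        lo, hi = SWEEP_RANGES[name]
        assert lo <= raw <= hi + 1e-12
        assert scale_value(name, raw) == pytest.approx(scaled, abs=1e-12)


def slice_frame(labels, scaled):
    return pd.DataFrame(
        {
            "point": np.arange(len(labels)),
            "scaled_psm_psm": scaled,
            "label": labels,
        }
    )


class TestTransition:
    def test_midpoint_rule(self):
        agg = slice_frame(["CONVERGENCE", "CONVERGENCE", "ELONGATION",
                           "ELONGATION", "ELONGATION"],
                          [0.1, 0.3, 0.5, 0.7, 0.9])
        tr = find_transition(agg)
        assert tr.scaled_value == pytest.approx(0.4)
        assert tr.monotone

    def test_invariant_to_slice_order(self):
        agg = slice_frame(["ELONGATION", "CONVERGENCE", "ELONGATION",
                           "CONVERGENCE"],
                          [0.9, 0.1, 0.6, 0.4])
        tr = find_transition(agg)
        assert tr.scaled_value == pytest.approx(0.5)

    def test_single_regime_errors(self):
        agg = slice_frame(["ELONGATION"] * 3, [0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="no transition"):
            find_transition(agg)

    def test_non_monotone_slice_is_flagged(self):
        agg = slice_frame(["CONVERGENCE", "ELONGATION", "CONVERGENCE",
                           "ELONGATION"],
                          [0.1, 0.4, 0.6, 0.9])
        tr = find_transition(agg)
        assert not tr.monotone

    def test_refinement_shrinks_interval(self):
        coarse = slice_frame(["CONVERGENCE", "CONVERGENCE", "ELONGATION"],
                             [0.0, 0.4, 0.8])
        fine = slice_frame(
            ["CONVERGENCE"] * 3 + ["ELONGATION"] * 2,
            [0.0, 0.2, 0.4, 0.6, 0.8],
        )
        w_coarse = np.diff(find_transition(coarse).interval)[0]
        w_fine = np.diff(find_transition(fine).interval)[0]
        assert w_fine < w_coarse


class TestRunSweep:
    def test_identical_seeds_identical_outputs(self):
        pts = generate_grid(mode="one_axis_slice", points=2)
        df1 = run_sweep(pts, n_iterations=30, replicates=1, seed=7)
        df2 = run_sweep(pts, n_iterations=30, replicates=1, seed=7)
        pd.testing.assert_frame_equal(df1, df2)

    def test_tidy_schema(self):
        pts = generate_grid(mode="one_axis_slice", points=2)
        df = run_sweep(pts, n_iterations=30, replicates=2, seed=0)
        assert len(df) == 4
        for n in PARAM_NAMES:
            assert f"raw_{n}" in df.columns and f"scaled_{n}" in df.columns
        assert {"length", "width", "ratio", "label", "seed"} <= set(df.columns)
        agg = aggregate_sweep(df)
        assert len(agg) == 2 and (agg["n_replicates"] == 2).all()


def planted_sweep(n=100, seed=0, shuffle_targets=False):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 5))
    w_l = np.array([3.0, -1.0, 0.5, 2.0, -0.7])
    w_w = np.array([-2.0, 0.8, 1.5, -0.3, 1.1])
    length = X @ w_l + 1.0
    width = X @ w_w + 2.0
    if shuffle_targets:
        perm = rng.permutation(n)
        length, width = length[perm], width[perm]
    cols = {f"scaled_{nm}": X[:, k] for k, nm in enumerate(PARAM_NAMES)}
    cols.update(length=length, width=width)
    return pd.DataFrame(cols)


class TestSurrogate:
    def test_recovers_planted_linear_map(self):
        res = fit_surrogate(planted_sweep(), split_seed=0)
        assert res.metrics["r2_test"] > 0.99

    def test_split_is_70_15_15(self):
        res = fit_surrogate(planted_sweep(n=100), split_seed=1)
        assert len(res.split["train"]) == 70
        assert len(res.split["val"]) == 15
        assert len(res.split["test"]) == 15
        all_idx = np.concatenate(list(res.split.values()))
        assert len(np.unique(all_idx)) == 100

    def test_permuted_targets_have_no_skill(self):
        res = fit_surrogate(planted_sweep(shuffle_targets=True), split_seed=0)
        assert res.metrics["r2_test"] < 0.2

    def test_constant_targets_error(self):
        df = planted_sweep()
        df["length"] = 1.0
        df["width"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_surrogate(df)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            fit_surrogate(planted_sweep(n=20))

    def test_predict_runs_on_new_inputs(self):
        res = fit_surrogate(planted_sweep(), split_seed=0)
        out = res.predict(np.full((3, 5), 0.5))
        assert out.shape == (3, 2)
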