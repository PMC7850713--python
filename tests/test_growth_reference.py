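"""LMS transform, tail restriction, interpolation and table I/O."""

import io

import numpy as np
import pytest

from nutriscreen import growth_reference as gr
from nutriscreen.synthetic import make_synthetic_reference


def _random_lms(rng, n):
    """Valid random (z, L, M, S) tuples away from the L=0 neighborhood."""
    z = rng.uniform(-5.5, 5.5, n)
    L = np.where(rng.random(n) < 0.5, rng.uniform(-2, -0.05, n), rng.uniform(0.05, 2, n))
    M = rng.uniform(0.5, 120.0, n)
    S = rng.uniform(0.01, 0.25, n)
    ok = 1.0 + L * S * z > 1e-6
    return z[ok], L[ok], M[ok], S[ok]


class TestZscore:
    @pytest.mark.parametrize(
        "x,L,M,S,expected",
        [
            (16.0, -0.5, 16.0, 0.08, 0.0),  # median maps to zero
            (11.0, 1.0, 10.0, 0.1, 1.0),  # linear case: (x - M) / (M S)
            (10.0, 1e-12, 10.0, 0.1, 0.0),  # log limit at the median
        ],
    )
    def test_known_values(self, x, L, M, S, expected):
        assert gr.zscore_lms(x, L, M, S) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_measurement_is_invalid(self):
        assert np.isnan(gr.zscore_lms(-1.0, 1.0, 10.0, 0.1))
        assert np.isnan(gr.zscore_lms(0.0, 1.0, 10.0, 0.1))

    def test_monotone_in_measurement(self):
        x = np.linspace(4.0, 30.0, 200)
        z = gr.zscore_lms(x, -0.4, 15.0, 0.09)
        assert np.all(np.diff(z) > 0)

    def test_round_trip_ten_thousand_draws(self):
        rng = np.random.default_rng(42)
        z, L, M, S = _random_lms(rng, 20_000)
        assert len(z) >= 10_000
        back = gr.zscore_lms(gr.inverse_zscore(z, L, M, S), L, M, S)
        assert np.max(np.abs(back - z)) < 1e-9

    def test_log_limit_continuity(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(5, 20, 500)
        M = rng.uniform(8, 15, 500)
        S = rng.uniform(0.05, 0.2, 500)
        near = gr.zscore_lms(x, 1e-7, M, S)
        limit = np.log(x / M) / S
        assert np.max(np.abs(near - limit)) < 1e-5


class TestInverse:
    def test_zero_z_returns_median(self):
        assert gr.inverse_zscore(0.0, -0.3, 16.0, 0.08) == pytest.approx(16.0)

    def test_linear_case(self):
        assert gr.inverse_zscore(3.0, 1.0, 10.0, 0.1) == pytest.approx(13.0)

    def test_domain_error_raises_for_scalar(self):
        with pytest.raises(ValueError):
            gr.inverse_zscore(-30.0, 1.0, 10.0, 0.1)  # 1 + LSz < 0

    def test_domain_error_is_nan_for_array(self):
        out = gr.inverse_zscore(np.array([-30.0, 0.0]), 1.0, 10.0, 0.1)
        assert np.isnan(out[0]) and out[1] == pytest.approx(10.0)


class TestRestricted:
    L, M, S = -0.35, 16.0, 0.11

    def test_identical_inside_pm3(self):
        x = gr.inverse_zscore(np.linspace(-3, 3, 101), self.L, self.M, self.S)
        plain = gr.zscore_lms(x, self.L, self.M, self.S)
        restricted = gr.zscore_restricted(x, self.L, self.M, self.S)
        np.testing.assert_allclose(restricted, plain, atol=1e-12)

    @pytest.mark.parametrize("z_anchor", [-3.0, 3.0])
    def test_exact_at_sd3(self, z_anchor):
        x = gr.inverse_zscore(z_anchor, self.L, self.M, self.S)
        assert gr.zscore_restricted(x, self.L, self.M, self.S) == pytest.approx(z_anchor, abs=1e-12)

    def test_linear_reference_unchanged_everywhere(self):
        # with L = 1 the LMS scale is already linear (SD3 - SD2 = M S), so
        # the tail extension coincides with the plain score
        x = np.linspace(2.0, 30.0, 300)
        plain = gr.zscore_lms(x, 1.0, 10.0, 0.1)
        restricted = gr.zscore_restricted(x, 1.0, 10.0, 0.1)
        np.testing.assert_allclose(restricted, plain, atol=1e-10)

    def test_strictly_increasing_across_the_join(self):
        x = np.linspace(4.0, 45.0, 2000)
        z = gr.zscore_restricted(x, self.L, self.M, self.S)
        assert np.all(np.diff(z) > 0)

    def test_restricted_inverse_round_trip_in_the_tails(self):
        z = np.array([-5.5, -4.0, -3.5, -1.0, 0.0, 2.5, 3.5, 4.8])
        x = gr.inverse_zscore_restricted(z, self.L, self.M, self.S)
        back = gr.zscore_restricted(x, self.L, self.M, self.S)
        np.testing.assert_allclose(back, z, atol=1e-9)


class TestInterpolation:
    @pytest.fixture
    def ref(self):
        return gr.GrowthReference(
            "hfa", "f",
            index=[0.0, 1.0, 2.0],
            L=[1.0, 1.0, 1.0],
            M=[49.0, 53.0, 57.0],
            S=[0.035, 0.036, 0.037],
        )

    def test_grid_point_exact(self, ref):
        assert ref.lookup(1.0) == (1.0, 53.0, 0.036)

    def test_midpoint_is_arithmetic_mean(self, ref):
        L, M, S = ref.lookup(0.5)
        assert (L, M, S) == (1.0, 51.0, pytest.approx(0.0355))

    @pytest.mark.parametrize("x", [-0.1, 2.1, np.nan])
    def test_out_of_range_is_unavailable(self, ref, x):
        assert all(np.isnan(v) for v in ref.lookup(x))

    def test_scoring_at_grid_equals_raw_row(self, ref):
        z_grid = gr.zscore_lms(54.0, *ref.lookup(1.0))
        z_raw = gr.zscore_lms(54.0, 1.0, 53.0, 0.036)
        assert z_grid == pytest.approx(z_raw)


class TestReferenceIO:
    def test_parse_minimal_file(self):
        text = "indicator,sex,index,L,M,S\nhfa,f,0,1,49,0.035\nhfa,f,1,1,53,0.036\n"
        refs = gr.load_reference(io.StringIO(text))
        assert set(refs) == {("hfa", "f")}
        assert len(refs[("hfa", "f")]) == 2

    def test_tab_delimited_autodetected(self):
        text = "indicator\tsex\tindex\tL\tM\tS\nhfa\tf\t0\t1\t49\t0.035\nhfa\tf\t1\t1\t53\t0.036\n"
        refs = gr.load_reference(io.StringIO(text))
        assert len(refs[("hfa", "f")]) == 2

    def test_duplicate_index_rejected(self):
        text = "indicator,sex,index,L,M,S\nhfa,f,1,1,49,0.035\nhfa,f,1,1,53,0.036\n"
        with pytest.raises(gr.ReferenceError, match="duplicate"):
            gr.load_reference(io.StringIO(text))

    def test_missing_column_rejected(self):
        text = "indicator,sex,index,L,M\nhfa,f,0,1,49\n"
        with pytest.raises(gr.ReferenceError, match="missing columns"):
            gr.load_reference(io.StringIO(text))

    def test_non_numeric_cell_names_line(self):
        text = "indicator,sex,index,L,M,S\nhfa,f,0,1,49,0.035\nhfa,f,one,1,53,0.036\n"
        with pytest.raises(gr.ReferenceError, match="line 3"):
            gr.load_reference(io.StringIO(text))

    def test_synthetic_reference_round_trips(self, refs, tmp_path):
        path = tmp_path / "reference.csv"
        gr.write_reference(refs, path)
        reloaded = gr.load_reference(path)
        assert set(reloaded) == set(refs)
        for key, ref in refs.items():
            np.testing.assert_allclose(reloaded[key].index, ref.index)
            np.testing.assert_allclose(reloaded[key].M, ref.M)
            np.testing.assert_allclose(reloaded[key].L, ref.L)
            np.testing.assert_allclose(reloaded[key].S, ref.S)


class TestChildScores:
    def test_child_at_reference_medians_scores_zero(self, refs):
        import pandas as pd

        age = 30.0
        height = refs[("hfa", "f")].lookup(age)[1]
        weight = refs[("wfh", "f")].lookup(height)[1]
        records = pd.DataFrame(
            {
                "age_months": [age],
                "sex": ["f"],
                "weight_kg": [weight],
                "height_cm": [height],
                "position": ["standing"],
            }
        )
        scores = gr.compute_child_scores(records, refs)
        assert scores.loc[0, "haz"] == pytest.approx(0.0, abs=1e-9)
        assert scores.loc[0, "whz"] == pytest.approx(0.0, abs=1e-9)
        # the weight-for-age median is composed from the other two tables,
        # so WAZ at the medians is zero up to grid-interpolation error
        assert scores.loc[0, "waz"] == pytest.approx(0.0, abs=1e-3)

    def test_position_conversion_shifts_height(self, refs):
        import pandas as pd

        base = dict(age_months=12.0, sex="f", weight_kg=9.0, height_cm=75.0)
        records = pd.DataFrame(
            [
                {**base, "position": "recumbent"},  # reference standard under 24 m
                {**base, "position": "standing"},  # measured standing: +0.7 cm
            ]
        )
        scores = gr.compute_child_scores(records, refs)
        assert scores.loc[1, "haz"] > scores.loc[0, "haz"]
        off = gr.compute_child_scores(records, refs, adjust_position=False)
        assert off.loc[1, "haz"] == pytest.approx(off.loc[0, "haz"])

    def test_missing_table_is_configuration_error(self, refs):
        import pandas as pd

        partial = {k: v for k, v in refs.items() if k != ("wfa", "m")}
        records = pd.DataFrame(
            {
                "age_months": [30.0],
                "sex": ["m"],
                "weight_kg": [12.0],
                "height_cm": [90.0],
                "position": ["standing"],
            }
        )
        with pytest.raises(gr.ReferenceError, match="wfa"):
            gr.compute_child_scores(records, partial)

    def test_out_of_reference_height_is_unavailable(self, refs):
        import pandas as pd

        records = pd.DataFrame(
            {
                "age_months": [30.0],
                "sex": ["f"],
                "weight_kg": [30.0],
                "height_cm": [140.0],  # above the weight-for-height grid
                "position": ["standing"],
            }
        )
        scores = gr.compute_child_scores(records, refs)
        assert np.isnan(scores.loc[0, "whz"])
        assert np.isfinite(scores.loc[0, "haz"])  # age is still on the hfa grid
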