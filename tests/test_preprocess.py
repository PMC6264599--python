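"""Background correction, normalization, summarization, yield scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from decayomics import (
    NormexpParams,
    ProbeMatrix,
    ValidationError,
    apply_yield,
    estimate_normexp_params,
    median_polish,
    normexp_signal,
    quantile_normalize,
    scale_between_conditions,
    select_invariant_probes,
    summarize_median,
    summarize_rma,
)
from decayomics.preprocess import quantile_normalize_values


def make_probes(values: np.ndarray, probes_per_transcript: int = 4, arrays=None):
    n = values.shape[0]
    assert n % probes_per_transcript == 0
    tids = np.repeat(
        [f"t{i:03d}" for i in range(n // probes_per_transcript)], probes_per_transcript
    )
    pids = [f"{t}_p{j}" for j, t in enumerate(tids)]
    cols = arrays or [f"a{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=pids, columns=cols)
    return ProbeMatrix(pd.Series(tids, index=vals.index, name="transcript_id"), vals)


class TestNormexp:
    def test_mode_of_pure_normal_is_the_mean(self, rng):
        p = estimate_normexp_params(rng.normal(100.0, 10.0, 100_000))
        assert 98.0 <= p.mu <= 102.0

    def test_alpha_recovers_exponential_mean(self, rng):
        x = rng.normal(100.0, 10.0, 100_000) + rng.exponential(500.0, 100_000)
        p = estimate_normexp_params(x)
        assert 450.0 <= p.alpha <= 550.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_normexp_params(np.full(500, 7.0))

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValidationError):
            estimate_normexp_params(rng.normal(size=50))

    def test_correction_matches_quadrature_oracle(self):
        # E[S | X = x] by numerical integration of the posterior
        mu, sigma, alpha = 100.0, 10.0, 100.0
        params = NormexpParams(mu, sigma, alpha)
        for x in (mu, mu + 30.0, mu - 15.0):
            def post(s):
                return np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma)

            num, _ = integrate.quad(lambda s: s * post(s), 0, np.inf)
            den, _ = integrate.quad(post, 0, np.inf)
            expected = num / den
            got = float(normexp_signal(np.array([x]), params)[0])
            assert got == pytest.approx(expected, rel=1e-4)

    def test_sigma_to_zero_limit_is_thresholding(self):
        x = np.array([50.0, 100.0, 150.0, 400.0])
        params = NormexpParams(mu=100.0, sigma=1e-6, alpha=1000.0)
        out = normexp_signal(x, params)
        np.testing.assert_allclose(out[2:], x[2:] - 100.0, rtol=1e-3)
        assert np.all(out > 0)

    def test_correction_monotone_in_raw_value(self, rng):
        params = NormexpParams(mu=80.0, sigma=12.0, alpha=300.0)
        x = np.sort(rng.uniform(0, 2000, 500))
        out = normexp_signal(x, params)
        assert np.all(np.diff(out) > 0)


class TestQuantileNormalize:
    def test_hand_computed_two_arrays(self):
        vals = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize_values(vals)
        expected = np.array([2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["a"], expected)
        np.testing.assert_allclose(out["b"], expected)

    def test_identical_arrays_unchanged(self, rng):
        col = rng.lognormal(size=50)
        vals = pd.DataFrame({"a": col, "b": col.copy()})
        out = quantile_normalize_values(vals)
        np.testing.assert_allclose(out["a"], col, rtol=1e-12)

    def test_sorted_vectors_identical_and_equal_mean(self, rng):
        vals = pd.DataFrame(rng.lognormal(size=(200, 5)))
        out = quantile_normalize_values(vals)
        ref = np.sort(vals.to_numpy(), axis=0).mean(axis=1)
        for c in out.columns:
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref, rtol=1e-12)

    def test_rank_order_preserved_within_array(self, rng):
        vals = pd.DataFrame(rng.lognormal(size=(100, 3)))
        out = quantile_normalize_values(vals)
        for c in out.columns:
            assert (
                np.argsort(out[c].to_numpy(), kind="stable")
                == np.argsort(vals[c].to_numpy(), kind="stable")
            ).all()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.lognormal(size=(40, 4)))
        once = quantile_normalize_values(vals)
        twice = quantile_normalize_values(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)

    def test_single_array_rejected(self):
        with pytest.raises(ValidationError):
            quantile_normalize_values(pd.DataFrame({"a": [1.0, 2.0]}))


class TestInvariantProbes:
    def test_planted_invariant_probes_fully_recovered(self, rng):
        # 400 noisy signal probes + 100 planted constant low-intensity probes
        n_sig, n_inv, n_arr = 400, 100, 9
        signal = rng.lognormal(mean=6.0, sigma=1.0, size=(n_sig, n_arr))
        planted = np.tile(np.linspace(1.0, 2.0, n_inv)[:, None], (1, n_arr))
        values = np.vstack([signal, planted])
        probes = make_probes(values, probes_per_transcript=4)
        planted_ids = probes.values.index[n_sig:]
        sel = select_invariant_probes(probes, probes.arrays)
        assert set(planted_ids) <= set(sel)
        recovery = len(set(planted_ids) & set(sel)) / n_inv
        assert recovery == 1.0

    def test_constant_rank_bottom_probe_selected_and_swapper_excluded(self):
        # probe 0: always the dimmest; probe 3: bottom in one array, top in another
        values = np.array(
            [
                [1.0, 1.0, 1.0],
                [10.0, 11.0, 12.0],
                [20.0, 21.0, 22.0],
                [2.0, 30.0, 2.0],
                [5.0, 5.0, 5.0],
                [40.0, 41.0, 42.0],
                [50.0, 51.0, 52.0],
                [60.0, 61.0, 62.0],
            ]
        )
        probes = make_probes(values, probes_per_transcript=4)
        sel = set(select_invariant_probes(probes, probes.arrays, 0.3, 0.05))
        ids = list(probes.values.index)
        assert ids[0] in sel
        assert ids[3] not in sel

    def test_empty_selection_raises_with_advice(self, rng):
        values = rng.permuted(
            np.tile(np.arange(1.0, 41.0)[:, None], (1, 4)), axis=0
        )  # independently shuffled ranks
        probes = make_probes(values, probes_per_transcript=4)
        with pytest.raises(ValidationError, match="relax"):
            select_invariant_probes(probes, probes.arrays, 0.05, 0.0)


class TestBetweenConditionScaling:
    def test_invariant_medians_equalized(self, rng):
        values = rng.lognormal(size=(80, 6))
        values[:, 3:] *= 2.0  # condition B twice as bright
        probes = make_probes(values, 4, arrays=[f"a{i}" for i in range(6)])
        inv = probes.values.index[:20]
        conditions = {"A": ["a0", "a1", "a2"], "B": ["a3", "a4", "a5"]}
        scaled, factors = scale_between_conditions(probes, inv, conditions)
        med = {
            c: np.median(scaled.values.loc[inv, arr].to_numpy())
            for c, arr in conditions.items()
        }
        assert med["A"] == pytest.approx(med["B"], rel=1e-12)

    def test_single_condition_is_identity(self, rng):
        values = rng.lognormal(size=(40, 3))
        probes = make_probes(values, 4)
        inv = probes.values.index[:10]
        scaled, factors = scale_between_conditions(
            probes, inv, {"A": probes.arrays}
        )
        assert factors["A"] == pytest.approx(1.0)
        np.testing.assert_allclose(scaled.values.to_numpy(), values, rtol=1e-12)

    def test_global_rescaling_cancels(self, rng):
        values = rng.lognormal(size=(40, 4))
        probes = make_probes(values, 4)
        inv = probes.values.index[:12]
        conditions = {"A": probes.arrays[:2], "B": probes.arrays[2:]}
        _, f1 = scale_between_conditions(probes, inv, conditions)
        probes2 = ProbeMatrix(probes.transcripts, probes.values * 37.5)
        _, f2 = scale_between_conditions(probes2, inv, conditions)
        for c in f1:
            assert f1[c] == pytest.approx(f2[c], rel=1e-12)


class TestMedianPolish:
    def test_single_probe_transcript_passthrough(self):
        vals = np.array([[4.0, 8.0, 16.0]])
        probes = ProbeMatrix(
            pd.Series(["t0"], index=["p0"]),
            pd.DataFrame(vals, index=["p0"], columns=["a", "b", "c"]),
        )
        out = summarize_rma(probes, ["a", "b", "c"])
        np.testing.assert_allclose(out.loc["t0"], np.log2(vals[0]), rtol=1e-12)

    def test_exactly_additive_matrix_recovered(self, rng):
        r = rng.normal(size=8)
        c = rng.normal(size=5)
        x = r[:, None] + c[None, :]
        overall, row, col, resid = median_polish(x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        fitted_cols = overall + col
        # column effects recovered up to an additive constant
        np.testing.assert_allclose(
            fitted_cols - fitted_cols.mean(), c - c.mean(), atol=1e-10
        )

    def test_matches_long_run_oracle(self, rng):
        x = rng.normal(size=(16, 12))
        # tol one order below the target so the geometric tail stays within 1e-6
        o1, r1, c1, _ = median_polish(x, tol=1e-7)
        o2, r2, c2, _ = median_polish(x, tol=0.0, max_iter=500)
        np.testing.assert_allclose(o1 + c1, o2 + c2, atol=1e-6)

    def test_residual_row_and_col_medians_below_tol(self, rng):
        x = rng.normal(size=(16, 12))
        _, _, _, resid = median_polish(x, tol=1e-9, max_iter=200)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6

    def test_nonpositive_intensity_rejected(self):
        probes = make_probes(np.array([[1.0, -2.0]] * 4), 4)
        with pytest.raises(ValidationError):
            summarize_rma(probes, probes.arrays)


class TestSummarizeMedian:
    def test_median_of_1_to_16_is_8_5(self):
        vals = np.arange(1.0, 17.0)[:, None]
        probes = make_probes(vals, probes_per_transcript=16)
        out = summarize_median(probes)
        assert out.iloc[0, 0] == pytest.approx(8.5)

    def test_constant_probes_give_constant(self):
        probes = make_probes(np.full((8, 3), 3.7), probes_per_transcript=8)
        np.testing.assert_allclose(summarize_median(probes).to_numpy(), 3.7)

    def test_matches_sort_oracle(self, rng):
        vals = rng.lognormal(size=(32, 5))
        probes = make_probes(vals, probes_per_transcript=16)
        out = summarize_median(probes)
        for g, (tid, grp) in enumerate(
            probes.values.groupby(probes.transcripts)
        ):
            arr = np.sort(grp.to_numpy(), axis=0)
            oracle = 0.5 * (arr[7] + arr[8])
            np.testing.assert_allclose(out.loc[tid].to_numpy(), oracle, rtol=1e-12)


class TestApplyYield:
    SHEET = pd.DataFrame(
        {
            "array_id": ["x1", "x2", "y1", "y2"],
            "strain": ["ctrl", "ctrl", "mut", "mut"],
            "replicate": [1, 2, 1, 2],
            "time_min": [0.0, 0.0, 0.0, 0.0],
            "role": ["T0", "T0", "T0", "T0"],
        }
    )

    def test_paper_yield_multiplication(self):
        expr = pd.DataFrame({"x1": [2.0], "x2": [2.0], "y1": [2.0], "y2": [2.0]}, index=["t0"])
        conc = apply_yield(expr, self.SHEET, {"ctrl": 1.0, "mut": 35.9})
        assert conc.per_array.loc["t0", "y1"] == pytest.approx(71.8)
        assert conc.mean.loc["t0", "ctrl"] == pytest.approx(2.0)  # yield 1 = identity

    def test_equal_intensity_ratio_equals_yield_ratio(self, rng):
        v = rng.lognormal(size=4)
        expr = pd.DataFrame([v], index=["t0"], columns=["x1", "x2", "y1", "y2"])
        conc = apply_yield(expr, self.SHEET, {"ctrl": 15.6, "mut": 35.9})
        ratio = conc.per_array.loc["t0", "y1"] / expr.loc["t0", "y1"]
        assert ratio == pytest.approx(35.9)

    def test_missing_yield_rejected(self):
        expr = pd.DataFrame({"x1": [1.0], "x2": [1.0], "y1": [1.0], "y2": [1.0]}, index=["t0"])
        with pytest.raises(ValidationError, match="mut"):
            apply_yield(expr, self.SHEET, {"ctrl": 15.6})
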