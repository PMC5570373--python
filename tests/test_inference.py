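import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinesim.inference import (FACTORS, CalibrationTarget, lhs_sample, prcc,
                                row_to_perturbation, transient_features)


class TestLhs:
    def test_exactly_one_sample_per_equal_probability_bin(self):
        n = 40
        design = lhs_sample(n, seed=5)
        for name, (lo, hi, integer) in FACTORS.items():
            if integer:
                continue
            u = (design[name].to_numpy() - lo) / (hi - lo)
            bins = np.floor(u * n).astype(int)
            assert sorted(bins) == list(range(n)), name

    def test_bounds_respected_for_all_factors(self):
        design = lhs_sample(100, seed=1)
        for name, (lo, hi, _) in FACTORS.items():
            assert design[name].min() >= lo
            assert design[name].max() <= hi

    def test_seed_reproducibility(self):
        a = lhs_sample(30, seed=42)
        b = lhs_sample(30, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = lhs_sample(30, seed=43)
        assert not a.equals(c)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(1, seed=0)

    def test_row_translates_to_valid_perturbation(self):
        design = lhs_sample(10, seed=2)
        for _, row in design.iterrows():
            p = row_to_perturbation(row)
            assert p.molecules_per_release >= 500
            assert all(0 <= v <= 1 for v in p.desens_inhibition.values())


def brute_force_prcc(X, Y):
    """Independent PRCC oracle: explicit rank regression residuals and
    Pearson correlation, computed with plain linear algebra."""
    from scipy.stats import pearsonr, rankdata
    n, k = X.shape
    out = np.empty(k)
    ry = rankdata(Y)
    rx = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    for j in range(k):
        Z = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        px = rx[:, j] - Z @ np.linalg.pinv(Z) @ rx[:, j]
        py = ry - Z @ np.linalg.pinv(Z) @ ry
        out[j] = pearsonr(px, py)[0]
    return out


class TestPrcc:
    def test_monotone_single_factor_dependence_detected(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(200, 4))
        Y = np.exp(3 * X[:, 1])          # depends only on factor 1, monotone
        res = prcc(X, Y)
        assert res.prcc.iloc[1, 0] > 0.99
        assert np.all(res.prcc.iloc[[0, 2, 3], 0].abs() < 0.2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(80, 5))
        Y = X[:, 0] - 2 * X[:, 3] + 0.3 * rng.standard_normal(80)
        res = prcc(X, Y)
        expected = brute_force_prcc(X, Y)
        assert np.allclose(res.prcc.to_numpy()[:, 0], expected, atol=1e-10)

    @given(st.integers(0, 1000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 1.0, size=(60, 3))
        Y = X[:, 0] + 0.5 * rng.standard_normal(60)
        base = prcc(X, Y).prcc.to_numpy()
        Xt = X.copy()
        Xt[:, 0] = np.log(X[:, 0])       # strictly monotone transform
        Yt = np.exp(Y)
        assert np.allclose(prcc(Xt, Yt).prcc.to_numpy(), base, atol=1e-12)

    def test_constant_output_flagged_not_computed(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(50, 3))
        Y = np.column_stack([X[:, 0], np.full(50, 7.0)])
        res = prcc(X, Y)
        assert res.constant_outputs == ["y1"]
        assert np.isnan(res.prcc.to_numpy()[:, 1]).all()

    def test_collinear_design_raises_naming_factors(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=50)
        X = np.column_stack([x, x, rng.uniform(size=50)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            prcc(X, x)

    def test_pvalues_in_unit_interval_and_small_for_strong_effects(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(100, 3))
        Y = 5 * X[:, 2] + 0.1 * rng.standard_normal(100)
        res = prcc(X, Y)
        pv = res.pvalue.to_numpy()[:, 0]
        assert np.all((pv >= 0) & (pv <= 1))
        assert pv[2] < 1e-6


class TestFeaturesAndTargets:
    def test_exponential_transient_features_recovered(self):
        t = np.linspace(0, 200, 4001)
        rest, amp, tau = 0.05, 1.2, 18.0
        trace = rest + amp * np.exp(-np.maximum(t - 10, 0) / tau)
        trace[t < 10] = rest
        a, tfit = transient_features(t, trace, rest)
        assert a == pytest.approx(amp, rel=1e-6)
        assert tfit == pytest.approx(tau, rel=0.02)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            CalibrationTarget(0.0, 10.0, 0.1, 20.0)

    def test_target_file_round_trip(self, tmp_path):
        from spinesim.io import load_target_file, write_target_file
        tgt = CalibrationTarget(0.9, 12.0, 0.2, 30.0)
        path = tmp_path / "target.yaml"
        write_target_file(tgt, path, seed=7)
        back = load_target_file(path)
        assert back == tgt
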