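"""Repeated-measures correlation and pooled lagged cross-correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbflux.correlation import (
    CrossCorrResult,
    attribute_lags,
    cross_correlation_per_patient,
    pool_cross_correlations,
    rmcorr,
)


def _paired(subjects, slope=1.0, noise=0.0, seed=0):
    """Per-subject x with its own offset, y = slope*x + offset + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (n, offset) in enumerate(subjects):
        x = rng.normal(size=n)
        y = slope * x + offset + noise * rng.normal(size=n)
        for xi, yi in zip(x, y):
            rows.append((f"S{i}", xi, yi))
    return pd.DataFrame(rows, columns=["subject_id", "x", "y"])


def _centering_oracle(df):
    """Subject-center x and y, then plain Pearson on the pooled residuals."""
    xc = df.groupby("subject_id")["x"].transform(lambda v: v - v.mean())
    yc = df.groupby("subject_id")["y"].transform(lambda v: v - v.mean())
    return float(np.corrcoef(xc, yc)[0, 1])


class TestRmcorr:
    def test_perfect_within_subject_line(self):
        df = _paired([(5, 0.0), (5, 10.0)], slope=1.0)
        res = rmcorr(df, "x", "y")
        assert res.rho == pytest.approx(1.0)

    def test_negative_slope_gives_minus_one(self):
        df = _paired([(5, 0.0), (5, 3.0)], slope=-2.0)
        res = rmcorr(df, "x", "y")
        assert res.rho == pytest.approx(-1.0)

    def test_matches_centering_oracle(self):
        df = _paired([(5, 0.0), (5, 2.0), (5, -3.0), (5, 7.0)], slope=0.8,
                     noise=0.5, seed=42)
        res = rmcorr(df, "x", "y")
        assert res.rho == pytest.approx(_centering_oracle(df), abs=1e-10)
        assert res.df == len(df) - 4 - 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = _paired([(6, 0.0), (6, 2.0), (7, -1.0)], slope=0.5, noise=1.0, seed=3)
        res = rmcorr(df, "x", "y")
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="subject_id")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_invariant_to_per_subject_offsets(self):
        df = _paired([(5, 0.0), (5, 0.0), (5, 0.0)], slope=0.7, noise=0.4, seed=9)
        res = rmcorr(df, "x", "y")
        shifted = df.copy()
        offsets = {"S0": 5.0, "S1": -30.0, "S2": 100.0}
        shifted["x"] = shifted["x"] + shifted["subject_id"].map(offsets)
        shifted["y"] = shifted["y"] + shifted["subject_id"].map(offsets).pow(2)
        res2 = rmcorr(shifted, "x", "y")
        assert res2.rho == pytest.approx(res.rho, abs=1e-10)

    def test_single_subject_reduces_to_pearson(self):
        df = _paired([(8, 0.0)], slope=0.6, noise=0.8, seed=1)
        res = rmcorr(df, "x", "y")
        r_pearson = float(np.corrcoef(df["x"], df["y"])[0, 1])
        assert res.rho == pytest.approx(r_pearson, abs=1e-10)
        assert res.df == len(df) - 2

    def test_ci_brackets_rho(self):
        df = _paired([(6, 0.0), (6, 1.0), (6, 2.0)], slope=0.5, noise=1.0, seed=5)
        res = rmcorr(df, "x", "y")
        assert -1 <= res.ci_low <= res.rho <= res.ci_high <= 1

    def test_constant_x_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["A"] * 3 + ["B"] * 3, "x": [1.0] * 6,
             "y": [1.0, 2.0, 3.0] * 2}
        )
        with pytest.raises(ValueError):
            rmcorr(df, "x", "y")


def _brute_force_ccf(x, y, max_lag, min_overlap):
    """Literal double-loop evaluation of the lagged correlation formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xo, yo = x[np.isfinite(x)], y[np.isfinite(y)]
    xbar, ybar = xo.mean(), yo.mean()
    sx, sy = xo.std(), yo.std()
    out = {}
    for lag in range(-max_lag, max_lag + 1):
        total, count = 0.0, 0
        for k in range(len(x)):
            j = k + lag
            if 0 <= j < len(y) and np.isfinite(x[k]) and np.isfinite(y[j]):
                total += (x[k] - xbar) * (y[j] - ybar)
                count += 1
        if count >= min_overlap:
            out[lag] = total / (count * sx * sy)
    return out


class TestCrossCorrelation:
    def test_identical_series_peak_at_zero(self, rng):
        x = rng.normal(size=12)
        r = cross_correlation_per_patient(x, x, max_lag=3, min_overlap=5)
        assert r.loc[0] == pytest.approx(1.0)
        assert (r.drop(0).dropna() < 1.0).all()

    def test_pure_delay_recovered(self, rng):
        x = rng.normal(size=14)
        y = np.r_[np.nan, x[:-1]]  # y follows x by one bin
        r = cross_correlation_per_patient(x, y, max_lag=3, min_overlap=5)
        assert r.idxmax() == 1

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        x[3] = np.nan
        r = cross_correlation_per_patient(x, y, max_lag=4, min_overlap=3)
        oracle = _brute_force_ccf(x, y, 4, 3)
        for lag, val in oracle.items():
            assert r.loc[lag] == pytest.approx(val, abs=1e-12)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_reversal_symmetry(self, data):
        n = data.draw(st.integers(8, 14))
        x = np.array(data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n)))
        if x.std() == 0 or y.std() == 0:
            return
        fwd = cross_correlation_per_patient(x, y, max_lag=3, min_overlap=4)
        rev = cross_correlation_per_patient(y, x, max_lag=3, min_overlap=4)
        for lag in fwd.index:
            a, b = fwd.loc[lag], rev.loc[-lag]
            if np.isfinite(a) and np.isfinite(b):
                assert a == pytest.approx(b, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation_per_patient(np.ones(10), np.arange(10.0), max_lag=2)

    def test_insufficient_overlap_rejected(self):
        x = np.r_[np.nan * np.ones(8), 1.0, 2.0]
        with pytest.raises(ValueError):
            cross_correlation_per_patient(x, np.arange(10.0), max_lag=2, min_overlap=5)


class TestPooling:
    def test_identical_patients_zero_width_ci(self, rng):
        x = rng.normal(size=12)
        table = cross_correlation_per_patient(x, np.r_[np.nan, x[:-1]], max_lag=3)
        pooled = pool_cross_correlations({"a": table, "b": table, "c": table})
        assert pooled.peak_lag == 1
        assert np.allclose(
            pooled.table["ci_high"] - pooled.table["ci_low"], 0.0, atol=1e-12
        )
        assert np.allclose(pooled.table["mean"], table.dropna())

    def test_requires_two_patients(self, rng):
        x = rng.normal(size=12)
        table = cross_correlation_per_patient(x, x, max_lag=2)
        with pytest.raises(ValueError):
            pool_cross_correlations({"a": table})

    def test_null_series_significance_near_nominal(self):
        """Independent series: ~5% of pooled lags flagged significant."""
        n_sig, n_lags = 0, 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            tables = {}
            for i in range(12):
                x = rng.normal(size=14)
                y = rng.normal(size=14)
                tables[f"p{i}"] = cross_correlation_per_patient(x, y, max_lag=4)
            pooled = pool_cross_correlations(tables, peak_se_factor=0.0)
            n_sig += len(pooled.significant_lags)
            n_lags += len(pooled.table)
        # binomial(180, 0.05): mean 9, 3 sigma ~ 8.8
        assert n_sig / n_lags < 0.11

    def test_parsimonious_peak_prefers_shortest_indistinguishable_lag(self):
        lags = pd.Index(range(-2, 3), name="lag")
        base = pd.Series([0.1, 0.2, 0.50, 0.505, 0.1], index=lags)
        tables = {f"p{i}": base + 0.05 * np.random.default_rng(i).normal(size=5)
                  for i in range(10)}
        pooled = pool_cross_correlations(tables, peak_se_factor=1.0)
        assert pooled.peak_lag == 0
        strict = pool_cross_correlations(tables, peak_se_factor=0.0)
        assert strict.peak_lag in (0, 1)


def _fake_ccf(peaks, sig=True, pair=("x", "y")):
    lags = pd.Index(range(-4, 5), name="lag")
    mean = pd.Series(0.1, index=lags)
    mean.loc[peaks] = 0.8
    half = 0.05 if sig else 1.0
    table = pd.DataFrame(
        {"mean": mean, "se": half / 2, "ci_low": mean - half, "ci_high": mean + half,
         "n_patients": 10}
    )
    return CrossCorrResult(pair=pair, table=table, per_patient=pd.DataFrame(),
                           peak_lag=int(peaks), significant_lags=tuple(
                               int(l) for l in lags if mean[l] - half > 0))


class TestAttribution:
    def test_barrier_mediated_pattern(self):
        verdict = attribute_lags(_fake_ccf(0), _fake_ccf(1), _fake_ccf(1))
        assert verdict == "bbb_mediated"

    def test_non_barrier_pattern(self):
        verdict = attribute_lags(_fake_ccf(-1), _fake_ccf(0), _fake_ccf(2))
        assert verdict == "not_bbb_mediated"

    def test_all_nonsignificant_is_indeterminate(self):
        verdict = attribute_lags(
            _fake_ccf(0, sig=False), _fake_ccf(1, sig=False), _fake_ccf(1, sig=False)
        )
        assert verdict == "indeterminate"

    def test_insignificant_link_blocks_attribution(self):
        verdict = attribute_lags(_fake_ccf(0), _fake_ccf(1, sig=False), _fake_ccf(1))
        assert verdict == "not_bbb_mediated"
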