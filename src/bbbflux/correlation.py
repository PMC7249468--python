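"""Repeated-measures ("momentary") correlation and pooled cross-correlation.

Two complementary views of how longitudinal series co-move:

* :func:`rmcorr` -- the within-subject (repeated-measures) correlation: the
  common-slope ANCOVA decomposition in which each subject contributes its own
  intercept and a shared slope measures the momentary association.
* :func:`cross_correlation_per_patient` / :func:`pool_cross_correlations` --
  per-patient lagged cross-correlation of 12-h binned series, pooled across
  patients with a t-interval per lag; the peak lag localizes the transport
  delay between compartments.
* :func:`attribute_lags` -- decides whether the CSF-to-blood delay of a
  biomarker is explained by the identically lagged relationship between
  barrier disruption (Q_A) and the blood level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RmcorrResult",
    "rmcorr",
    "CrossCorrResult",
    "cross_correlation_per_patient",
    "pool_cross_correlations",
    "attribute_lags",
]


@dataclass(frozen=True)
class RmcorrResult:
    """Within-subject correlation with Fisher-z confidence interval."""

    rho: float
    ci_low: float
    ci_high: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


def rmcorr(data: pd.DataFrame, x: str, y: str, subject: str = "subject_id") -> RmcorrResult:
    """Repeated-measures correlation of ``x`` and ``y``.

    Fits the analysis-of-covariance model ``y ~ subject + x`` (per-subject
    intercepts, one common slope) and returns
    ``rho = sign(slope) * sqrt(SS_x / (SS_x + SS_error))`` with
    ``df = n_obs - n_subjects - 1``; the p-value is the F test on the common
    slope, and the CI is Fisher-z with standard error ``1/sqrt(df - 1)``.

    Complete pairs only; subjects need >= 2 pairs and ``x`` must vary within
    subjects.  With a single subject the statistic reduces to the ordinary
    Pearson correlation with ``n - 2`` degrees of freedom.
    """
    d = data[[subject, x, y]].dropna()
    counts = d.groupby(subject).size()
    d = d[d[subject].isin(counts[counts >= 2].index)]
    k = d[subject].nunique()
    n = len(d)
    if k < 1:
        raise ValueError("rmcorr needs at least 1 subject with >= 2 complete pairs")
    df = n - k - 1
    if df <= 0:
        raise ValueError(f"non-positive error degrees of freedom ({df})")

    # ANCOVA via dummy-coded least squares (distinct numerical path from the
    # subject-centering identity used as an oracle in the tests)
    xv = d[x].to_numpy(dtype=float)
    yv = d[y].to_numpy(dtype=float)
    dummies = pd.get_dummies(d[subject], dtype=float).to_numpy()
    X_full = np.column_stack([dummies, xv])
    beta, _, rank, _ = np.linalg.lstsq(X_full, yv, rcond=None)
    if rank < X_full.shape[1]:
        raise ValueError("x has no within-subject variation (singular ANCOVA design)")
    resid_full = yv - X_full @ beta
    ss_error = float(resid_full @ resid_full)
    beta0, *_ = np.linalg.lstsq(dummies, yv, rcond=None)
    resid_red = yv - dummies @ beta0
    ss_measure = float(resid_red @ resid_red) - ss_error
    ss_measure = max(ss_measure, 0.0)
    slope = float(beta[-1])

    denom = ss_measure + ss_error
    if denom <= 0:
        raise ValueError("zero within-subject variation in y")
    rho = float(np.sign(slope) * np.sqrt(ss_measure / denom))
    f_stat = ss_measure / (ss_error / df) if ss_error > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df)) if np.isfinite(f_stat) else 0.0
    if df - 1 <= 0:
        raise ValueError("too few observations for a Fisher-z interval")
    se = 1.0 / np.sqrt(df - 1)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    zc = stats.norm.ppf(0.975)
    ci_low, ci_high = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return RmcorrResult(
        rho=rho,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        df=df,
        p=p,
        n_subjects=k,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# lagged cross-correlation


def cross_correlation_per_patient(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    max_lag: int = 4,
    min_overlap: int = 5,
) -> pd.Series:
    """Cross-correlation of one patient's binned series over integer lags.

    ``x`` and ``y`` are aligned per-bin values (NaN = empty bin).  The value
    at lag ``l`` (positive ``l``: y follows x) is

    ``r(l) = sum_k (x_k - xbar)(y_{k+l} - ybar) / (N * s_x * s_y)``

    with means and standard deviations taken over each full series
    (population SD) and ``N`` the number of valid pairs in the common span.
    Lags with fewer than ``min_overlap`` pairs are NaN.  Raises for a
    zero-variance series or if fewer than ``min_overlap`` pairs exist at
    lag 0.
    """
    xv = np.asarray(pd.Series(x), dtype=float)
    yv = np.asarray(pd.Series(y), dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y must be aligned to the same bins")
    x_ok, y_ok = np.isfinite(xv), np.isfinite(yv)
    if x_ok.sum() < 2 or y_ok.sum() < 2:
        raise ValueError("too few non-missing bins")
    xbar, ybar = xv[x_ok].mean(), yv[y_ok].mean()
    sx, sy = xv[x_ok].std(ddof=0), yv[y_ok].std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance series; cross-correlation undefined")
    if int((x_ok & y_ok).sum()) < min_overlap:
        raise ValueError(
            f"fewer than min_overlap={min_overlap} paired bins at lag 0"
        )
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full(len(lags), np.nan)
    n = len(xv)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = xv[: n - lag], yv[lag:]
            ok = x_ok[: n - lag] & y_ok[lag:]
        else:
            xs, ys = xv[-lag:], yv[: n + lag]
            ok = x_ok[-lag:] & y_ok[: n + lag]
        m = int(ok.sum())
        if m < min_overlap:
            continue
        out[i] = float(
            np.sum((xs[ok] - xbar) * (ys[ok] - ybar)) / (m * sx * sy)
        )
    return pd.Series(out, index=pd.Index(lags, name="lag"), name="r")


@dataclass
class CrossCorrResult:
    """Pooled cross-correlation for an ordered series pair (x leads y)."""

    pair: tuple[str, str]
    table: pd.DataFrame  # index lag; columns mean, ci_low, ci_high, n_patients
    per_patient: pd.DataFrame  # index lag, columns per subject
    peak_lag: int
    significant_lags: tuple = ()

    @property
    def peak_significant(self) -> bool:
        return self.peak_lag in self.significant_lags


def pool_cross_correlations(
    per_patient: dict[str, pd.Series] | pd.DataFrame,
    pair: tuple[str, str] = ("x", "y"),
    conf_level: float = 0.95,
    peak_se_factor: float = 1.0,
) -> CrossCorrResult:
    """Pool per-patient lag tables: mean, t-interval, peak-lag attribution.

    Per lag, patients contributing a finite correlation are averaged and a
    ``mean +- t_{1-a/2, m-1} * sd/sqrt(m)`` interval is attached (m =
    contributing patients; lags with m < 2 are dropped).  A lag is
    significant when its CI excludes zero.

    The peak lag is chosen parsimoniously (the one-standard-error rule
    familiar from model selection): among lags whose pooled mean lies within
    ``peak_se_factor`` standard errors of the maximum -- i.e. statistically
    indistinguishable from it -- the shortest delay wins (smallest ``|lag|``,
    then the positive, causal side).  Set ``peak_se_factor=0`` for the plain
    argmax.
    """
    pp = pd.DataFrame(per_patient)
    if pp.shape[1] < 1:
        raise ValueError("no per-patient tables supplied")
    rows = []
    for lag, vals in pp.iterrows():
        v = vals.dropna().to_numpy(dtype=float)
        m = len(v)
        if m < 2:
            continue
        mean = v.mean()
        sd = v.std(ddof=1)
        se = sd / np.sqrt(m)
        tq = stats.t.ppf(0.5 + conf_level / 2, m - 1)
        half = tq * se
        rows.append(
            {"lag": int(lag), "mean": mean, "se": se,
             "ci_low": mean - half, "ci_high": mean + half, "n_patients": m}
        )
    if not rows:
        raise ValueError("no lag has >= 2 contributing patients")
    table = pd.DataFrame(rows).set_index("lag").sort_index()
    best = table["mean"].max()
    se_at_best = float(table.loc[table["mean"].idxmax(), "se"])
    threshold = best - peak_se_factor * se_at_best - 1e-12
    contenders = table.index[table["mean"] >= threshold]
    peak = sorted(contenders, key=lambda l: (abs(l), l < 0))[0]
    sig = tuple(
        int(l) for l, r in table.iterrows() if r["ci_low"] > 0 or r["ci_high"] < 0
    )
    return CrossCorrResult(
        pair=pair, table=table, per_patient=pp, peak_lag=int(peak), significant_lags=sig
    )


def attribute_lags(
    ccf_csf_qa: CrossCorrResult,
    ccf_qa_blood: CrossCorrResult,
    ccf_csf_blood: CrossCorrResult,
) -> str:
    """Attribute the CSF-to-blood delay to the barrier, or not.

    The causal chain CSF -> barrier leakage -> blood predicts that the
    CSF:blood peak lag decomposes into the delay from CSF to barrier
    disruption (non-negative part of the CSF:Q_A peak) plus the delay from
    barrier disruption to blood.  Verdicts:

    * ``"bbb_mediated"`` -- both barrier links (CSF:Q_A and Q_A:blood) are
      significant at their peaks and the decomposition matches the observed
      CSF:blood peak lag;
    * ``"not_bbb_mediated"`` -- the CSF:blood delay is real but the barrier
      chain cannot account for it: either a link is not significant, or the
      observed lag exceeds what the chain explains;
    * ``"indeterminate"`` -- the CSF:blood peak is not significant, or the
      observed lag falls short of the chain (no coherent ordering).
    """
    if not ccf_csf_blood.peak_significant:
        return "indeterminate"
    l_cq = ccf_csf_qa.peak_lag
    l_qb = ccf_qa_blood.peak_lag
    l_cb = ccf_csf_blood.peak_lag
    explained = max(l_cq, 0) + l_qb
    links_significant = ccf_csf_qa.peak_significant and ccf_qa_blood.peak_significant
    if links_significant and l_cb == explained:
        return "bbb_mediated"
    if l_cb > explained or not links_significant:
        return "not_bbb_mediated"
    return "indeterminate"
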