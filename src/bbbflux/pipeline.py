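"""End-to-end orchestration: simulate/ingest -> align -> correlate -> model -> report.

A run branches the ingested long table in two: the modelling path
(interpolate to a 6-h grid, derive Q_A, log10, complete cases, fit the
clearance models) and the cross-correlation path (12-h lag bins on the
original scale).  Blood S100B models exclude the first 12 h, where
extracranial release can contaminate the signal.  Every run writes a
manifest (config hash, seeds, per-stage row counts, warnings) sufficient to
re-execute the deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    add_albumin_quotient,
    bin_to_lags,
    complete_cases,
    exclude_early_window,
    interpolate_to_grid,
)
from .correlation import (
    CrossCorrResult,
    attribute_lags,
    cross_correlation_per_patient,
    pool_cross_correlations,
    rmcorr,
)
from .data_model import read_long_table
from .models import (
    fit_linear_mixed,
    make_clearance_design,
    satterthwaite_df,
    select_arma_by_aic,
)
from .synthetic import make_study_like_cohort

__all__ = ["RunConfig", "RunResult", "run_pipeline", "report", "qa_observation_frame", "ccf_pair"]


@dataclass(frozen=True)
class RunConfig:
    """Parameterization of one pipeline run."""

    profile: str | None = "s100b_like"  # simulation profile, or None to read inputs
    measurements_path: str | None = None
    demographics_path: str | None = None
    n_subjects: int = 16
    seed: int = 1
    grid_spacing_h: float = 6.0
    max_lag: int = 4
    min_overlap: int = 5
    arma_grid: tuple = ((0, 0), (1, 0), (0, 1), (1, 1))
    time_scale_h: float = 24.0
    estimation: str = "reml"
    exclude_first_h: float = 12.0  # applied to S100B-family model fits
    outdir: str = "run_output"
    make_figures: bool = True

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    manifest: dict
    momentary: dict
    cross_correlations: dict[str, CrossCorrResult]
    verdict: str
    model_fit: object
    model_table: pd.DataFrame
    aic_table: pd.DataFrame
    outdir: Path


def qa_observation_frame(measurements: pd.DataFrame) -> pd.DataFrame:
    """Derive per-time Q_A pseudo-observations from paired albumin rows."""
    alb = measurements[measurements["analyte"].isin(["ALB_CSF", "ALB_BLOOD"])]
    wide = alb.pivot_table(
        index=["subject_id", "time_h"], columns="analyte", values="value"
    ).dropna()
    qa = ((wide["ALB_CSF"] / 1000.0) / wide["ALB_BLOOD"]).reset_index()
    qa.columns = ["subject_id", "time_h", "value"]
    qa["analyte"] = "QA"
    qa["unit"] = ""
    return qa[["subject_id", "analyte", "time_h", "value", "unit"]]


def ccf_pair(
    lag_table: pd.DataFrame,
    x: str,
    y: str,
    max_lag: int = 4,
    min_overlap: int = 5,
) -> CrossCorrResult:
    """Per-patient cross-correlation of two binned analytes, pooled.

    Patients whose series are degenerate (zero variance, too few overlapping
    bins) are skipped rather than aborting the pooled analysis.
    """
    per_patient: dict[str, pd.Series] = {}
    for sid, sub in lag_table.groupby("subject_id"):
        sub = sub.set_index("lag_bin").sort_index()
        if x not in sub.columns or y not in sub.columns:
            continue
        try:
            per_patient[sid] = cross_correlation_per_patient(
                sub[x], sub[y], max_lag=max_lag, min_overlap=min_overlap
            )
        except ValueError:
            continue
    if len(per_patient) < 2:
        raise ValueError(f"fewer than 2 patients usable for pair {x}:{y}")
    return pool_cross_correlations(per_patient, pair=(x, y))


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write tables, figures and the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    counts: dict[str, int] = {}

    # -- ingest -------------------------------------------------------------
    if config.profile is not None:
        measurements, demographics, truth = make_study_like_cohort(
            config.profile, n=config.n_subjects, seed=config.seed
        )
    else:
        if config.measurements_path is None:
            raise ValueError("either a simulation profile or input paths are required")
        measurements, rejected = read_long_table(config.measurements_path)
        if len(rejected):
            warnings_log.append(f"{len(rejected)} input rows rejected")
        demographics = (
            pd.read_csv(config.demographics_path)
            if config.demographics_path
            else pd.DataFrame()
        )
    counts["measurements"] = len(measurements)
    analytes = set(measurements["analyte"])
    csf_a = next(a for a in ("S100B_CSF", "NSE_CSF") if a in analytes)
    blood_a = csf_a.replace("_CSF", "_BLOOD")
    if blood_a not in analytes or "ALB_CSF" not in analytes or "ALB_BLOOD" not in analytes:
        raise ValueError(f"inputs lack required analytes for {csf_a} analysis")

    # -- align (model path) -------------------------------------------------
    grid = interpolate_to_grid(measurements, config.grid_spacing_h)
    grid = add_albumin_quotient(grid)
    counts["grid_rows"] = len(grid.values)
    if csf_a == "S100B_CSF" and config.exclude_first_h > 0:
        grid_model = exclude_early_window(grid, cutoff_h=config.exclude_first_h)
    else:
        grid_model = grid
    grid_cc, cc_report = complete_cases(grid_model, [csf_a, blood_a, "QA"])
    counts["model_rows_retained"] = cc_report["retained"]
    counts["model_rows_dropped"] = cc_report["dropped"]

    # -- momentary correlations on the log10 scale --------------------------
    logs = grid_cc.values.copy()
    for col in (csf_a, blood_a, "QA"):
        logs[col] = np.log10(logs[col])
    momentary = {
        f"{csf_a}:{blood_a}": rmcorr(logs, csf_a, blood_a),
        f"QA:{blood_a}": rmcorr(logs, "QA", blood_a),
    }

    # -- cross-correlations on the original scale ---------------------------
    with_qa = pd.concat([measurements, qa_observation_frame(measurements)], ignore_index=True)
    lag_table = bin_to_lags(with_qa)
    counts["lag_rows"] = len(lag_table)
    ccfs = {
        "csf_qa": ccf_pair(lag_table, csf_a, "QA", config.max_lag, config.min_overlap),
        "qa_blood": ccf_pair(lag_table, "QA", blood_a, config.max_lag, config.min_overlap),
        "csf_blood": ccf_pair(lag_table, csf_a, blood_a, config.max_lag, config.min_overlap),
    }
    verdict = attribute_lags(ccfs["csf_qa"], ccfs["qa_blood"], ccfs["csf_blood"])

    # -- clearance model ----------------------------------------------------
    design = make_clearance_design(
        grid_cc.values, response=blood_a, csf=csf_a, qa="QA",
        time_scale_h=config.time_scale_h,
    )
    gls_fit, aic_table = select_arma_by_aic(
        design["y"], design["X"], design["groups"],
        candidates=config.arma_grid, estimation=config.estimation,
        terms=design["terms"], response=blood_a,
    )
    order = (gls_fit.arma.p, gls_fit.arma.q)
    try:
        lmm_fit = fit_linear_mixed(
            design["y"], design["X"], design["groups"], design["z_slope"],
            order=order, terms=design["terms"], response=blood_a,
            estimation=config.estimation,
        )
    except Exception as exc:  # mixed fit may fail outright on small cohorts
        warnings_log.append(f"mixed model failed ({exc}); using marginal model")
        lmm_fit = None
    if lmm_fit is not None and not lmm_fit.boundary_psi:
        final = lmm_fit
    else:
        if lmm_fit is not None and lmm_fit.boundary_psi:
            warnings_log.append(
                "mixed-model random-effect covariance on boundary; marginal model used"
            )
        final = gls_fit
    rows = []
    for term in final.terms:
        df_s, p_s, fb = satterthwaite_df(final, term)
        est = final.params.loc[term]
        rows.append(
            {
                "term": term,
                "estimate": est["estimate"],
                "se": est["se"],
                "satterthwaite_df": df_s,
                "p": p_s,
                "df_fallback": fb,
            }
        )
    model_table = pd.DataFrame(rows).set_index("term")

    # -- write artifacts ----------------------------------------------------
    for name, res in ccfs.items():
        res.table.to_csv(outdir / f"ccf_{name}.csv")
    model_table.to_csv(outdir / "model_table.csv")
    aic_table.to_csv(outdir / "aic_table.csv", index=False)
    momentary_json = {
        k: dataclasses.asdict(v) for k, v in momentary.items()
    }
    (outdir / "momentary.json").write_text(json.dumps(momentary_json, indent=1))
    results_json = {
        "verdict": verdict,
        "peak_lags": {k: v.peak_lag for k, v in ccfs.items()},
        "significant_lags": {k: list(v.significant_lags) for k, v in ccfs.items()},
        "final_model": final.kind,
        "arma": {"p": final.arma.p, "q": final.arma.q,
                 "phi": list(final.arma.phi), "theta": list(final.arma.theta)},
        "aic": final.aic,
    }
    (outdir / "results.json").write_text(json.dumps(results_json, indent=1))
    if config.make_figures:
        from .plots import fitted_observed_plot, lag_panel

        lag_panel(list(ccfs.values()), outdir / "lag_panels.svg")
        fitted_observed_plot(final, outdir / "fitted_observed.png")

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "version": __version__,
        "seed": config.seed,
        "row_counts": counts,
        "warnings": warnings_log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    result = RunResult(
        config=config,
        manifest=manifest,
        momentary=momentary,
        cross_correlations=ccfs,
        verdict=verdict,
        model_fit=final,
        model_table=model_table,
        aic_table=aic_table,
        outdir=outdir,
    )
    (outdir / "report.md").write_text(report(result))
    return result


def report(result: RunResult | None) -> str:
    """Human-readable markdown summary of a completed run."""
    if result is None:
        return "# Clearance analysis report\n\nNo analytes were analysed.\n"
    lines = ["# Clearance analysis report", ""]
    lines.append(f"Run `{result.manifest['config_hash']}` (seed {result.config.seed}), "
                 f"bbbflux {result.manifest['version']}.")
    lines.append("")
    lines.append("## Momentary (repeated-measures) correlations")
    for pair, rm in result.momentary.items():
        lines.append(
            f"- {pair}: rho = {rm.rho:.3f} (95% CI {rm.ci_low:.3f} to {rm.ci_high:.3f}, "
            f"p = {rm.p:.2g}, {rm.n_obs} obs / {rm.n_subjects} subjects)"
        )
    lines.append("")
    lines.append("## Cross-correlations (12-h lags, original scale)")
    for name, res in result.cross_correlations.items():
        lines.append(f"- {res.pair[0]} leads {res.pair[1]}: peak lag {res.peak_lag}, "
                     f"significant lags {sorted(res.significant_lags)}")
    lines.append(f"- lag attribution verdict: **{result.verdict}**")
    lines.append("")
    fit = result.model_fit
    lines.append(f"## Clearance model ({fit.kind}, ARMA({fit.arma.p},{fit.arma.q}), "
                 f"AIC {fit.aic:.1f})")
    retained = []
    for term, row in result.model_table.iterrows():
        sig = row["p"] <= 0.05
        if sig and term != "intercept":
            retained.append(term)
        lines.append(
            f"- {term}: {row['estimate']:.4g} (SE {row['se']:.3g}, "
            f"Satterthwaite df {row['satterthwaite_df']:.1f}, p = {row['p']:.3g})"
        )
    lines.append("")
    lines.append(f"Retained terms at the 0.05 level: {', '.join(retained) if retained else 'none'}.")
    lines.append("")
    lines.append("## AIC trail")
    lines.append(result.aic_table.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
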