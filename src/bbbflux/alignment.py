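"""Data preparation: gridding, transforms, filtering and lag binning.

Multi-rate longitudinal series (biomarkers every 6-12 h, albumin every
12-24 h) are merged onto a common within-subject grid by linear
interpolation, with strict no-extrapolation semantics and per-cell
provenance.  Downstream branches then diverge: the modelling path applies a
log10 transform and complete-case filtering, while the cross-correlation
path bins the *untransformed* measurements into half-open 12-h lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlignedGrid",
    "interpolate_to_grid",
    "add_albumin_quotient",
    "complete_cases",
    "log10_transform",
    "exclude_early_window",
    "bin_to_lags",
    "LAG_WIDTH_H",
]

#: half-open lag bin width in hours (0.5 days)
LAG_WIDTH_H = 12.0

OBSERVED = "observed"
INTERPOLATED = "interpolated"
MISSING = "missing"


@dataclass
class AlignedGrid:
    """Per-subject regular time grid with interpolated analyte values.

    ``values`` is a tidy frame with columns ``subject_id, time_h`` and one
    column per analyte (NaN where missing); ``provenance`` mirrors it with
    string flags ``observed | interpolated | missing`` per cell.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    spacing_h: float

    @property
    def analytes(self) -> list[str]:
        return [c for c in self.values.columns if c not in ("subject_id", "time_h")]

    def copy(self) -> "AlignedGrid":
        return AlignedGrid(self.values.copy(), self.provenance.copy(), self.spacing_h)


def interpolate_to_grid(measurements: pd.DataFrame, grid_spacing_h: float = 6.0) -> AlignedGrid:
    """Linearly interpolate each subject's analyte series onto a regular grid.

    Grid times coincide with an observation return the observed value
    (flagged ``observed``); times strictly inside the observed span are
    linear interpolants (``interpolated``); times outside any analyte's
    observed span are NaN (``missing``) -- never extrapolated.  Duplicate
    (subject, analyte, time) rows with differing values are an error;
    upstream code must aggregate them first.
    """
    if grid_spacing_h <= 0:
        raise ValueError("grid_spacing_h must be positive")
    dup = measurements.duplicated(subset=["subject_id", "analyte", "time_h"], keep=False)
    if dup.any():
        conflicting = (
            measurements[dup]
            .groupby(["subject_id", "analyte", "time_h"])["value"]
            .nunique()
        )
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index[0]
            raise ValueError(
                f"duplicate measurements with differing values at {bad}; aggregate upstream"
            )
        measurements = measurements.drop_duplicates(subset=["subject_id", "analyte", "time_h"])

    analytes = sorted(measurements["analyte"].unique())
    value_rows, prov_rows = [], []
    for sid, sub in measurements.groupby("subject_id", sort=True):
        t_max = sub["time_h"].max()
        n_pts = int(np.floor(t_max / grid_spacing_h + 1e-9)) + 1
        grid = np.arange(n_pts) * grid_spacing_h
        vals = {a: np.full(n_pts, np.nan) for a in analytes}
        prov = {a: np.full(n_pts, MISSING, dtype=object) for a in analytes}
        for a, ser in sub.groupby("analyte"):
            ser = ser.sort_values("time_h")
            t_obs = ser["time_h"].to_numpy(dtype=float)
            v_obs = ser["value"].to_numpy(dtype=float)
            inside = (grid >= t_obs[0] - 1e-9) & (grid <= t_obs[-1] + 1e-9)
            if len(t_obs) == 1:
                on = np.isclose(grid, t_obs[0], atol=1e-9)
                vals[a][on] = v_obs[0]
                prov[a][on] = OBSERVED
                continue
            vals[a][inside] = np.interp(grid[inside], t_obs, v_obs)
            on_obs = inside & np.isclose(
                grid[:, None], t_obs[None, :], atol=1e-9
            ).any(axis=1)
            prov[a][inside] = INTERPOLATED
            prov[a][on_obs] = OBSERVED
            # exact value at observed points (guards against fp drift)
            for t0, v0 in zip(t_obs, v_obs):
                hit = np.isclose(grid, t0, atol=1e-9)
                vals[a][hit] = v0
        base = {"subject_id": sid, "time_h": grid}
        value_rows.append(pd.DataFrame({**base, **vals}))
        prov_rows.append(pd.DataFrame({**base, **prov}))
    values = pd.concat(value_rows, ignore_index=True)
    provenance = pd.concat(prov_rows, ignore_index=True)
    return AlignedGrid(values=values, provenance=provenance, spacing_h=float(grid_spacing_h))


def add_albumin_quotient(grid: AlignedGrid, name: str = "QA") -> AlignedGrid:
    """Derive the albumin quotient column from gridded albumin values.

    ``QA = (ALB_CSF / 1000) / ALB_BLOOD``; the cell is missing wherever
    either albumin value is, and its provenance is ``interpolated`` unless
    both inputs were directly observed.
    """
    out = grid.copy()
    if "ALB_CSF" not in out.values.columns or "ALB_BLOOD" not in out.values.columns:
        raise ValueError("grid lacks ALB_CSF / ALB_BLOOD columns")
    csf = out.values["ALB_CSF"]
    blood = out.values["ALB_BLOOD"]
    out.values[name] = (csf / 1000.0) / blood
    both_obs = (out.provenance["ALB_CSF"] == OBSERVED) & (
        out.provenance["ALB_BLOOD"] == OBSERVED
    )
    prov = np.where(out.values[name].isna(), MISSING, np.where(both_obs, OBSERVED, INTERPOLATED))
    out.provenance[name] = prov
    return out


def complete_cases(
    grid: AlignedGrid, required_analytes: list[str]
) -> tuple[AlignedGrid, dict[str, int]]:
    """Keep grid rows where every required analyte is non-missing.

    Returns the filtered grid and a ``{"retained": ..., "dropped": ...}``
    report.  Degenerates to the identity when nothing is missing.
    """
    missing_cols = [a for a in required_analytes if a not in grid.values.columns]
    if missing_cols:
        raise ValueError(f"required analytes absent from grid: {missing_cols}")
    mask = grid.values[required_analytes].notna().all(axis=1)
    report = {"retained": int(mask.sum()), "dropped": int((~mask).sum())}
    out = AlignedGrid(
        grid.values[mask].reset_index(drop=True),
        grid.provenance[mask].reset_index(drop=True),
        grid.spacing_h,
    )
    return out, report


def log10_transform(grid: AlignedGrid, analytes: list[str]) -> AlignedGrid:
    """Elementwise log10 of the given analyte columns (provenance preserved).

    Raises, identifying subject/analyte/time, if any value to transform is
    non-positive.
    """
    out = grid.copy()
    for a in analytes:
        col = out.values[a]
        bad = col.notna() & (col <= 0)
        if bad.any():
            row = out.values[bad].iloc[0]
            raise ValueError(
                f"non-positive value for {a} at subject {row['subject_id']} "
                f"t={row['time_h']} h; cannot log10-transform"
            )
        out.values[a] = np.log10(col)
    return out


def exclude_early_window(
    grid: AlignedGrid, analyte: str | None = None, cutoff_h: float = 12.0
) -> AlignedGrid:
    """Drop grid rows earlier than ``cutoff_h`` (half-open: t == cutoff stays).

    Used to remove the extracranial contamination window from model fitting
    of blood S100B; with ``analyte`` given, only that analyte's cells are
    blanked, otherwise whole rows are dropped.  Idempotent.
    """
    out = grid.copy()
    early = out.values["time_h"] < cutoff_h
    if analyte is None:
        return AlignedGrid(
            out.values[~early].reset_index(drop=True),
            out.provenance[~early].reset_index(drop=True),
            out.spacing_h,
        )
    out.values.loc[early, analyte] = np.nan
    out.provenance.loc[early, analyte] = MISSING
    return out


def bin_to_lags(measurements: pd.DataFrame, bin_width_h: float = LAG_WIDTH_H) -> pd.DataFrame:
    """Average raw measurements into half-open 12-h lag bins, original scale.

    Bin ``k`` covers ``[k*width, (k+1)*width)`` hours, so an observation at
    exactly 12 h belongs to bin 1.  Returns a tidy frame with columns
    ``subject_id, lag_bin`` and one column per analyte; bins with no
    observation are NaN.  Empty input yields an empty frame.
    """
    if len(measurements) == 0:
        return pd.DataFrame(columns=["subject_id", "lag_bin"])
    df = measurements.copy()
    df["lag_bin"] = np.floor(df["time_h"] / bin_width_h + 1e-9).astype(int)
    wide = (
        df.groupby(["subject_id", "lag_bin", "analyte"])["value"]
        .mean()
        .unstack("analyte")
    )
    # dense bin index per subject so later lag shifts are well defined
    full = []
    for sid, sub in wide.groupby(level="subject_id"):
        bins = sub.index.get_level_values("lag_bin")
        idx = pd.MultiIndex.from_product(
            [[sid], range(int(bins.min()), int(bins.max()) + 1)],
            names=["subject_id", "lag_bin"],
        )
        full.append(sub.reindex(idx))
    out = pd.concat(full).reset_index()
    out.columns.name = None
    return out
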