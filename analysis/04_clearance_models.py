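"""Inferential clearance models of blood biomarker level.

Aligns each simulated cohort onto a 6-h grid, derives the albumin quotient,
log10-transforms, selects the within-patient ARMA structure by AIC, fits the
marginal GLS and the random-intercept+slope mixed model, and reports
Satterthwaite-based p-values for time, time^2, CSF level and Q_A.  The first
12 h are excluded for the S100B-family model (extracranial window).
Writes model tables under ``results/``.
"""

from pathlib import Path

import pandas as pd

from bbbflux.alignment import (
    add_albumin_quotient,
    complete_cases,
    exclude_early_window,
    interpolate_to_grid,
)
from bbbflux.data_model import read_long_table
from bbbflux.models import (
    fit_linear_mixed,
    make_clearance_design,
    satterthwaite_df,
    select_arma_by_aic,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
ARMA_GRID = ((0, 0), (1, 0), (0, 1), (1, 1))


def main() -> None:
    for profile in ("s100b_like", "nse_like"):
        meas, _ = read_long_table(RESULTS / "cohorts" / profile / "measurements.csv")
        csf = "S100B_CSF" if "s100b" in profile else "NSE_CSF"
        blood = csf.replace("_CSF", "_BLOOD")
        grid = add_albumin_quotient(interpolate_to_grid(meas, 6.0))
        if csf == "S100B_CSF":
            grid = exclude_early_window(grid, cutoff_h=12.0)
        gcc, report = complete_cases(grid, [csf, blood, "QA"])
        d = make_clearance_design(gcc.values, blood, csf=csf, qa="QA")
        gls, aic_table = select_arma_by_aic(
            d["y"], d["X"], d["groups"], candidates=ARMA_GRID,
            terms=d["terms"], response=blood,
        )
        order = (gls.arma.p, gls.arma.q)
        lmm = fit_linear_mixed(d["y"], d["X"], d["groups"], d["z_slope"],
                               order=order, terms=d["terms"], response=blood)
        final = gls if lmm.boundary_psi else lmm
        rows = []
        for term in final.terms:
            df_s, p_s, _ = satterthwaite_df(final, term)
            est = final.params.loc[term]
            rows.append({"term": term, "estimate": est["estimate"], "se": est["se"],
                         "df": df_s, "p": p_s})
        table = pd.DataFrame(rows).set_index("term")
        table.to_csv(RESULTS / f"model_{profile}.csv")
        aic_table.to_csv(RESULTS / f"aic_{profile}.csv", index=False)
        retained = [t for t, r in table.iterrows()
                    if r["p"] <= 0.05 and t != "intercept"]
        print(f"{profile}: {final.kind} with ARMA{order} "
              f"(phi={final.arma.phi}, theta={final.arma.theta}); "
              f"complete cases {report['retained']} rows; "
              f"terms at p<=0.05: {retained or 'none'}")


if __name__ == "__main__":
    main()
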