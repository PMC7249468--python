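"""Generate the two synthetic study cohorts used by the downstream analyses.

One barrier-mediated (S100B-like) and one barrier-independent (NSE-like)
cohort of 16 subjects over one week, written as long-format CSV +
demographics CSV + latent-truth JSON under ``results/cohorts/``.
"""

from pathlib import Path

from bbbflux.synthetic import make_study_like_cohort, write_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    for profile in ("s100b_like", "nse_like"):
        meas, demo, truth = make_study_like_cohort(profile, n=16, seed=SEED)
        outdir = RESULTS / "cohorts" / profile
        write_cohort(outdir, meas, demo, truth)
        n_disrupted = sum(v["disrupted"] for k, v in truth.items() if k != "config")
        print(f"{profile}: {len(meas)} measurements, 16 subjects "
              f"({n_disrupted} with a disrupted barrier) -> {outdir}")


if __name__ == "__main__":
    main()
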