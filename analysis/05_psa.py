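"""Probabilistic sensitivity analysis: 10,000 Monte Carlo replicates.

Propagates the beta/gamma parameter distributions through the cohort
model for both countries, writes the acceptability curves, the median
ICER intervals against the dose-adjusted reference (the published
summary), and a 250-draw cost-effectiveness-plane sample.  Outputs:
results/ceac_<country>.csv, results/psa_summary.json,
results/ce_plane_sample_<country>.csv.
"""

import json
from pathlib import Path

import numpy as np

from hcc_cea.psa import ceac, icer_summary, run_psa
from hcc_cea.scenarios import STRATEGIES, load_builtin

SEED = 0
N_DRAWS = 10_000


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "results"
    out.mkdir(exist_ok=True)

    summary = {}
    for country in ("china", "usa"):
        scn = load_builtin(country)
        res = run_psa(scn, N_DRAWS, seed=SEED)
        curve = ceac(res)
        curve.to_csv(out / f"ceac_{country}.csv", index=False)
        res.samples[res.samples.draw < 250].to_csv(
            out / f"ce_plane_sample_{country}.csv", index=False
        )

        gap = curve["sorafenib_full"].to_numpy() - curve["tace"].to_numpy()
        first = np.where(gap >= 0)[0]
        crossing = float(curve["wtp"].iloc[first[0]]) if first.size else None
        adj_always = bool(
            (
                curve["sorafenib_adjusted"]
                >= curve[["tace", "sorafenib_full"]].max(axis=1)
            ).all()
        )
        summary[country] = {
            "seed": SEED,
            "n_draws": N_DRAWS,
            "n_clipped": res.n_clipped,
            "mean_by_strategy": {
                s: {
                    "cost": float(res.wide("cost")[s].mean()),
                    "qaly_years": float(res.wide("qaly_years")[s].mean()),
                }
                for s in STRATEGIES
            },
            "full_vs_tace_ceac_crossing_wtp": crossing,
            "adjusted_highest_probability_everywhere": adj_always,
            "icer_vs_adjusted": icer_summary(res).to_dict(orient="records"),
        }
        print(
            f"{country}: full-dose overtakes TACE on the acceptability curve "
            f"at WTP ${crossing:,.0f} (threshold ${scn.wtp_usd_per_qaly:,.0f}); "
            f"dose-adjusted highest everywhere: {adj_always}; "
            f"clipped draws: {res.n_clipped}"
        )

    (out / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
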