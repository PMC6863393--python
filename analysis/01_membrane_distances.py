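#!/usr/bin/env python
"""Intermembrane distance recovery over cohorts of synthetic contact sites.

Generates cohorts of flat ER-PM contact sites whose true separations are set
to the distances reported for the three bridging-protein families (GFP-Scs2
21.9 nm over 29 sites, GFP-Ist2 19.8 nm over 31, Tcb3-GFP 20.8 nm over 45),
with 1 nm click jitter, and runs the full surface-distance chain per site.
Also measures the shortest distance at a buckled site (ER locally
approaching the PM to 14.2 nm).  Writes per-cohort tables to results/.
"""

from pathlib import Path

import pandas as pd

from mcsquant import surface
from mcsquant.pipelines import distance_survey
from mcsquant.synthetic import SiteTruth, gen_membrane_site

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

COHORTS = [
    ("GFP-Scs2-like", 21.9, 29),
    ("GFP-Ist2-like", 19.8, 31),
    ("Tcb3-GFP-like", 20.8, 45),
]


def main() -> None:
    rows = []
    per_site = []
    for i, (label, sep, n) in enumerate(COHORTS):
        r = distance_survey(n_sites=n, separation_nm=sep, jitter_sd_nm=1.0, seed=100 + i)
        detail = r.detail.assign(cohort=label, true_separation_nm=sep)
        per_site.append(detail)
        rows.append(
            {
                "cohort": label,
                "n_sites": n,
                "true_separation_nm": sep,
                "grand_mean_nm": round(r.measured, 3),
                "grand_sd_nm": round(detail["mean_nm"].std(ddof=1), 3),
                "error_nm": round(r.error, 3),
            }
        )
        print(
            f"{label}: true {sep} nm, recovered grand mean "
            f"{r.measured:.2f} nm over {n} sites (error {r.error:+.2f} nm)"
        )

    # buckled site: shortest ER-to-PM distance at the buckle apex
    truth = SiteTruth(
        separation_nm=22.0,
        geometry="buckled",
        buckle_depth_nm=22.0 - 14.2,
        buckle_radius_nm=20.0,
        jitter_sd_nm=0.3,
        seed=200,
        site_id="buckle",
    )
    pm, er = gen_membrane_site(truth, 150.0)
    shortest = surface.buckle_distance(pm, er.points)
    print(f"buckled site: true apex gap 14.2 nm, measured shortest {shortest:.2f} nm")
    rows.append(
        {
            "cohort": "buckled",
            "n_sites": 1,
            "true_separation_nm": 14.2,
            "grand_mean_nm": round(shortest, 3),
            "grand_sd_nm": 0.0,
            "error_nm": round(shortest - 14.2, 3),
        }
    )

    pd.concat(per_site, ignore_index=True).round(3).to_csv(
        OUT / "distance_sites.csv", index=False
    )
    pd.DataFrame(rows).to_csv(OUT / "distance_survey.csv", index=False)
    print(f"wrote {OUT / 'distance_survey.csv'} and per-site table")


if __name__ == "__main__":
    main()
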