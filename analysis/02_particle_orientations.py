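#!/usr/bin/env python
"""Tilt geometry of bridging particles from 4-point picks.

Recovers the deviation from perpendicular to the PM for synthetic rods:
first noiselessly at the reported mean deviation (15.2 deg), then for a
large jittered cohort emulating the 1513-particle data set, whose tilt
distribution is drawn to match the reported spread (SD 12.1 deg, folded to
[0, 90]).  Writes the per-particle angles and the 5-degree histogram.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mcsquant.particles import orientation_summary, particle_axis_angle
from mcsquant.pipelines import tilt_recovery
from mcsquant.synthetic import gen_particle_picks

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def rod_table(tilts_deg: np.ndarray, sep: float = 22.0) -> dict:
    rng = np.random.default_rng(7)
    rows = []
    for i, tilt in enumerate(tilts_deg):
        theta, phi = np.radians(tilt), rng.uniform(0, 2 * np.pi)
        a = np.array([0.0, 0.0, 40.0])
        d = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)])
        b = a + (sep / np.cos(theta)) * d
        rows.append(
            {"rod_id": i, "x_nm": 0.0, "y_nm": 0.0, "tilt_deg": tilt,
             "azimuth_deg": np.degrees(phi), "length_nm": sep / np.cos(theta),
             "ax_nm": a[0], "ay_nm": a[1], "az_nm": a[2],
             "bx_nm": b[0], "by_nm": b[1], "bz_nm": b[2]}
        )
    return {"rods": pd.DataFrame(rows)}


def main() -> None:
    r = tilt_recovery(100, 15.2, click_jitter_nm=0.0, seed=1)
    print(f"noiseless picks at 15.2 deg: recovered mean {r.measured:.6f} deg")

    # jittered cohort: half-normal-like tilt distribution, mean ~15.2 deg
    rng = np.random.default_rng(11)
    tilts = np.clip(np.abs(rng.normal(0.0, 19.06, 1513)), 0.0, 85.0)
    picks = gen_particle_picks(rod_table(tilts), click_jitter_nm=1.0, seed=13)
    orients = [particle_axis_angle(p) for p in picks]
    summary = orientation_summary(orients, bin_width_deg=5.0)
    print(
        f"jittered cohort (n={summary.n}): true mean {tilts.mean():.1f} deg, "
        f"recovered mean {summary.mean_deg:.1f} deg, SD {summary.sd_deg:.1f} deg"
    )

    pd.DataFrame(
        {
            "particle_id": [o.particle_id for o in orients],
            "true_tilt_deg": tilts,
            "recovered_deviation_deg": [o.tilt_deviation_deg for o in orients],
            "inplane_rotation_deg": [o.inplane_rotation_deg for o in orients],
            "axis_length_nm": [o.axis_length_nm for o in orients],
        }
    ).round(3).to_csv(OUT / "particle_orientations.csv", index=False)
    pd.DataFrame(
        {
            "bin_left_deg": summary.bin_edges_deg[:-1],
            "bin_right_deg": summary.bin_edges_deg[1:],
            "count": summary.counts,
        }
    ).to_csv(OUT / "orientation_histogram.csv", index=False)
    print(f"wrote {OUT / 'particle_orientations.csv'} and histogram")


if __name__ == "__main__":
    main()
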