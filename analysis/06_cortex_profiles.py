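#!/usr/bin/env python
"""Linearized cortical line profiles: colocalized vs segregated signals.

Renders two-channel cortical ring images emulating protein pairs that
colocalize extensively (overlapping angular domains with small private
regions) and pairs that segregate (disjoint domains), straightens the
signal along the cell contour, and compares channels by Pearson
correlation of the linearized profiles.
"""

from pathlib import Path

import pandas as pd

from mcsquant.cortex import CortexContour, linearize_profile, profile_correlation
from mcsquant.synthetic import gen_cortex_image
from mcsquant.synthetic.rings import RingSpec

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SCENARIOS = {
    # extensively overlapping domains with individual enriched regions
    "colocalized": ([(0.0, 200.0), (250.0, 300.0)], [(0.0, 220.0)]),
    # disjoint halves
    "segregated": ([(0.0, 170.0)], [(190.0, 350.0)]),
    # identical distributions
    "identical": ([(30.0, 150.0), (200.0, 330.0)], [(30.0, 150.0), (200.0, 330.0)]),
}


def main() -> None:
    spec = RingSpec(noise_sd=2.0)
    rows = []
    frames = []
    for name, domains in SCENARIOS.items():
        image, contour = gen_cortex_image(domains, seed=31, spec=spec)
        prof = linearize_profile(image, CortexContour(contour))
        r = profile_correlation(prof)
        rows.append({"scenario": name, "pearson_r": round(r, 4)})
        frames.append(
            pd.DataFrame(
                {
                    "scenario": name,
                    "position_px": prof.positions_px,
                    "channel_1": prof.intensities[0],
                    "channel_2": prof.intensities[1],
                }
            )
        )
        print(f"{name}: profile correlation r = {r:+.3f}")
    pd.concat(frames, ignore_index=True).round(2).to_csv(
        OUT / "cortex_profiles.csv", index=False
    )
    pd.DataFrame(rows).to_csv(OUT / "cortex_correlations.csv", index=False)
    print(f"wrote {OUT / 'cortex_profiles.csv'} and correlations")


if __name__ == "__main__":
    main()
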