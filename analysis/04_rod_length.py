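#!/usr/bin/env python
"""Rod length from collapsed-2D particle averages.

Renders contact volumes bridged by perpendicular rods at the two reported
length regimes (the short class-4-like 16.7 nm and a long-class-like
22 nm leaflet separation), runs the particle route (box extraction at the
truth picks, collapse, k=1 constrained averaging) and measures the
cytosolic-leaflet-to-cytosolic-leaflet distance on 15-pixel-wide profiles.
"""

from pathlib import Path

import pandas as pd

from mcsquant.pipelines import BINNED_VOXEL_NM, rod_length_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for label, sep in (("class4-like", 16.7), ("long-class-like", 22.0)):
        r = rod_length_pipeline(sep, n_rods=50, seed=5)
        rows.append(
            {
                "regime": label,
                "true_length_nm": sep,
                "measured_length_nm": round(r.measured, 4),
                "error_nm": round(r.error, 4),
                "n_particles": r.n,
            }
        )
        print(
            f"{label}: truth {sep} nm, measured {r.measured:.2f} nm "
            f"(error {r.error:+.2f} nm, one voxel = {BINNED_VOXEL_NM} nm)"
        )
    pd.DataFrame(rows).to_csv(OUT / "rod_length.csv", index=False)
    print(f"wrote {OUT / 'rod_length.csv'}")


if __name__ == "__main__":
    main()
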