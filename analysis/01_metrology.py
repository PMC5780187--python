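#!/usr/bin/env python
"""Stereo-metrology error budget and grating geometry of the free-fall box.

Computes the minimal resolvable distance of the dual-view rig at the near
and far walls, the pixel-quantization positional uncertainty it implies, and
the spatial frequency of the wall grating seen from the corridor midline.
Writes results/metrology.csv.
"""

from pathlib import Path

import pandas as pd

from hoverfall.metrics import (
    DEFAULT_RIG,
    grating_spatial_frequency,
    quantization_uncertainty,
    stereo_min_distance,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, d in (("near wall", 1131.0), ("far wall", 1531.0)):
        dd = stereo_min_distance(DEFAULT_RIG, d)
        rows.append(
            {
                "quantity": f"Delta_d ({label})",
                "value": round(dd, 3),
                "units": "mm",
                "note": f"object distance {d:.0f} mm",
            }
        )
        rows.append(
            {
                "quantity": f"QPU_rms ({label})",
                "value": round(quantization_uncertainty(dd), 3),
                "units": "mm",
                "note": "Delta_d / sqrt(12)",
            }
        )
    rows.append(
        {
            "quantity": "grating spatial frequency",
            "value": round(grating_spatial_frequency(0.028, 0.20), 4),
            "units": "c/deg",
            "note": "2.8 cm stripes at 20 cm",
        }
    )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "metrology.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nThe rig resolves ~2.6-4.7 mm across the box: enough to separate "
        "head and tail of a 10-15 mm body, so the axis-regression pitch "
        "measurement is viable everywhere in the arena."
    )


if __name__ == "__main__":
    main()
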