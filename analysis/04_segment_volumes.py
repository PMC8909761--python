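#!/usr/bin/env python
"""3D segmentation volumetry: count recovery and the two-population contrast.

Segments synthetic volumetric scenes with the fixed chain (upper-Otsu →
3D erosion, kernel 3 → 26-connected labeling → <10-voxel speckle removal →
measurement), checks exact object-count recovery, then measures the mean
mitochondrial volume of two populations generated at a true 2:1 ratio
(3.8 vs 1.9 µm³, the control-vs-knockdown contrast).  Writes
results/segmentation/volumes.csv.
"""

from pathlib import Path

import pandas as pd

from mitomorph import io
from mitomorph import validation as V

OUT = Path(__file__).resolve().parents[1] / "results" / "segmentation"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    rec = V.count_recovery(seed=1, n_scenes=10)
    print(
        f"exact count recovery on 50-object scenes: "
        f"{100 * rec['fraction_exact']:.0f}% of 10 seeds"
    )

    res = V.volume_ratio_two_populations(seed=1, n_scenes=3)
    print(
        f"shell-loss correction calibrated at {res['shell_correction_um']:.4f} µm"
    )
    print(
        f"measured mean volumes: {res['mean_large_um3']:.2f} µm³ vs "
        f"{res['mean_small_um3']:.2f} µm³ -> ratio {res['ratio']:.2f} "
        f"(true 2.00)"
    )
    io.write_csv(
        pd.DataFrame(
            [
                {
                    "mean_large_um3": res["mean_large_um3"],
                    "mean_small_um3": res["mean_small_um3"],
                    "measured_ratio": res["ratio"],
                    "true_ratio": 2.0,
                    "shell_correction_um": res["shell_correction_um"],
                    "count_recovery_fraction": rec["fraction_exact"],
                }
            ]
        ),
        OUT / "volumes.csv",
    )
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
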