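#!/usr/bin/env python
"""Axial repeat distance of negative-stain-like egg-coat filaments.

Generates 100 noisy synthetic class images at the ~65 Å medaka egg-coat
repeat (5 Å/px, SNR 0.5) and measures the spacing per class by axial
projection and autocorrelation, then aggregates.
Writes results/repeat_estimate.json.
"""

import json
from pathlib import Path

from zpfilament.workflows import run_repeat_recovery

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    est, truth = run_repeat_recovery(seed=SEED)
    print(f"{est.n_measurements} usable classes "
          f"({est.n_excluded} excluded for weak repeat signal)")
    print(f"repeat {est.spacing_angstrom:.2f} ± "
          f"{est.spacing_sd_angstrom:.2f} Å "
          f"(truth {truth['repeat_angstrom']:.0f} Å at "
          f"{truth['pixel_size_angstrom']:.0f} Å/px)")

    OUT.mkdir(exist_ok=True)
    (OUT / "repeat_estimate.json").write_text(json.dumps({
        "seed": SEED,
        "mean_spacing_angstrom": est.spacing_angstrom,
        "sd_angstrom": est.spacing_sd_angstrom,
        "n_measurements": est.n_measurements,
        "n_excluded": est.n_excluded,
        "truth": truth,
    }, indent=1))
    print(f"\nwrote {OUT / 'repeat_estimate.json'}")


if __name__ == "__main__":
    main()
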