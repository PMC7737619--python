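#!/usr/bin/env python
"""Filament interface metrics: SASA, buried area, buried fraction.

Runs the Shrake–Rupley machinery on a SYNTHETIC interlocking subunit
(the deposited filament coordinates, PDB 6TQK, are not distributed with
this repository; when a local copy exists at data/deposited/6tqk.cif
the same metrics are computed on it with the selections used for the
published linker-belt interface). Writes results/interface_metrics.json.
"""

import json
from pathlib import Path

from zpfilament.helix import HelicalSymmetry
from zpfilament.structure import (buried_area, buried_fraction,
                                  com_distance, expand_filament,
                                  make_synthetic_subunit_structure,
                                  read_structure, sasa)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
DEPOSITED = ROOT / "data" / "deposited" / "6tqk.cif"


def synthetic_metrics() -> dict:
    model = make_synthetic_subunit_structure(seed=0)
    sym = HelicalSymmetry(62.5, 180.0)
    _, alone = sasa(model)
    expanded = expand_filament(model, sym, range(-2, 3))
    frac = buried_fraction(expanded, "A")
    pair = expand_filament(model, sym, [0, 1])
    buried = buried_area(pair, "A", "A@1")
    half = len(model) // 2
    com = com_distance(model,
                       (model.resnums <= half), (model.resnums > half))
    print("synthetic interlocking subunit (not a deposited model):")
    print(f"  isolated SASA             {alone:9.1f} Å²")
    print(f"  buried vs next subunit    "
          f"{buried['two_sided_angstrom2']:9.1f} Å² (two-sided)")
    print(f"  buried fraction in 5-mer  {frac:9.3f}")
    print(f"  COM distance lobe A/B     {com:9.1f} Å")
    return {
        "isolated_sasa_angstrom2": alone,
        "pair_buried_two_sided_angstrom2": buried["two_sided_angstrom2"],
        "buried_fraction_five_subunits": frac,
        "lobe_com_distance_angstrom": com,
    }


def deposited_metrics() -> dict:
    model = read_structure(str(DEPOSITED))
    res = buried_area(model, "A:430-465", "B:466-587,C:296-429")
    expanded = expand_filament(
        model, HelicalSymmetry(62.5, 180.0), range(-2, 3), selection="A"
    )
    frac = buried_fraction(expanded, "A")
    print("deposited full-length filament model:")
    print(f"  linker belt buried area   "
          f"{res['two_sided_angstrom2']:9.1f} Å² (two-sided)")
    print(f"  central buried fraction   {frac:9.3f}")
    return {
        "linker_belt_buried_two_sided_angstrom2":
            res["two_sided_angstrom2"],
        "central_buried_fraction": frac,
    }


def main() -> None:
    report = {"synthetic": synthetic_metrics()}
    if DEPOSITED.exists():
        report["deposited_6tqk"] = deposited_metrics()
    else:
        print(f"\n(no deposited coordinates at {DEPOSITED}; place the "
              "PDB 6TQK mmCIF there to compute the published linker-belt "
              "numbers)")
        report["deposited_6tqk"] = None
    OUT.mkdir(exist_ok=True)
    (OUT / "interface_metrics.json").write_text(
        json.dumps(report, indent=1)
    )
    print(f"\nwrote {OUT / 'interface_metrics.json'}")


if __name__ == "__main__":
    main()
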