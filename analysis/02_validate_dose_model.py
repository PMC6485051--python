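#!/usr/bin/env python
"""Dose-model validation on synthetic measured/modelled curve pairs.

Emulates the commissioning step of checking a modelled beam against water-tank
measurements: a percentage-depth-dose pair whose modelled curve carries a
small dose perturbation, and a lateral-profile pair with a 1 mm positioning
shift plus 1% output difference.  Agreement is quantified as the maximum and
mean pointwise dose difference (percent of maximum) and by the gamma index at
3%/3 mm with 1 mm resampling of the evaluated curve.

Writes results/dose_validation.json and the four curves as CSV.
"""

import json
from pathlib import Path

from portalqa import compare_profiles, make_dose_curve_pair
from portalqa.io import write_profile

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)

    pdd_ref, pdd_ev = make_dose_curve_pair("pdd", (1.2, 0.0, 0.3), seed=SEED)
    pdd = compare_profiles(pdd_ref, pdd_ev, normalize="max")

    prof_ref, prof_ev = make_dose_curve_pair("lateral", (1.0, 1.0, 0.0),
                                             seed=SEED + 1)
    prof = compare_profiles(prof_ref, prof_ev, normalize="cax",
                            roi_mm=(-100.0, 100.0))

    write_profile(pdd_ref, OUT / "pdd_measured.csv")
    write_profile(pdd_ev, OUT / "pdd_modelled.csv")
    write_profile(prof_ref, OUT / "profile_measured.csv")
    write_profile(prof_ev, OUT / "profile_modelled.csv")
    (OUT / "dose_validation.json").write_text(
        json.dumps({"pdd": pdd, "lateral_profile": prof}, indent=2))

    print("Depth dose (max-normalized):")
    print(f"  max deviation {pdd['max_dose_diff_percent']:.2f}% of maximum "
          f"(mean {pdd['mean_dose_diff_percent']:.2f}%)")
    print(f"  gamma 3%/3mm: pass fraction {pdd['pass_fraction']:.3f}, "
          f"max gamma {pdd['max_gamma']:.3f}")
    print("Lateral profile (CAX-normalized, in-field -100..100 mm):")
    print(f"  gamma 3%/3mm: pass fraction {prof['pass_fraction']:.3f}, "
          f"max gamma {prof['max_gamma']:.3f}")
    verdict = "consistent" if pdd["pass_fraction"] == 1.0 and \
        prof["pass_fraction"] == 1.0 else "NOT consistent"
    print(f"\nModelled and measured curves are {verdict} under the "
          "3%/3 mm criteria: all gamma values in the evaluated region "
          "are below one." if verdict == "consistent" else "")


if __name__ == "__main__":
    main()
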