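"""Contrast the wet-day and dry-day regimens cycle by cycle.

Runs the same night session after a full daytime dwell (WD) and after a dry
day (DD).  With the cavity filled all day the superficial tissue stays
hydrated, so the first night cycle behaves like the later ones; after a dry
day the first-cycle UF is depressed by ~100 mL.  Writes the contrast table to
results/regimen_contrast.json.
"""

import json
from pathlib import Path

import numpy as np

import peritonsim as ps

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    params = ps.default_parameters()
    out = {}
    for name, rx in (("DD", ps.Prescription.dd_reference()),
                     ("WD", ps.Prescription.wd_reference())):
        print(f"simulating 3 {name} days ...")
        days = ps.simulate_days(params, rx, 3, n_cells=50)
        uf = days[-1].session.per_cycle_uf
        out[name] = {
            "per_cycle_uf_ml": [round(u, 1) for u in uf],
            "C1_ml": round(uf[0], 1),
            "mean_C3plus_ml": round(float(np.mean(uf[2:])), 1),
            "C1_minus_C3plus_ml": round(uf[0] - float(np.mean(uf[2:])), 1),
            "pre_session_theta_surface": round(
                days[-1].session.tissue_snapshots[0].theta[0], 4),
        }
    ratio = (abs(out["DD"]["C1_minus_C3plus_ml"])
             / max(abs(out["WD"]["C1_minus_C3plus_ml"]), 1e-9))
    out["DD_to_WD_contrast_ratio"] = round(ratio, 1)
    with open(RESULTS / "regimen_contrast.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(json.dumps(out, indent=1))
    print(f"\nThe first-cycle UF depression is {ratio:.0f}x larger after a dry "
          "day than after a wet day: daytime tissue dehydration, not the "
          "prescription, drives the first-cycle deficit.")


if __name__ == "__main__":
    main()
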