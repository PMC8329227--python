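"""Generate the synthetic RPM cohort used by the statistics analysis.

Emulates 16 days of cycler records for 6 dry-day and 8 wet-day patients with
the observed cycle-class structure (dry-day first-cycle depression) and high
day-to-day variability.  Writes results/rpm_synthetic.csv (+ metadata
sidecar).  One abnormal day-exchange record is injected to exercise the
explicit exclusion path of the analysis.
"""

from pathlib import Path

from peritonsim.io import write_rpm_csv
from peritonsim.synthetic import GeneratorConfig, generate

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 20260929


def main() -> None:
    cfg = GeneratorConfig(seed=SEED, inject_abnormal_day_exchange=True)
    ds = generate(cfg)
    out = RESULTS / "rpm_synthetic.csv"
    write_rpm_csv(ds, out, header_comment=f"synthetic RPM cohort, seed={SEED}")
    n_night = (ds.records["phase"] == "night_cycle").sum()
    print(f"wrote {out}: {len(ds.records)} records "
          f"({n_night} night cycles) for {len(ds.meta)} patients "
          f"({(ds.meta.regimen == 'DD').sum()} DD / "
          f"{(ds.meta.regimen == 'WD').sum()} WD), seed={SEED}")
    print("note: one abnormal day-exchange record injected "
          "(first day-exchange row); exclude it in the analysis step.")


if __name__ == "__main__":
    main()
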