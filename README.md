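# peritonsim

Mechanistic simulation and statistical analysis of **cycle-by-cycle water
removal in automated peritoneal dialysis (APD)**.

Home APD cyclers with remote patient monitoring log the infused and drained
volume of every exchange, so net ultrafiltration (UF = drained − infused) can
be followed cycle by cycle.  Patients on a *dry-day* regimen (no daytime
dwell) often show depressed — sometimes negative — UF in the first night
cycle, recovering by the third; patients on a *wet-day* regimen do not.
`peritonsim` implements the physiological explanation and the data analysis
around it, for modellers and clinical researchers studying peritoneal fluid
transport:

* a **spatially distributed model** of the peritoneal tissue — Darcy water
  flow with crystalloid osmosis through a deformable interstitium whose
  hydration θ follows local pressure through a saturating compliance law,
  hydration-dependent conductivity/diffusivity, Starling capillary exchange
  with glucose-driven vasodilation, and pressure-sensitive (saturating)
  lymphatic uptake:

      ∂θ/∂t = −∂j_v/∂x + q_v − q_l,   j_v = −K(θ)(∂P/∂x − σ_T RT ∂C/∂x)
      ∂(θC)/∂t = −∂j_s/∂x + q_s − q_l C,   j_s = −θD(θ)∂C/∂x + (1−σ_T)C↑ j_v

* an **APD session simulator** (fill/dwell/drain at pump rates, dry-day and
  wet-day daily schedules, multi-day runs to the periodic state) coupled to
  the tissue layer with exact water/glucose bookkeeping;
* the **RPM cycle statistics**: C1/C2/C3+ contrasts (repeated-measures ANOVA
  with Tukey post-hoc), drain-volume ratios VdrR1/VdrR2 with Wilcoxon and
  Mann–Whitney tests, daily water removal;
* a **seeded synthetic-data generator** for RPM-style cohorts, so the whole
  pipeline runs end-to-end without clinical data.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Simulate three dry-day treatment days (six 90-min cycles of 2 L glucose
1.36% per night, 100 mL comfort fill resting all day) and print the last
day's water-removal table:

```bash
python analysis/01_simulate_dd_session.py
```

```
                          quantity   value
            UF for APD session, mL  437.60
                      UF in C1, mL  -19.80
                      UF in C2, mL   76.40
                Mean UF in C3+, mL   95.30
               SD of UF in C3+, mL    2.64
  C1 deficit vs mean of C2..C6, mL  111.30
       Water accumulated in C1, mL  213.10
Water accumulated in C1 and C2, mL  268.30
           Day exchange net UF, mL -100.00

per-cycle UF, day 3: [-19.8, 76.4, 90.9, 95.4, 97.0, 97.8]
near-cavity hydration: pre-session 0.191, end of C1 dwell 0.360
```

Reading: after the dry day the superficial tissue sits near its
physiological 18% hydration.  The first 2-L fill pressurises the cavity to
~9.5 mmHg and drives ~213 mL of fluid into the first ~0.2 cm of tissue
(near-cavity hydration rises to 36%), so the first cycle *removes* no water
(net UF −19.8 mL).  The hydrated layer persists through the brief drains;
by cycle 3 each exchange yields the ~95 mL plateau that the glucose osmotic
gradient earns, and the session still nets +437.6 mL.  Overnight tissue
water then drains away during the next dry day and the pattern repeats.
`analysis/02_wet_day_contrast.py` shows the control: with a daytime dwell
(wet day) the first-cycle deficit collapses from ~111 mL to ~7 mL.

The same machinery is available as a CLI:

```bash
peritonsim simulate --days 3 --regimen DD --out-dir out/
peritonsim generate --seed 7 --out cohort.csv
peritonsim analyze --input cohort.csv --out report.json
```

`analysis/03_generate_rpm_cohort.py` and `analysis/04_cycle_statistics.py`
run the statistical arm: on a synthetic 16-day cohort (6 dry-day / 8 wet-day
patients) the dry-day arm shows a strongly significant cycle-class effect
with C1 below C3+ and VdrR1 median ≈ 0.87 < 1, while the wet-day arm's
omnibus test is non-significant — the inference pattern the simulation
explains mechanistically.

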