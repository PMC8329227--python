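"""Synthetic RPM datasets with the statistical structure of home-APD records.

Two generators:

* :func:`generate` — a statistical emulator.  Per-cycle net UF is a cycle-class
  mean (regimen-specific, with the dry-day first-cycle depression) plus a
  patient random effect, a patient-by-class random effect, and large
  day-to-day noise; drained = infused + UF with a constant residual volume per
  patient (zero cycle-to-cycle carryover).
* :func:`generate_from_simulator` — a mechanistic emulator: per-cycle UF from
  the distributed-model day simulation plus observation noise.

Both are fully reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import ModelParameters
from .session import Prescription, simulate_days
from .stats import RPMDataset, RECORD_COLUMNS

__all__ = ["GeneratorConfig", "generate", "generate_from_simulator"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic RPM cohort.

    Class means and day-exchange means follow the observed cohort medians;
    the variance components (patient, patient-by-class, day-to-day) are
    calibration choices reproducing the observed interquartile spreads and
    the within-regimen inference pattern.
    """

    n_patients_dd: int = 6
    n_patients_wd: int = 8
    n_days: int = 16
    # night cycles per patient: 4..7, median 5
    n_cycles_values: tuple[int, ...] = (4, 5, 6, 7)
    n_cycles_probs: tuple[float, ...] = (0.25, 0.45, 0.20, 0.10)
    fill_volume_range: tuple[float, float] = (1600.0, 2300.0)  # mL, per patient
    # per-cycle-class mean net UF (mL): C1, C2, C3+
    class_means_dd: tuple[float, float, float] = (-61.0, 170.0, 213.0)
    class_means_wd: tuple[float, float, float] = (81.0, 81.0, 115.0)
    sd_patient: float = 60.0          # between-patient random effect, mL
    sd_patient_class: float = 45.0    # patient-by-cycle-class random effect, mL
    sd_day: float = 90.0              # day-to-day noise per cycle, mL
    # day exchange
    day_uf_mean_dd: float = -96.0
    day_uf_mean_wd: float = 254.0
    day_uf_sd_patient: float = 40.0
    day_uf_sd_day: float = 60.0
    day_fill_dd_choices: tuple[float, ...] = (100.0, 100.0, 100.0, 100.0, 300.0, 500.0)
    day_fill_wd_range: tuple[float, float] = (1000.0, 1800.0)
    # daily urine output, per patient (median ~1150 DD / ~600 WD clinically)
    diuresis_median_dd: float = 1150.0
    diuresis_median_wd: float = 600.0
    diuresis_sd: float = 500.0
    residual_volume_range: tuple[float, float] = (150.0, 350.0)
    inject_abnormal_day_exchange: bool = False  # exercise the exclusion path
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_dd < 1 or self.n_patients_wd < 1 or self.n_days < 1:
            raise ValueError("counts must be >= 1")
        for name in ("sd_patient", "sd_patient_class", "sd_day",
                     "day_uf_sd_patient", "day_uf_sd_day", "diuresis_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.n_cycles_probs) - 1.0) > 1e-9:
            raise ValueError("n_cycles_probs must sum to 1")
        if len(self.n_cycles_values) != len(self.n_cycles_probs):
            raise ValueError("n_cycles_values and n_cycles_probs length mismatch")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


def _class_of(cycle_index: int) -> int:
    return 0 if cycle_index == 1 else (1 if cycle_index == 2 else 2)


def generate(config: GeneratorConfig = GeneratorConfig()) -> RPMDataset:
    """Draw a synthetic RPM cohort dataset.

    UF_cycle = class mean + patient effect + patient-by-class effect +
    day noise; drained = infused + UF (constant residual volume per patient,
    no carryover noise).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    meta_rows = []
    specs = ([("DD", i) for i in range(config.n_patients_dd)]
             + [("WD", i) for i in range(config.n_patients_wd)])
    for regimen, i in specs:
        pid = f"{regimen}{i + 1:02d}"
        n_cycles = int(rng.choice(config.n_cycles_values, p=config.n_cycles_probs))
        fill = float(np.round(rng.uniform(*config.fill_volume_range), -1))
        class_means = np.asarray(config.class_means_dd if regimen == "DD"
                                 else config.class_means_wd)
        b_pat = rng.normal(0.0, config.sd_patient)
        b_pat_class = rng.normal(0.0, config.sd_patient_class, size=3)
        day_mean = (config.day_uf_mean_dd if regimen == "DD"
                    else config.day_uf_mean_wd)
        b_day_pat = rng.normal(0.0, config.day_uf_sd_patient)
        if regimen == "DD":
            day_fill = float(rng.choice(config.day_fill_dd_choices))
        else:
            day_fill = float(np.round(rng.uniform(*config.day_fill_wd_range), -1))
        diuresis_med = (config.diuresis_median_dd if regimen == "DD"
                        else config.diuresis_median_wd)
        diuresis = float(max(0.0, rng.normal(diuresis_med, config.diuresis_sd)))
        fluid = "glucose 1.36%" if rng.random() < 0.5 else "glucose 2.27%"
        for day in range(1, config.n_days + 1):
            for ci in range(1, n_cycles + 1):
                k = _class_of(ci)
                uf = (class_means[k] + b_pat + b_pat_class[k]
                      + rng.normal(0.0, config.sd_day))
                uf = max(uf, -fill)  # the cycler cannot drain less than nothing
                rows.append((pid, day, "night_cycle", ci, round(fill),
                             round(fill + uf), fluid))
            day_uf = day_mean + b_day_pat + rng.normal(0.0, config.day_uf_sd_day)
            day_uf = max(day_uf, -day_fill)
            rows.append((pid, day, "day_exchange", 0, round(day_fill),
                         round(day_fill + day_uf), fluid))
        meta_rows.append((pid, regimen, round(diuresis),
                          float(np.round(rng.uniform(*config.residual_volume_range)))))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    meta = pd.DataFrame(meta_rows, columns=["patient_id", "regimen",
                                            "diuresis_ml", "residual_volume_ml"])
    if config.inject_abnormal_day_exchange:
        # one grossly abnormal day-exchange value, to exercise the explicit
        # exclusion path downstream
        j = records.index[records["phase"] == "day_exchange"][0]
        records.loc[j, "drained_ml"] = records.loc[j, "infused_ml"] + 4000
    return RPMDataset(records, meta)


def generate_from_simulator(params: ModelParameters, prescription: Prescription,
                            n_days: int = 16, sd_day: float = 90.0,
                            seed: int = 0, n_cells: int = 50,
                            patient_id: str = "SIM01",
                            sim_days: int = 3, days_result=None) -> RPMDataset:
    """Mechanistic generator: simulator per-cycle UF plus observation noise.

    The distributed model is run to its periodic state (``sim_days`` days) and
    the final day's per-cycle UF pattern is replicated over ``n_days`` of
    records with additive Gaussian day-to-day noise — preserving the dry-day
    first-cycle depression in the record stream.  Zero noise reproduces the
    simulator output exactly.  A precomputed ``days_result`` (the output of
    :func:`peritonsim.session.simulate_days` for the same prescription) may be
    passed to skip the simulation.
    """
    rng = np.random.default_rng(seed)
    days = (days_result if days_result is not None
            else simulate_days(params, prescription, sim_days, n_cells=n_cells))
    last = days[-1]
    base_uf = last.session.per_cycle_uf
    fill = prescription.fill_volume
    day_fill = prescription.day_fill_volume
    day_uf = last.day_net_uf
    fluid = f"glucose {prescription.glucose_pct}%"
    rows = []
    for day in range(1, n_days + 1):
        for ci, uf in enumerate(base_uf, start=1):
            noisy = max(uf + rng.normal(0.0, sd_day), -fill)
            rows.append((patient_id, day, "night_cycle", ci,
                         float(fill), float(fill + noisy), fluid))
        noisy = max(day_uf + rng.normal(0.0, sd_day), -day_fill)
        rows.append((patient_id, day, "day_exchange", 0,
                     float(day_fill), float(day_fill + noisy), fluid))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    meta = pd.DataFrame([(patient_id, prescription.regimen, 0.0,
                          params.residual_volume)],
                        columns=["patient_id", "regimen", "diuresis_ml",
                                 "residual_volume_ml"])
    return RPMDataset(records, meta)
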