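"""Cycle-by-cycle ultrafiltration statistics for RPM (remote patient
monitoring) APD records.

A cycler logs, for every exchange, the infused and drained volume; net UF is
their difference.  The analysis contrasts the first (C1) and second (C2)
night cycles against the mean of the remaining cycles (C3+, cycles 3 up to at
most 7), per patient per day, summarised as per-patient medians over the
observation period and group medians [Q1, Q3] over patients.  Drain-volume
ratios VdrR1/VdrR2 (early-cycle drained volume over mean drained volume of
the remaining cycles) provide a tonicity-robust version of the contrast.

Inference follows the clinical-study conventions: repeated-measures ANOVA
across the three cycle classes (patients as subjects, per-patient means per
class as the unit of analysis) with Tukey HSD post-hoc contrasts on the
repeated-measures error term; Wilcoxon tests for ratios against unity and
for paired ratios; Mann-Whitney U between regimens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CycleRecord", "RPMDataset", "StatsReport", "net_uf", "cycle_classes",
    "vdr_ratio", "compare_cycles", "compare_groups", "wilcoxon_vs_unity",
    "wilcoxon_paired", "daily_water_removal", "patient_summary",
    "group_summary", "analyze",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "day", "phase", "cycle_index",
                  "infused_ml", "drained_ml", "fluid_label"]
PHASES = ("night_cycle", "day_exchange")
MAX_CYCLE = 7  # C3+ uses cycles 3 up to at most 7


@dataclass(frozen=True)
class CycleRecord:
    """One cycler log line: an exchange with infused and drained volume."""
    patient_id: str
    day: int
    phase: str              # night_cycle | day_exchange
    cycle_index: int        # 1-based within the night session; 0 for day
    infused_ml: float
    drained_ml: float
    fluid_label: str = "glucose 1.36%"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.infused_ml < 0 or self.drained_ml < 0:
            raise ValueError("volumes must be >= 0")
        if self.phase == "night_cycle" and self.cycle_index < 1:
            raise ValueError("night cycle_index must be >= 1")


@dataclass
class RPMDataset:
    """Cycle records plus per-patient metadata (regimen, daily diuresis)."""
    records: pd.DataFrame                  # RECORD_COLUMNS
    meta: pd.DataFrame                     # patient_id, regimen, diuresis_ml

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        for col in ("patient_id", "regimen"):
            if col not in self.meta.columns:
                raise ValueError(f"meta missing column: {col}")
        bad = set(self.meta["regimen"]) - {"DD", "WD"}
        if bad:
            raise ValueError(f"unknown regimen labels: {bad}")
        dup = self.meta["patient_id"].duplicated()
        if dup.any():
            raise ValueError("each patient must have exactly one metadata row "
                             "(single regimen per patient)")

    @property
    def patients(self) -> list[str]:
        return list(self.meta["patient_id"])

    def regimen_of(self, patient: str) -> str:
        row = self.meta.loc[self.meta["patient_id"] == patient, "regimen"]
        if row.empty:
            raise KeyError(f"unknown patient {patient!r}")
        return str(row.iloc[0])

    def patients_in(self, regimen: str) -> list[str]:
        return list(self.meta.loc[self.meta["regimen"] == regimen, "patient_id"])

    def exclude(self, exclusions: Iterable[tuple]) -> "RPMDataset":
        """Drop explicitly listed records (patient_id, day, phase[, cycle_index]).

        Exclusion is always explicit and logged, never silent.
        """
        rec = self.records.copy()
        for item in exclusions:
            if len(item) == 3:
                pid, day, phase = item
                mask = ((rec["patient_id"] == pid) & (rec["day"] == int(day))
                        & (rec["phase"] == phase))
            elif len(item) == 4:
                pid, day, phase, ci = item
                mask = ((rec["patient_id"] == pid) & (rec["day"] == int(day))
                        & (rec["phase"] == phase) & (rec["cycle_index"] == int(ci)))
            else:
                raise ValueError(f"exclusion must have 3 or 4 fields, got {item!r}")
            n = int(mask.sum())
            if n == 0:
                logger.warning("exclusion %r matched no record", item)
            else:
                logger.info("excluding %d record(s) matching %r", n, item)
            rec = rec.loc[~mask]
        return RPMDataset(rec.reset_index(drop=True), self.meta)


def net_uf(record) -> float:
    """Net ultrafiltration of one exchange: drained minus infused volume (mL)."""
    if isinstance(record, (CycleRecord,)):
        return record.drained_ml - record.infused_ml
    return record["drained_ml"] - record["infused_ml"]


def _night_sessions(ds: RPMDataset, patient: str) -> pd.core.groupby.DataFrameGroupBy:
    rec = ds.records
    night = rec[(rec["patient_id"] == patient) & (rec["phase"] == "night_cycle")]
    return night.sort_values(["day", "cycle_index"]).groupby("day")


def cycle_classes(ds: RPMDataset, patient: str) -> pd.DataFrame:
    """Per-day UF_C1, UF_C2 and mean UF_C3+ (cycles 3..min(n, 7)) for a patient.

    Days with fewer than three night cycles are excluded with a warning.
    """
    rows = []
    for day, grp in _night_sessions(ds, patient):
        uf = (grp["drained_ml"] - grp["infused_ml"]).to_numpy()
        idx = grp["cycle_index"].to_numpy()
        if uf.size < 3:
            logger.warning("patient %s day %s has %d night cycles (<3); "
                           "day excluded from cycle-class analysis",
                           patient, day, uf.size)
            continue
        tail = uf[(idx >= 3) & (idx <= MAX_CYCLE)]
        rows.append({"day": day, "UF_C1": uf[idx == 1][0], "UF_C2": uf[idx == 2][0],
                     "UF_C3plus": float(np.mean(tail))})
    return pd.DataFrame(rows, columns=["day", "UF_C1", "UF_C2", "UF_C3plus"])


def vdr_ratio(ds: RPMDataset, patient: str, i: int, on: str = "drained") -> pd.Series:
    """Per-day VdrR_i: cycle-i volume over the mean volume of cycles 3..7.

    ``on='drained'`` (default) uses drained volumes, the tonicity-robust drain
    volume ratio; ``on='net_uf'`` computes the literal net-UF ratio instead.
    """
    if i not in (1, 2):
        raise ValueError("i must be 1 or 2")
    if on not in ("drained", "net_uf"):
        raise ValueError("on must be 'drained' or 'net_uf'")
    out = {}
    for day, grp in _night_sessions(ds, patient):
        idx = grp["cycle_index"].to_numpy()
        if idx.size < 3 or i not in idx:
            continue
        if on == "drained":
            vals = grp["drained_ml"].to_numpy()
        else:
            vals = (grp["drained_ml"] - grp["infused_ml"]).to_numpy()
        denom = np.mean(vals[(idx >= 3) & (idx <= MAX_CYCLE)])
        if denom == 0:
            raise ZeroDivisionError(
                f"zero mean cycle-3+ volume for patient {patient} day {day}")
        out[day] = float(vals[idx == i][0] / denom)
    return pd.Series(out, name=f"VdrR{i}")


@dataclass
class RMANOVAResult:
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    posthoc: dict[str, float]            # pair label -> Tukey p
    cell_means: dict[str, float]
    n_subjects: int


def compare_cycles(ds: RPMDataset, regimen: str) -> RMANOVAResult:
    """Repeated-measures ANOVA of net UF across cycle classes within a regimen.

    Unit of analysis: each patient's mean UF per cycle class over the
    observation period (subjects x 3 within-factor levels).  If the omnibus
    test is computed, Tukey HSD post-hoc contrasts (studentized range on the
    repeated-measures error mean square) are returned for C1-C2, C1-C3+,
    C2-C3+.
    """
    pats = ds.patients_in(regimen)
    rows = []
    for p in pats:
        cc = cycle_classes(ds, p)
        if cc.empty:
            continue
        rows.append([cc["UF_C1"].mean(), cc["UF_C2"].mean(), cc["UF_C3plus"].mean()])
    data = np.asarray(rows, dtype=float)
    if data.shape[0] < 2:
        raise ValueError(f"need >= 2 subjects with valid sessions in {regimen}, "
                         f"got {data.shape[0]}")
    n, k = data.shape
    # omnibus via statsmodels' repeated-measures ANOVA
    from statsmodels.stats.anova import AnovaRM
    long = pd.DataFrame({
        "patient": np.repeat(np.arange(n), k),
        "cls": np.tile(np.arange(k), n),
        "uf": data.ravel(),
    })
    table = AnovaRM(long, "uf", "patient", within=["cls"]).fit().anova_table
    f = float(table["F Value"].iloc[0])
    df_cond = float(table["Num DF"].iloc[0])
    df_err = float(table["Den DF"].iloc[0])
    p = float(table["Pr > F"].iloc[0])
    # error mean square for the post-hoc contrasts, from the same decomposition
    grand = data.mean()
    cond_means = data.mean(axis=0)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_err = float(np.sum((data - grand) ** 2)) - ss_cond - ss_subj
    ms_err = ss_err / ((n - 1) * (k - 1))
    # Tukey HSD on the RM error term: q = |diff| / sqrt(MS_err / n)
    labels = ["C1", "C2", "C3plus"]
    posthoc = {}
    se = math.sqrt(ms_err / n)
    for a in range(k):
        for b in range(a + 1, k):
            q = abs(cond_means[a] - cond_means[b]) / se
            posthoc[f"{labels[a]}-{labels[b]}"] = float(
                sps.studentized_range.sf(q, k, df_err))
    return RMANOVAResult(float(f), df_cond, df_err, p, posthoc,
                         dict(zip(labels, map(float, cond_means))), n)


def compare_groups(a: Sequence[float], b: Sequence[float]):
    """Mann-Whitney U test between two independent samples (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    return sps.mannwhitneyu(a, b, alternative="two-sided",
                            method="exact" if max(a.size, b.size) <= 25 else "auto")


def wilcoxon_vs_unity(ratios: Sequence[float], alternative: str = "less"):
    """One-sample Wilcoxon signed-rank test of ratios against 1.

    Default alternative 'less': ratios are systematically below unity.
    Exact null distribution for n <= 25 (ties at 1 are dropped, scipy's
    wilcox handling).
    """
    r = np.asarray(ratios, float)
    if r.size < 2:
        raise ValueError("need at least two ratios")
    d = r - 1.0
    if np.all(d == 0):
        # no deviation from unity at all: trivially not significant
        from collections import namedtuple
        return namedtuple("WilcoxonResult", ["statistic", "pvalue"])(0.0, 1.0)
    method = "exact" if (r.size <= 25 and not np.any(d == 0)) else "auto"
    return sps.wilcoxon(d, alternative=alternative, method=method)


def wilcoxon_paired(a: Sequence[float], b: Sequence[float],
                    alternative: str = "two-sided"):
    """Paired Wilcoxon signed-rank test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = a - b
    method = "exact" if (a.size <= 25 and not np.any(diff == 0)) else "auto"
    return sps.wilcoxon(a, b, alternative=alternative, method=method)


def daily_water_removal(ds: RPMDataset, patient: str, day: int) -> float:
    """Night net UF + day-exchange net UF + diuresis for one patient-day (mL).

    Raises if the patient's diuresis is missing (never imputed).
    """
    rec = ds.records
    sel = rec[(rec["patient_id"] == patient) & (rec["day"] == day)]
    if sel.empty:
        raise ValueError(f"no records for patient {patient} day {day}")
    uf = (sel["drained_ml"] - sel["infused_ml"]).sum()
    row = ds.meta.loc[ds.meta["patient_id"] == patient]
    if "diuresis_ml" not in ds.meta.columns or row["diuresis_ml"].isna().any():
        raise ValueError(f"diuresis missing for patient {patient}; not imputed")
    return float(uf + row["diuresis_ml"].iloc[0])


def patient_summary(ds: RPMDataset, patient: str) -> dict[str, float]:
    """Per-patient medians over days: UF per cycle class, VdrR1/2, day UF."""
    cc = cycle_classes(ds, patient)
    rec = ds.records
    dayx = rec[(rec["patient_id"] == patient) & (rec["phase"] == "day_exchange")]
    night = _night_uf_per_day(ds, patient)
    return {
        "UF_C1": float(cc["UF_C1"].median()),
        "UF_C2": float(cc["UF_C2"].median()),
        "UF_C3plus": float(cc["UF_C3plus"].median()),
        "VdrR1": float(vdr_ratio(ds, patient, 1).median()),
        "VdrR2": float(vdr_ratio(ds, patient, 2).median()),
        "night_UF": float(night.median()) if not night.empty else math.nan,
        "day_UF": float((dayx["drained_ml"] - dayx["infused_ml"]).median())
                  if not dayx.empty else math.nan,
    }


def _night_uf_per_day(ds: RPMDataset, patient: str) -> pd.Series:
    rec = ds.records
    night = rec[(rec["patient_id"] == patient) & (rec["phase"] == "night_cycle")]
    return (night["drained_ml"] - night["infused_ml"]).groupby(night["day"]).sum()


def group_summary(ds: RPMDataset, regimen: str) -> pd.DataFrame:
    """Group median [Q1, Q3] of the per-patient medians, per summary variable."""
    pats = ds.patients_in(regimen)
    per = pd.DataFrame([patient_summary(ds, p) for p in pats], index=pats)
    return per.quantile([0.25, 0.5, 0.75]).T.rename(
        columns={0.25: "Q1", 0.5: "median", 0.75: "Q3"})


@dataclass
class StatsReport:
    """Full analysis output mirroring the clinical tables."""
    group_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova: dict[str, RMANOVAResult | None] = field(default_factory=dict)
    vdr_tests: dict[str, dict] = field(default_factory=dict)
    between_groups: dict[str, dict] = field(default_factory=dict)
    n_patients: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"n_patients": self.n_patients, "group_summaries": {},
               "anova": {}, "vdr_tests": self.vdr_tests,
               "between_groups": self.between_groups}
        for g, df in self.group_summaries.items():
            out["group_summaries"][g] = {
                var: {k: float(v) for k, v in row.items()}
                for var, row in df.iterrows()}
        for g, r in self.anova.items():
            out["anova"][g] = None if r is None else {
                "F": r.f_stat, "df": [r.df_num, r.df_den], "p": r.p_value,
                "posthoc": r.posthoc, "cell_means": r.cell_means,
                "n_subjects": r.n_subjects}
        return out


def analyze(ds: RPMDataset, exclusions: Iterable[tuple] = ()) -> StatsReport:
    """Run the full cycle-statistics pipeline on an RPM dataset.

    Order-invariant in the input records.  Exclusions are applied explicitly
    up front.
    """
    ds = ds.exclude(exclusions) if exclusions else ds
    report = StatsReport()
    vdr_by_group: dict[str, dict[int, list[float]]] = {}
    for reg in ("DD", "WD"):
        pats = ds.patients_in(reg)
        if not pats:
            continue
        report.n_patients[reg] = len(pats)
        report.group_summaries[reg] = group_summary(ds, reg)
        try:
            report.anova[reg] = compare_cycles(ds, reg)
        except ValueError:
            report.anova[reg] = None
        # per-day VdrR values pooled within group, as the clinical analysis
        pooled = {1: [], 2: []}
        per_patient_median = {1: [], 2: []}
        for p in pats:
            for i in (1, 2):
                s = vdr_ratio(ds, p, i)
                pooled[i].extend(s.to_list())
                per_patient_median[i].append(float(s.median()))
        vdr_by_group[reg] = per_patient_median
        tests = {}
        for i in (1, 2):
            res = wilcoxon_vs_unity(pooled[i], alternative="less")
            tests[f"VdrR{i}_vs_unity_p"] = float(res.pvalue)
        res = wilcoxon_paired(per_patient_median[1], per_patient_median[2])
        tests["VdrR1_vs_VdrR2_p"] = float(res.pvalue)
        report.vdr_tests[reg] = tests
    if "DD" in vdr_by_group and "WD" in vdr_by_group:
        for i in (1, 2):
            res = compare_groups(vdr_by_group["DD"][i], vdr_by_group["WD"][i])
            report.between_groups[f"VdrR{i}_DD_vs_WD_p"] = float(res.pvalue)
    return report
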