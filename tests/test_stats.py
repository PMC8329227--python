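"""Cycle statistics: class summaries, VdrR, tests vs brute-force oracles."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peritonsim.stats import (
    CycleRecord, RPMDataset, RECORD_COLUMNS, analyze, compare_cycles,
    compare_groups, cycle_classes, daily_water_removal, net_uf,
    vdr_ratio, wilcoxon_paired, wilcoxon_vs_unity,
)
from peritonsim.synthetic import GeneratorConfig, generate


def make_dataset(sessions, regimen="DD", diuresis=1000.0, day_uf=None):
    """Build an RPMDataset from {patient: {day: [per-cycle net UF]}} with a
    constant infused volume of 1800 mL."""
    rows = []
    for pid, days in sessions.items():
        for day, ufs in days.items():
            for ci, uf in enumerate(ufs, start=1):
                rows.append((pid, day, "night_cycle", ci, 1800.0, 1800.0 + uf,
                             "glucose 1.36%"))
            if day_uf is not None:
                rows.append((pid, day, "day_exchange", 0, 100.0,
                             100.0 + day_uf, "glucose 1.36%"))
    rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    meta = pd.DataFrame({"patient_id": list(sessions), "regimen": regimen,
                         "diuresis_ml": diuresis})
    return RPMDataset(rec, meta)


class TestNetUF:
    @pytest.mark.parametrize("infused,drained,expected", [
        (1800, 1739, -61), (1500, 1500, 0), (2000, 2198, 198)])
    def test_examples(self, infused, drained, expected):
        r = CycleRecord("P1", 1, "night_cycle", 1, infused, drained)
        assert net_uf(r) == expected

    def test_record_validation(self):
        with pytest.raises(ValueError):
            CycleRecord("P1", 1, "night_cycle", 0, 1800, 1800)
        with pytest.raises(ValueError):
            CycleRecord("P1", 1, "nap", 1, 1800, 1800)
        with pytest.raises(ValueError):
            CycleRecord("P1", 1, "night_cycle", 1, -5, 1800)


class TestCycleClasses:
    def test_simple_session(self):
        ds = make_dataset({"P1": {1: [-61, 170, 210, 216]}})
        cc = cycle_classes(ds, "P1")
        assert cc.loc[0, "UF_C1"] == -61
        assert cc.loc[0, "UF_C2"] == 170
        assert cc.loc[0, "UF_C3plus"] == pytest.approx(213.0)

    def test_cap_at_cycle_seven(self):
        # 8-cycle session: C3+ averages cycles 3..7 only
        ufs = [0, 0, 100, 110, 120, 130, 140, 999]
        ds = make_dataset({"P1": {1: ufs}})
        cc = cycle_classes(ds, "P1")
        assert cc.loc[0, "UF_C3plus"] == pytest.approx(np.mean([100, 110, 120, 130, 140]))

    def test_short_sessions_excluded_with_warning(self, caplog):
        ds = make_dataset({"P1": {1: [10, 20], 2: [10, 20, 30]}})
        with caplog.at_level(logging.WARNING, logger="peritonsim.stats"):
            cc = cycle_classes(ds, "P1")
        assert list(cc["day"]) == [2]
        assert "excluded" in caplog.text

    def test_brute_force_recomputation_matches_pipeline(self):
        """Naive per-record loops over a 5-patient synthetic set must agree
        exactly with the grouped pipeline."""
        ds = generate(GeneratorConfig(n_patients_dd=3, n_patients_wd=2,
                                      n_days=6, seed=11))
        rec = ds.records
        for pid in ds.patients:
            got = cycle_classes(ds, pid).set_index("day")
            sub = rec[(rec.patient_id == pid) & (rec.phase == "night_cycle")]
            for day in sorted(sub.day.unique()):
                rows = sub[sub.day == day].sort_values("cycle_index")
                ufs = {int(r.cycle_index): r.drained_ml - r.infused_ml
                       for r in rows.itertuples()}
                if len(ufs) < 3:
                    assert day not in got.index
                    continue
                tail = [v for k, v in ufs.items() if 3 <= k <= 7]
                assert got.loc[day, "UF_C1"] == ufs[1]
                assert got.loc[day, "UF_C2"] == ufs[2]
                assert got.loc[day, "UF_C3plus"] == pytest.approx(sum(tail) / len(tail))
                # drain-volume ratio, recomputed naively
                drains = {int(r.cycle_index): r.drained_ml for r in rows.itertuples()}
                dtail = [v for k, v in drains.items() if 3 <= k <= 7]
                expect = drains[1] / (sum(dtail) / len(dtail))
                assert vdr_ratio(ds, pid, 1)[day] == pytest.approx(expect, rel=1e-12)


class TestVdrRatio:
    def test_identical_drains_give_unity(self):
        ds = make_dataset({"P1": {1: [50, 50, 50, 50, 50]}})
        assert vdr_ratio(ds, "P1", 1)[1] == pytest.approx(1.0)
        assert vdr_ratio(ds, "P1", 2)[1] == pytest.approx(1.0)

    def test_reference_arithmetic(self):
        # (1800 - 61) / (1800 + 213) = 0.864
        ds = make_dataset({"P1": {1: [-61, 170, 213, 213]}})
        assert vdr_ratio(ds, "P1", 1)[1] == pytest.approx(1739 / 2013, rel=1e-12)
        assert vdr_ratio(ds, "P1", 1)[1] == pytest.approx(0.864, abs=5e-4)

    def test_net_uf_variant(self):
        ds = make_dataset({"P1": {1: [100, 200, 200, 200]}})
        assert vdr_ratio(ds, "P1", 1, on="net_uf")[1] == pytest.approx(0.5)

    def test_invalid_arguments(self):
        ds = make_dataset({"P1": {1: [1, 2, 3]}})
        with pytest.raises(ValueError):
            vdr_ratio(ds, "P1", 3)
        with pytest.raises(ValueError):
            vdr_ratio(ds, "P1", 1, on="bogus")


class TestCompareCycles:
    def test_dd_like_data_is_significant(self):
        ds = generate(GeneratorConfig(seed=5))
        res = compare_cycles(ds, "DD")
        assert res.p_value < 0.001
        assert res.posthoc["C1-C3plus"] < 0.05
        assert res.posthoc["C1-C2"] < 0.05
        assert res.cell_means["C1"] < res.cell_means["C3plus"]

    def test_wd_like_data_is_not_significant(self):
        ds = generate(GeneratorConfig(seed=5))
        assert compare_cycles(ds, "WD").p_value > 0.05

    def test_null_data_rejects_at_nominal_rate(self):
        """With no true class effect the omnibus test fires ~5% of the time."""
        null_cfg = dict(class_means_dd=(150.0, 150.0, 150.0),
                        n_patients_dd=6, n_patients_wd=1, n_days=8)
        rejections = sum(
            compare_cycles(generate(GeneratorConfig(seed=s, **null_cfg)),
                           "DD").p_value < 0.05
            for s in range(40))
        assert rejections <= 8  # ~5% nominal; far below the powered case

    def test_omnibus_matches_closed_form_decomposition(self):
        """Dual route: the fitted repeated-measures F equals the classical
        sum-of-squares decomposition computed by hand."""
        ds = generate(GeneratorConfig(seed=13, n_patients_dd=5,
                                      n_patients_wd=2, n_days=5))
        res = compare_cycles(ds, "DD")
        rows = [[cycle_classes(ds, pid)[c].mean()
                 for c in ("UF_C1", "UF_C2", "UF_C3plus")]
                for pid in ds.patients_in("DD")]
        data = np.asarray(rows)
        n, k = data.shape
        grand, cm, sm = data.mean(), data.mean(axis=0), data.mean(axis=1)
        ss_c = n * np.sum((cm - grand) ** 2)
        ss_s = k * np.sum((sm - grand) ** 2)
        ss_e = np.sum((data - grand) ** 2) - ss_c - ss_s
        f = (ss_c / (k - 1)) / (ss_e / ((n - 1) * (k - 1)))
        assert res.f_stat == pytest.approx(float(f), rel=1e-9)
        assert res.p_value == pytest.approx(
            float(sps.f.sf(f, k - 1, (n - 1) * (k - 1))), rel=1e-9)

    def test_insufficient_subjects_rejected(self):
        ds = generate(GeneratorConfig(n_patients_dd=1, n_patients_wd=1,
                                      n_days=4, seed=0))
        with pytest.raises(ValueError):
            compare_cycles(ds, "DD")


def wilcoxon_exact_oracle(diffs, alternative="less"):
    """Exhaustive enumeration of all sign assignments (n <= 7)."""
    d = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    n = d.size
    ws = [float(np.sum(np.compress(signs, ranks)))
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    if alternative == "less":
        return float(np.mean(ws <= w_obs))
    if alternative == "greater":
        return float(np.mean(ws >= w_obs))
    return float(min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs))))


def mannwhitney_exact_oracle(a, b):
    """Exhaustive enumeration of group labelings (n + m small)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = a.size
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    us = []
    for idx in itertools.combinations(range(pooled.size), n):
        r = np.sum(ranks[list(idx)]) - n * (n + 1) / 2
        us.append(float(r))
    us = np.asarray(us)
    mu = n * b.size / 2
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    # continuity for symmetric case: count ties fully on both sides
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(p_lo, p_hi)))


class TestRankTests:
    def test_identical_samples_mann_whitney_p_near_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue > 0.9

    def test_all_unity_ratios_not_significant(self):
        res = wilcoxon_vs_unity([1.0, 1.0, 1.0, 1.0])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wilcoxon_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ratios = 1.0 + rng.normal(-0.05, 0.08, size=6)
        ratios = ratios[ratios != 1.0]
        res = wilcoxon_vs_unity(ratios, alternative="less")
        oracle = wilcoxon_exact_oracle(ratios - 1.0, "less")
        assert res.pvalue == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_mann_whitney_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.9, 0.05, size=6)
        b = rng.normal(1.0, 0.05, size=7)
        res = compare_groups(a, b)
        assert res.pvalue == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-12)

    def test_paired_wilcoxon_small_sample(self):
        a = [0.80, 0.85, 0.86, 0.90, 0.83, 0.88]
        b = [0.95, 0.97, 0.99, 1.00, 0.96, 0.94]
        res = wilcoxon_paired(a, b)
        assert res.pvalue == pytest.approx(1 / 32, abs=1e-12)  # 2 * (1/2^6) * 2

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            wilcoxon_vs_unity([1.0])
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0])


class TestDailyWaterRemoval:
    def test_reference_arithmetic(self):
        ds = make_dataset({"P1": {1: [200, 180, 185]}}, diuresis=1150.0,
                          day_uf=-96.0)
        # night 565 + day -96 + diuresis 1150 = 1619
        assert daily_water_removal(ds, "P1", 1) == pytest.approx(1619.0)

    def test_anuric_patient(self):
        ds = make_dataset({"P1": {1: [100, 100, 100]}}, diuresis=0.0,
                          day_uf=-50.0)
        assert daily_water_removal(ds, "P1", 1) == pytest.approx(250.0)

    def test_missing_diuresis_flagged(self):
        ds = make_dataset({"P1": {1: [100, 100, 100]}}, diuresis=math.nan)
        with pytest.raises(ValueError, match="diuresis"):
            daily_water_removal(ds, "P1", 1)

    def test_naive_loop_oracle_on_synthetic_set(self):
        ds = generate(GeneratorConfig(n_patients_dd=2, n_patients_wd=2,
                                      n_days=4, seed=9))
        rec = ds.records
        for pid in ds.patients:
            diu = float(ds.meta.loc[ds.meta.patient_id == pid, "diuresis_ml"].iloc[0])
            for day in range(1, 5):
                expect = diu + sum(
                    r.drained_ml - r.infused_ml
                    for r in rec.itertuples()
                    if r.patient_id == pid and r.day == day)
                assert daily_water_removal(ds, pid, day) == pytest.approx(expect)


class TestPipeline:
    def test_order_invariance(self):
        ds = generate(GeneratorConfig(n_patients_dd=4, n_patients_wd=4,
                                      n_days=6, seed=21))
        shuffled = RPMDataset(
            ds.records.sample(frac=1.0, random_state=5).reset_index(drop=True),
            ds.meta)
        a, b = analyze(ds).to_dict(), analyze(shuffled).to_dict()
        assert a == b

    def test_explicit_exclusion_changes_day_summary(self):
        ds = generate(GeneratorConfig(n_patients_dd=2, n_patients_wd=2,
                                      n_days=4, seed=2,
                                      inject_abnormal_day_exchange=True))
        rec = ds.records
        abnormal = rec.loc[rec.phase == "day_exchange"].iloc[0]
        pid, day = abnormal["patient_id"], int(abnormal["day"])
        with_abn = analyze(ds).to_dict()
        without = analyze(ds, [(pid, day, "day_exchange")]).to_dict()
        assert with_abn != without
        # the exclusion matches a manual drop of the record
        manual = RPMDataset(rec.drop(abnormal.name).reset_index(drop=True), ds.meta)
        assert analyze(manual).to_dict() == without

    def test_single_regimen_per_patient_enforced(self):
        ds = generate(GeneratorConfig(n_patients_dd=2, n_patients_wd=1,
                                      n_days=2, seed=1))
        meta_dup = pd.concat([ds.meta, ds.meta.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            RPMDataset(ds.records, meta_dup)
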