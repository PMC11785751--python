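from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from nephrodx import (
    AlgorithmConfig,
    BaselineResult,
    BaselineWindow,
    AKIRationale,
    CKDRationale,
    assess_aki,
    assess_ckd,
    diagnose_hospitalization,
    find_index_scr,
    select_baseline,
)
from nephrodx.errors import DataError

from conftest import day, make_timeline, random_timeline


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerates windows day by day, recomputes
# eGFR from its own transcription, and never calls the package's selectors.
# ---------------------------------------------------------------------------

def _oracle_egfr(scr, age, sex):
    k, a = (0.7, -0.329) if sex == "female" else (0.9, -0.411)
    v = 141 * min(scr / k, 1) ** a * max(scr / k, 1) ** -1.209 * 0.993 ** age
    return v * 1.018 if sex == "female" else v


def oracle_diagnose(tl, ep, cfg):
    labs = sorted(tl.labs, key=lambda r: (r.collected_at, r.scr))
    in_ep = [r for r in labs if ep.admit_date <= r.collected_at <= ep.discharge_date]

    # --- AKI ---
    abnormal = [r for r in in_ep if r.scr > cfg.scr_abnormal_threshold]
    aki = None
    if abnormal:
        top = max(r.scr for r in abnormal)
        idx = min((r for r in abnormal if r.scr == top), key=lambda r: r.collected_at)
        baseline = None
        for off in range(1, cfg.acute_window_days + 1):
            hits = [r for r in labs if r.collected_at == idx.collected_at - timedelta(days=off)]
            for r in hits:
                if baseline is None or r.scr < baseline[0]:
                    baseline = (r.scr, "D1_7")
        if baseline is None:
            for off in range(cfg.acute_window_days + 1, cfg.chronicity_days + 1):
                hits = [r for r in labs
                        if r.collected_at == idx.collected_at - timedelta(days=off)]
                for r in hits:
                    if baseline is None or r.scr < baseline[0]:
                        baseline = (r.scr, "D8_90")
        if baseline is None:
            old = [r for r in labs
                   if (idx.collected_at - r.collected_at).days > cfg.chronicity_days]
            if old:
                last_day = max(r.collected_at for r in old)
                val = min(r.scr for r in old if r.collected_at == last_day)
                baseline = (val, "D_GT90")
        if baseline is None:
            aki = (True, idx.collected_at, None, "NONE")
        else:
            ratio = idx.scr / baseline[0]
            pos = ratio > cfg.aki_ratio_threshold if cfg.ratio_strict \
                else ratio >= cfg.aki_ratio_threshold
            aki = (pos, idx.collected_at, baseline[0], baseline[1])

    # --- CKD ---
    sex, age = tl.demographics.sex, tl.demographics.age_years
    ckd = None
    low = [r for r in in_ep if _oracle_egfr(r.scr, age, sex) < cfg.egfr_threshold]
    if low:
        ckd_idx = min(r.collected_at for r in low)
        old = [r for r in labs if (ckd_idx - r.collected_at).days > cfg.chronicity_days]
        if not old:
            ckd = (False, ckd_idx)
        else:
            last_day = max(r.collected_at for r in old)
            val = min(r.scr for r in old if r.collected_at == last_day)
            ckd = (_oracle_egfr(val, age, sex) < cfg.egfr_threshold, ckd_idx)
    return aki, ckd


def summarize(diag):
    aki = None
    if diag.aki is not None:
        a = diag.aki
        aki = (a.positive, a.index_date,
               None if a.baseline.assumed_normal else a.baseline.value,
               a.baseline.window.value)
    ckd = None
    if diag.ckd is not None:
        ckd = (diag.ckd.positive, diag.ckd.index_date)
    return aki, ckd


# ---------------------------------------------------------------------------
# find_index_scr
# ---------------------------------------------------------------------------

class TestFindIndex:
    def test_max_with_earliest_tie(self, cfg):
        tl = make_timeline([(1, 1.2), (2, 1.4), (3, 2.0), (4, 2.0)])
        assert find_index_scr(tl, tl.episodes[0], cfg) == (day(3), 2.0)

    def test_absent_when_all_at_or_below_threshold(self, cfg):
        tl = make_timeline([(1, 1.3), (2, 1.1)])
        assert find_index_scr(tl, tl.episodes[0], cfg) is None

    def test_out_of_episode_records_ignored(self, cfg):
        tl = make_timeline([(-5, 9.0), (2, 1.5), (12, 9.0)], episode=(0, 10))
        assert find_index_scr(tl, tl.episodes[0], cfg) == (day(2), 1.5)

    def test_matches_brute_force_scan(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(100):
            tl = random_timeline(rng)
            ep = tl.episodes[0]
            got = find_index_scr(tl, ep, cfg)
            eligible = [r for r in tl.labs
                        if ep.admit_date <= r.collected_at <= ep.discharge_date
                        and r.scr > cfg.scr_abnormal_threshold]
            if not eligible:
                assert got is None
            else:
                top = max(r.scr for r in eligible)
                first = min(r.collected_at for r in eligible if r.scr == top)
                assert got == (first, top)


# ---------------------------------------------------------------------------
# select_baseline
# ---------------------------------------------------------------------------

class TestSelectBaseline:
    def test_acute_window_takes_precedence(self, cfg):
        tl = make_timeline([(-2, 1.2), (-5, 1.0), (-30, 0.8)])
        b = select_baseline(tl, day(0), cfg)
        assert (b.value, b.window, b.source_date) == (1.0, BaselineWindow.D1_7, day(-5))

    def test_subacute_when_acute_empty(self, cfg):
        tl = make_timeline([(-30, 0.8), (-60, 1.4)])
        b = select_baseline(tl, day(0), cfg)
        assert (b.value, b.window) == (0.8, BaselineWindow.D8_90)

    def test_nearest_beyond_chronicity(self, cfg):
        tl = make_timeline([(-100, 1.1), (-150, 0.7)])
        b = select_baseline(tl, day(0), cfg)
        assert (b.value, b.window, b.source_date) == (1.1, BaselineWindow.D_GT90, day(-100))

    def test_assumed_normal_without_history(self, cfg):
        tl = make_timeline([(0, 2.0)])
        b = select_baseline(tl, day(0), cfg)
        assert b.assumed_normal and b.window is BaselineWindow.NONE

    def test_any_window_mode_takes_global_minimum(self):
        cfg = AlgorithmConfig(window_mode="any_window")
        tl = make_timeline([(-2, 1.2), (-30, 0.8), (-100, 0.5)])
        b = select_baseline(tl, day(0), cfg)
        assert (b.value, b.window) == (0.5, BaselineWindow.D_GT90)

    def test_beyond_window_record_cannot_change_recent_baseline(self, cfg):
        """Adding history older than 90 days never alters a D1-7/D8-90 pick."""
        rng = np.random.default_rng(5)
        from nephrodx import LabRecord, PatientTimeline
        for _ in range(50):
            tl = random_timeline(rng)
            before = select_baseline(tl, day(0), cfg)
            if before.window not in (BaselineWindow.D1_7, BaselineWindow.D8_90):
                continue
            extra = LabRecord(collected_at=day(-int(rng.integers(91, 400))),
                              scr=0.01 + float(rng.uniform(0, 3)),
                              patient_id=tl.patient_id)
            tl2 = PatientTimeline(demographics=tl.demographics,
                                  labs=tl.labs + [extra], episodes=tl.episodes)
            assert select_baseline(tl2, day(0), cfg) == before


# ---------------------------------------------------------------------------
# assess_aki / assess_ckd
# ---------------------------------------------------------------------------

class TestAssessAKI:
    def _baseline(self, value):
        return BaselineResult(value=value, window=BaselineWindow.D1_7,
                              source_date=day(-1))

    def test_clear_rise_positive(self, cfg):
        a = assess_aki(day(0), 2.0, self._baseline(1.0), cfg)
        assert a.positive and a.ratio == pytest.approx(2.0)
        assert a.rationale is AKIRationale.RATIO_MET

    def test_small_rise_negative(self, cfg):
        a = assess_aki(day(0), 1.6, self._baseline(1.4), cfg)
        assert not a.positive and a.ratio == pytest.approx(1.6 / 1.4)

    def test_dialysis_trough_baseline_fires(self, cfg):
        # the documented false-positive mechanism: inter-dialytic trough as baseline
        a = assess_aki(day(0), 3.5, self._baseline(1.9), cfg)
        assert a.positive

    def test_exact_threshold_depends_on_strictness(self):
        lax, strict = AlgorithmConfig(), AlgorithmConfig(ratio_strict=True)
        b = self._baseline(1.0)
        assert assess_aki(day(0), 1.5, b, lax).positive
        assert not assess_aki(day(0), 1.5, b, strict).positive

    def test_assumed_normal_is_positive(self, cfg):
        a = assess_aki(day(0), 1.5, BaselineResult.assumed_normal_result(), cfg)
        assert a.positive and a.ratio is None
        assert a.rationale is AKIRationale.NO_PRIOR_RECORDS

    def test_nonpositive_baseline_rejected(self, cfg):
        with pytest.raises(ValueError):
            BaselineResult(value=None, window=BaselineWindow.D1_7, source_date=day(-1))
        with pytest.raises(DataError):
            assess_aki(day(0), 2.0, self._baseline(1.0).__class__(
                value=-1.0, window=BaselineWindow.D1_7, source_date=day(-1)), cfg)


class TestAssessCKD:
    def test_low_prior_egfr_positive(self, cfg):
        # scr 1.6 at 70 M ~ eGFR 43 < 60, 120 days before the abnormal index
        tl = make_timeline([(-120, 1.6), (0, 2.0)])
        c = assess_ckd(tl, day(0), cfg)
        assert c.positive and c.evidence_date == day(-120)
        assert c.rationale is CKDRationale.PRIOR_LOW_EGFR_BEYOND_90D

    def test_normal_prior_egfr_negative(self, cfg):
        # scr 0.9 at 70 M ~ eGFR 86 >= 60
        tl = make_timeline([(-120, 0.9), (0, 2.0)])
        c = assess_ckd(tl, day(0), cfg)
        assert not c.positive
        assert c.rationale is CKDRationale.PRIOR_NORMAL_EGFR_BEYOND_90D

    def test_no_prior_records_negative(self, cfg):
        tl = make_timeline([(0, 2.0), (-30, 2.0)])
        c = assess_ckd(tl, day(0), cfg)
        assert not c.positive and c.rationale is CKDRationale.NO_PRIOR_RECORDS

    def test_most_recent_beyond_window_record_decides(self, cfg):
        # low eGFR at -200 d but normal at -100 d: least-stale evidence wins
        tl = make_timeline([(-200, 2.5), (-100, 0.9), (0, 2.0)])
        assert not assess_ckd(tl, day(0), cfg).positive
        tl = make_timeline([(-200, 0.9), (-100, 2.5), (0, 2.0)])
        assert assess_ckd(tl, day(0), cfg).positive


# ---------------------------------------------------------------------------
# diagnose_hospitalization
# ---------------------------------------------------------------------------

class TestDiagnose:
    def test_no_abnormal_scr_skips_both_assessments(self, cfg):
        tl = make_timeline([(1, 1.0), (2, 1.2)], age=40)
        d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
        assert d.aki is None and d.ckd is None

    def test_toy_rise_with_subacute_baseline(self, cfg):
        # prior 1.0 at -30 d; in-episode rise 1.4 -> 2.2 on consecutive days
        tl = make_timeline([(-30, 1.0), (3, 1.4), (4, 2.2)])
        d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
        a = d.aki
        assert a.positive and a.index_date == day(4) and a.index_scr == 2.2
        # 1.4 one day earlier sits in the acute window; 2.2/1.4 >= 1.5 fires
        assert a.baseline.window is BaselineWindow.D1_7 and a.baseline.value == 1.4
        assert d.ckd is not None and not d.ckd.positive

    def test_chronic_stable_patient_is_ckd_not_aki(self, cfg):
        tl = make_timeline([(-150, 2.5), (-100, 2.5), (-50, 2.5), (1, 2.5), (2, 2.5)])
        d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
        assert not d.aki.positive and d.aki.ratio == pytest.approx(1.0)
        assert d.ckd.positive

    def test_exclude_dialysis_flag_gates_aki_only(self):
        cfg = AlgorithmConfig(exclude_dialysis=True)
        tl = make_timeline([(-120, 4.0), (1, 3.0), (2, 6.0)], dialysis=True)
        d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
        assert d.aki is None and d.ckd.positive

    def test_monotone_in_index_scr(self, cfg):
        """Raising the peak creatinine can never flip AKI positive -> negative."""
        from nephrodx import LabRecord, PatientTimeline
        rng = np.random.default_rng(9)
        for _ in range(100):
            tl = random_timeline(rng)
            d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
            if d.aki is None or not d.aki.positive:
                continue
            boosted = [LabRecord(collected_at=r.collected_at,
                                 scr=r.scr * 2 if r.collected_at == d.aki.index_date
                                 and r.scr == d.aki.index_scr else r.scr,
                                 patient_id=r.patient_id) for r in tl.labs]
            tl2 = PatientTimeline(demographics=tl.demographics, labs=boosted,
                                  episodes=tl.episodes)
            d2 = diagnose_hospitalization(tl2, tl2.episodes[0], cfg)
            assert d2.aki is not None and d2.aki.positive

    def test_permutation_invariance(self, cfg):
        from nephrodx import PatientTimeline
        rng = np.random.default_rng(13)
        for _ in range(30):
            tl = random_timeline(rng)
            shuffled = list(tl.labs)
            rng.shuffle(shuffled)
            tl2 = PatientTimeline(demographics=tl.demographics, labs=shuffled,
                                  episodes=tl.episodes)
            assert summarize(diagnose_hospitalization(tl, tl.episodes[0], cfg)) == \
                summarize(diagnose_hospitalization(tl2, tl2.episodes[0], cfg))

    def test_always_low_egfr_with_old_history_is_ckd_positive(self, cfg):
        """Uniformly eGFR<60 with earliest record >90 d old must always call CKD."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            offsets = sorted(set([-int(rng.integers(91, 300))]
                                 + [int(o) for o in rng.integers(-250, 10, 6)]))
            labs = [(o, float(rng.uniform(2.5, 6.0))) for o in offsets]  # eGFR << 60
            tl = make_timeline(labs, age=float(rng.uniform(40, 90)))
            d = diagnose_hospitalization(tl, tl.episodes[0], cfg)
            if d.ckd is not None:
                assert d.ckd.positive

    def test_matches_independent_oracle(self, cfg):
        rng = np.random.default_rng(23)
        for _ in range(300):
            tl = random_timeline(rng)
            got = summarize(diagnose_hospitalization(tl, tl.episodes[0], cfg))
            assert got == oracle_diagnose(tl, tl.episodes[0], cfg)
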