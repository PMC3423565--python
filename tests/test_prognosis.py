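"""Prognostic score and transplant guideline.

The subscore grid is checked against an independently hand-coded lookup
table over every cut point +/- epsilon; the guideline is checked against a
brute-force criterion counter on 10,000 random records.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alf_triage import (ComaGrade, MissingDataError, PrognosisConfig,
                        mortality_band, reassess_day5, score_component,
                        total_score, transplant_candidate_initial)
from alf_triage.errors import ConfigError, PreconditionError
from alf_triage.prognosis import partial_score_range

from conftest import make_record

# Independent oracle: literal value -> subscore lookups at each cut point
# and on either side of it (never computed from the implementation).
ORACLE = {
    "oc_days": {0: 0, 5: 0, 6: 1, 10: 1, 11: 2, 40: 2},
    "pt": {1.0: 2, 4.99: 2, 5.0: 2, 5.01: 1, 20.0: 1, 20.01: 0, 39.0: 0},
    "tb": {0.0: 0, 9.99: 0, 10.0: 1, 14.99: 1, 15.0: 2, 30.0: 2},
    "dt_ratio": {0.1: 2, 0.49: 2, 0.5: 1, 0.69: 1, 0.7: 0, 0.9: 0},
    "plt": {0.5: 2, 4.99: 2, 5.0: 2, 5.01: 1, 10.0: 1, 10.01: 0, 30.0: 0},
    "atrophy": {False: 0, True: 1},
}


class TestScoreComponent:
    @pytest.mark.parametrize("param", sorted(ORACLE))
    def test_matches_oracle_at_every_cut_point(self, param):
        for value, expected in ORACLE[param].items():
            assert score_component(param, value) == expected, (param, value)

    def test_exhaustive_grid_total_matches_oracle_sum(self):
        """Over the full product grid (all parameters at cut points +/- eps)
        the total equals the oracle sum and stays in [0, 11]."""
        params = sorted(ORACLE)
        for combo in itertools.product(*(ORACLE[p].items() for p in params)):
            total = sum(score_component(p, v) for p, (v, _) in zip(params, combo))
            expected = sum(e for _, (_, e) in zip(params, combo))
            assert total == expected
            assert 0 <= total <= 11

    def test_missing_value_refused(self):
        with pytest.raises(MissingDataError):
            score_component("pt", None)

    def test_atrophy_weight_configurable(self):
        cfg = PrognosisConfig(atrophy_max_subscore=2)
        assert score_component("atrophy", True, cfg) == 2
        assert score_component("atrophy", True) == 1


class TestTotalScore:
    def test_all_maximum_case(self):
        rec = make_record(onset_to_encephalopathy_days=12, pt_percent=4.0,
                          inr=None, total_bilirubin=16.0, direct_bilirubin=6.4,
                          platelets=4.0, liver_atrophy=True)
        ps = total_score(rec)
        assert ps.total == 11
        assert ps.death_call is True
        assert ps.band.lower_percent == 90.0

    def test_all_minimum_case(self):
        rec = make_record(onset_to_encephalopathy_days=3, pt_percent=35.0,
                          inr=None, total_bilirubin=5.0, direct_bilirubin=4.0,
                          platelets=15.0, liver_atrophy=False)
        ps = total_score(rec)
        assert ps.total == 0
        assert ps.death_call is False

    def test_death_threshold_at_5(self):
        # oc 11d (2) + pt 18 (1) + tb 12 (1) + dt 0.6 (1) + plt 15 (0) = 5
        rec = make_record(onset_to_encephalopathy_days=11, pt_percent=18.0,
                          inr=None, total_bilirubin=12.0, direct_bilirubin=7.2,
                          platelets=15.0, liver_atrophy=False)
        ps = total_score(rec)
        assert ps.total == 5 and ps.death_call is True
        looser = PrognosisConfig(death_threshold=6)
        assert total_score(rec, looser).death_call is False

    def test_missing_parameters_listed(self):
        rec = make_record(platelets=None, liver_atrophy=None)
        with pytest.raises(MissingDataError) as exc:
            total_score(rec)
        assert set(exc.value.missing) == {"plt", "atrophy"}

    def test_requires_coma_grade_ii(self):
        rec = make_record(coma_grade=ComaGrade.I,
                          onset_to_encephalopathy_days=None)
        with pytest.raises(PreconditionError):
            total_score(rec)

    def test_partial_range_brackets_missing_parameters(self):
        rec = make_record(platelets=None, liver_atrophy=None)
        lo, hi, missing = partial_score_range(rec)
        # observed: oc 7d (1) + pt 30 (0) + tb 12 (1) + dt 0.6 (1) = 3
        assert (lo, hi) == (3, 3 + 2 + 1)
        assert set(missing) == {"plt", "atrophy"}

    @given(st.integers(0, 40), st.floats(1, 40), st.floats(0.5, 30),
           st.floats(0.1, 0.9), st.floats(0.5, 30), st.booleans(),
           st.sampled_from(["oc_days", "pt", "tb", "dt_ratio", "plt", "atrophy"]))
    @settings(max_examples=300, derandomize=True)
    def test_worsening_one_parameter_never_lowers_total(
            self, oc, pt, tb, dt, plt, atrophy, worsen):
        def build(oc, pt, tb, dt, plt, atrophy):
            return make_record(
                onset_to_encephalopathy_days=oc, pt_percent=round(pt, 2),
                inr=None, total_bilirubin=round(tb, 2),
                direct_bilirubin=round(tb * dt, 3), platelets=round(plt, 2),
                liver_atrophy=atrophy)

        base = total_score(build(oc, pt, tb, dt, plt, atrophy)).total
        worse_args = dict(oc=oc, pt=pt, tb=tb, dt=dt, plt=plt, atrophy=atrophy)
        # direction of "worse": longer interval, lower PT/DT/PLT, higher TB
        worse_args.update({
            "oc_days": {"oc": oc + 10}, "pt": {"pt": max(pt / 2, 1)},
            "tb": {"tb": tb + 10}, "dt_ratio": {"dt": dt / 2},
            "plt": {"plt": max(plt / 2, 0.5)}, "atrophy": {"atrophy": True},
        }[worsen])
        worse = total_score(build(**worse_args)).total
        assert worse >= base


class TestMortalityBand:
    @pytest.mark.parametrize("total,lower,upper", [
        (0, 0, 30), (3, 0, 30),
        (4, 50, 60), (5, 70, 80), (6, 80, 90),
        (7, 90, 100), (11, 90, 100),
    ])
    def test_printed_bands(self, total, lower, upper):
        band = mortality_band(total)
        assert (band.lower_percent, band.upper_percent) == (lower, upper)

    def test_lower_bound_non_decreasing(self):
        lowers = [mortality_band(t).lower_percent for t in range(12)]
        assert lowers == sorted(lowers)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mortality_band(12)
        with pytest.raises(ValueError):
            mortality_band(-1)

    def test_band_table_must_partition(self):
        with pytest.raises(ConfigError):
            PrognosisConfig(bands=((0, 3, mortality_band(0)),))


class TestGuideline:
    def test_two_criteria_make_a_candidate(self):
        rec = make_record(age_years=50, onset_to_encephalopathy_days=12,
                          pt_percent=30.0, total_bilirubin=10.0,
                          direct_bilirubin=8.0)
        a = transplant_candidate_initial(rec)
        assert a.criteria_met == {"age", "interval"}
        assert a.n_met == 2 and a.candidate is True

    def test_no_criterion_met(self):
        rec = make_record(age_years=30, onset_to_encephalopathy_days=5,
                          pt_percent=15.0, total_bilirubin=10.0,
                          direct_bilirubin=8.0)
        a = transplant_candidate_initial(rec)
        assert a.n_met == 0 and a.candidate is False

    def test_boundary_strictness_matches_printed_inequalities(self):
        # age >=45 and interval >=11 and TB >=18.0 are inclusive;
        # PT <10 and D/T <0.67 are strict, so the exact boundary fails them
        rec = make_record(age_years=45, onset_to_encephalopathy_days=11,
                          pt_percent=10.0, total_bilirubin=18.0,
                          direct_bilirubin=12.06)  # D/T exactly 0.67
        a = transplant_candidate_initial(rec)
        assert a.criteria_met == {"age", "interval", "bilirubin"}
        assert a.n_met == 3

    def test_requires_coma_and_complete_data(self):
        no_coma = make_record(coma_grade=ComaGrade.I,
                              onset_to_encephalopathy_days=None)
        with pytest.raises(PreconditionError):
            transplant_candidate_initial(no_coma)
        partial = make_record(total_bilirubin=None, direct_bilirubin=None)
        with pytest.raises(MissingDataError):
            transplant_candidate_initial(partial)

    def test_brute_force_over_random_records(self):
        """candidate is true iff >= 2 of the 5 printed criteria hold, over
        10,000 random records (criteria re-counted independently here)."""
        rng = np.random.default_rng(20260930)
        n = 10_000
        age = rng.integers(18, 90, n)
        interval = rng.integers(0, 40, n)
        pt = np.round(rng.uniform(1, 40, n), 1)
        tb = np.round(rng.uniform(1, 30, n), 1)
        dt = np.round(rng.uniform(0.1, 0.9, n), 2)
        for i in range(n):
            rec = make_record(age_years=int(age[i]),
                              onset_to_encephalopathy_days=int(interval[i]),
                              pt_percent=float(pt[i]), inr=None,
                              total_bilirubin=float(tb[i]),
                              direct_bilirubin=float(np.round(tb[i] * dt[i], 4)))
            brute = sum([bool(age[i] >= 45), bool(interval[i] >= 11),
                         bool(pt[i] < 10), bool(tb[i] >= 18.0),
                         rec.labs.dt_ratio < 0.67])
            a = transplant_candidate_initial(rec)
            assert a.n_met == brute
            assert a.candidate == (brute >= 2)


class TestDay5Reassessment:
    def candidate(self, **overrides):
        rec = make_record(age_years=50, onset_to_encephalopathy_days=12,
                          coma_grade=ComaGrade.IV, **overrides)
        return transplant_candidate_initial(rec)

    def test_two_grade_attenuation_and_pt_over_50_revises_to_alive(self):
        a = reassess_day5(self.candidate(), ComaGrade.IV, ComaGrade.II, 60.0)
        assert a.day5.coma_improved and a.day5.pt_improved
        assert a.day5.reassessed_alive is True
        assert a.predicted_death is False

    def test_single_grade_attenuation_insufficient(self):
        a = reassess_day5(self.candidate(), ComaGrade.III, ComaGrade.II, 60.0)
        assert a.day5.reassessed_alive is False
        assert a.predicted_death is True

    def test_pt_boundary_is_strictly_over_50(self):
        a = reassess_day5(self.candidate(), ComaGrade.IV, ComaGrade.I, 50.0)
        assert a.day5.coma_improved is True
        assert a.day5.reassessed_alive is False

    def test_improvement_to_grade_i_or_less_suffices(self):
        a = reassess_day5(self.candidate(), ComaGrade.II, ComaGrade.I, 55.0)
        assert a.day5.reassessed_alive is True

    def test_only_flips_death_toward_alive(self):
        """Reassessment never turns a non-candidate into a death call, and
        never raises a candidate's risk: predicted_death can only go
        True -> False."""
        non_candidate = transplant_candidate_initial(
            make_record(age_years=30, onset_to_encephalopathy_days=5,
                        pt_percent=15.0))
        assert non_candidate.predicted_death is False
        with pytest.raises(PreconditionError):
            reassess_day5(non_candidate, ComaGrade.II, ComaGrade.I, 60.0)
        rng = np.random.default_rng(7)
        for _ in range(200):
            onset = ComaGrade(int(rng.integers(2, 6)))
            day5 = ComaGrade(int(rng.integers(0, 6)))
            pt5 = float(rng.uniform(10, 90))
            a = reassess_day5(self.candidate(), onset, day5, pt5)
            assert a.candidate is True           # candidacy facts unchanged
            expected_alive = (day5 <= ComaGrade.I or onset - day5 >= 2) and pt5 > 50
            assert a.predicted_death == (not expected_alive)
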