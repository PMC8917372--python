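"""The five indicators, the additive score and the performance outcome."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nurselabor as nl
from nurselabor.exceptions import DomainError, ValidationError
from nurselabor.precarity import FLAG_COLUMNS, PrecarityComponents


def _worker(income=3.0, hours=40.0, contract=1, benefit=1, ss=1, working=1):
    return dict(working=working, income_mw=income, weekly_hours=hours,
                written_contract=contract, any_social_benefit=benefit,
                ss_health_access=ss)


class TestComponents:
    @pytest.mark.parametrize("record,flags", [
        (_worker(income=1.5), (1, 0, 0, 0, 0)),          # low salary only
        (_worker(income=2.0), (1, 0, 0, 0, 0)),          # boundary inclusive
        (_worker(hours=33.9), (0, 1, 0, 0, 0)),          # part-time
        (_worker(hours=48.0), (0, 0, 0, 0, 0)),          # 34-48 h unflagged
        (_worker(hours=48.5), (0, 1, 0, 0, 0)),          # extended time
        (_worker(income=1.0, hours=10, contract=0, benefit=0, ss=0),
         (1, 1, 1, 1, 1)),                               # all adverse
        (_worker(), (0, 0, 0, 0, 0)),                    # fully protected
    ])
    def test_indicator_rules(self, record, flags):
        comp = nl.precarity_components(record)
        got = (comp.salary_flag, comp.workday_flag, comp.contract_flag,
               comp.benefits_flag, comp.social_security_flag)
        assert got == flags
        assert comp.score == sum(flags)

    def test_non_working_out_of_domain(self):
        with pytest.raises(DomainError):
            nl.precarity_components(_worker(working=0))

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            nl.precarity_components(_worker(income=-1.0))
        with pytest.raises(ValidationError):
            nl.precarity_components(_worker(hours=-2.0))

    @given(income=st.floats(0, 12), hours=st.floats(0, 90),
           contract=st.booleans(), benefit=st.booleans(), ss=st.booleans())
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_single_field_worsening(self, income, hours,
                                                contract, benefit, ss):
        """Worsening any one raw field never decreases the score."""
        base = _worker(income, hours, int(contract), int(benefit), int(ss))
        score = nl.precarity_components(base).score
        worse = [
            _worker(min(income, 1.0), hours, int(contract), int(benefit), int(ss)),
            _worker(income, 10.0, int(contract), int(benefit), int(ss)),
            _worker(income, hours, 0, int(benefit), int(ss)),
            _worker(income, hours, int(contract), 0, int(ss)),
            _worker(income, hours, int(contract), int(benefit), 0),
        ]
        for record in worse:
            assert nl.precarity_components(record).score >= score


class TestLevelAndOutcome:
    @pytest.mark.parametrize("score,cut,level", [
        (0, 1, "non_or_low"), (0, 5, "non_or_low"), (2, 3, "non_or_low"),
        (3, 3, "high"), (5, 3, "high"), (5, 5, "high"), (2, 2, "high"),
    ])
    def test_level_cut(self, score, cut, level):
        assert nl.classify_precarity_level(score, cut) == level

    def test_level_validation(self):
        with pytest.raises(ValidationError):
            nl.classify_precarity_level(6, 3)
        with pytest.raises(ValidationError):
            nl.classify_precarity_level(2, 0)

    def test_high_share_monotone_in_cut(self, small_sample, design):
        """Raising the cut can only shrink the 'highly precarious' share."""
        sample, _ = small_sample
        workers = sample[sample["working"] == 1]
        shares = [
            (workers["score"].astype(int) >= cut).mean()
            for cut in range(1, 6)
        ]
        assert all(a >= b for a, b in zip(shares, shares[1:]))

    def test_outcome_rules(self):
        comp0 = nl.precarity_components(_worker())
        comp2 = nl.precarity_components(_worker(income=1.0, contract=0))
        assert comp2.score == 2
        assert nl.market_performance_outcome({}, comp0, "employed_health") == 1
        assert nl.market_performance_outcome({}, comp2, "employed_health") == 0
        assert nl.market_performance_outcome({}, comp0, "underemployed") == 0
        with pytest.raises(DomainError):
            nl.market_performance_outcome({}, comp0, "unemployed")


class TestVectorizedScoring:
    def test_matches_bruteforce_on_random_records(self):
        """Vectorized score equals the per-record flag sum on 10,000
        independently drawn records (exact match)."""
        rng = np.random.default_rng(1234)
        n = 10_000
        df = pd.DataFrame({
            "working": 1,
            "income_mw": np.round(rng.uniform(0, 8, n), 3),
            "weekly_hours": np.round(rng.uniform(0, 90, n), 1),
            "written_contract": rng.integers(0, 2, n),
            "any_social_benefit": rng.integers(0, 2, n),
            "ss_health_access": rng.integers(0, 2, n),
            "labor_status": rng.choice(["underemployed", "employed_health"], n),
        })
        scored = nl.add_precarity_columns(df)
        for i in range(n):
            comp = nl.precarity_components(df.iloc[i])
            assert scored["score"].iloc[i] == comp.score
            expected_flags = (comp.salary_flag, comp.workday_flag,
                              comp.contract_flag, comp.benefits_flag,
                              comp.social_security_flag)
            got = tuple(int(scored[c].iloc[i]) for c in FLAG_COLUMNS)
            assert got == expected_flags
        # outcome: 1 iff employed in health sector with zero score
        expected_outcome = ((df["labor_status"] == "employed_health")
                            & (scored["score"] == 0)).astype(int)
        assert (scored["non_precarious_employment"].astype(int)
                == expected_outcome).all()

    def test_score_is_flag_sum_and_bounded(self, small_sample):
        sample, _ = small_sample
        working = sample[sample["working"] == 1]
        flagsum = sum(working[c].astype(int) for c in FLAG_COLUMNS)
        assert (working["score"].astype(int) == flagsum).all()
        assert working["score"].astype(int).between(0, 5).all()
        assert sample.loc[sample["working"] == 0, "score"].isna().all()

    def test_nonprecarious_iff_score_zero(self, small_sample):
        sample, _ = small_sample
        employed = sample[sample["labor_status"] == "employed_health"]
        assert ((employed["non_precarious_employment"] == 1)
                == (employed["score"] == 0)).all()
        under = sample[sample["labor_status"] == "underemployed"]
        assert (under["non_precarious_employment"] == 0).all()


def test_income_conversion_real_data_path():
    mw_table = {2005: 45.24}
    assert nl.income_to_mw(90.48, 2005, mw_table) == pytest.approx(2.0)
    with pytest.raises(DomainError):
        nl.income_to_mw(100.0, 2004, mw_table)
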