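"""Dose equations, hazard quotients/indices, cancer risk and the risk table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aquarisk as aq
from aquarisk.exceptions import ConfigurationError, DomainError, ParameterError
from aquarisk.risk_core import render_bank_summary

from conftest import TABLE_STATS, make_table

AS_TOX = aq.DEFAULT_TOXICITY["As"]


class TestDoseEquations:
    @pytest.mark.parametrize(
        "cw, profile, expected",
        [
            (8.52, aq.ADULT, 2.880e-4),   # As maximum
            (1.61, aq.ADULT, 5.443e-5),   # As mean
            (0.0, aq.ADULT, 0.0),
            (0.0, aq.KID, 0.0),
        ],
    )
    def test_ingestion_dose(self, cw, profile, expected):
        assert aq.daily_dose_ingestion(cw, profile) == pytest.approx(expected, rel=5e-4)

    @pytest.mark.parametrize(
        "cw, profile, expected",
        [
            (8.52, aq.ADULT, 1.0867e-6),
            (8.52, aq.KID, 1.9326e-6),
            (0.0, aq.ADULT, 0.0),
        ],
    )
    def test_dermal_dose(self, cw, profile, expected):
        assert aq.daily_dose_dermal(cw, profile) == pytest.approx(expected, rel=5e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            aq.daily_dose_ingestion(-1.0, aq.ADULT)
        with pytest.raises(DomainError):
            aq.daily_dose_dermal(-0.5, aq.KID)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ParameterError):
            aq.ExposureProfile("bad", BW=0, AT=1, EF=1, IR=1, ABS_GI=1,
                               ED=1, KP=1, ET=1, SA=1)
        with pytest.raises(ParameterError):
            aq.ExposureProfile("bad", BW=60, AT=1, EF=400, IR=1, ABS_GI=1,
                               ED=1, KP=1, ET=1, SA=1)

    @pytest.mark.parametrize(
        "rfd, abs_gi, expected",
        [(0.003, 1.0, 0.003), (0.0003, 0.41, 1.23e-4), (0.005, 1.0, 0.005)],
    )
    def test_dermal_rfd_from_drinking(self, rfd, abs_gi, expected):
        assert aq.rfd_dermal_from_drinking(rfd, abs_gi) == pytest.approx(expected)

    def test_dermal_rfd_requires_positive(self):
        with pytest.raises(ParameterError):
            aq.rfd_dermal_from_drinking(0.0, 1.0)


class TestHazardAndCancer:
    @staticmethod
    def _hq(cw, profile, tox):
        return aq.hazard_quotient(
            aq.daily_dose_ingestion(cw, profile),
            aq.daily_dose_dermal(cw, profile), tox)

    def test_as_hq_adult_at_maximum(self):
        assert self._hq(8.52, aq.ADULT, AS_TOX) == pytest.approx(0.9690, abs=5e-5)

    def test_as_hq_kid_at_maximum(self):
        assert self._hq(8.52, aq.KID, AS_TOX) == pytest.approx(1.37, abs=5e-3)

    def test_zero_concentration_gives_zero_hq(self):
        for tox in aq.DEFAULT_TOXICITY.values():
            assert self._hq(0.0, aq.ADULT, tox) == 0.0

    def test_hazard_index_sums(self):
        assert aq.hazard_index([0.0] * 7) == 0.0
        assert aq.hazard_index([0.9690]) == 0.9690
        with pytest.raises(DomainError):
            aq.hazard_index([])

    def test_hazard_index_at_mean_concentrations(self):
        hqs = [self._hq(TABLE_STATS[m][0], aq.ADULT, aq.DEFAULT_TOXICITY[m])
               for m in aq.METALS]
        assert aq.hazard_index(hqs) == pytest.approx(0.210, abs=1.5e-3)

    def test_cr_adult_cr_at_cr_maximum(self):
        cr = aq.cancer_risk(aq.daily_dose_ingestion(2.26, aq.ADULT),
                            aq.daily_dose_dermal(2.26, aq.ADULT),
                            aq.DEFAULT_TOXICITY["Cr"])
        assert cr == pytest.approx(31.44e-4, abs=5e-7)

    def test_as_kid_cr_at_maximum(self):
        cr = aq.cancer_risk(aq.daily_dose_ingestion(8.52, aq.KID),
                            aq.daily_dose_dermal(8.52, aq.KID), AS_TOX)
        assert cr == pytest.approx(61.74e-5, abs=5e-8)

    def test_non_carcinogen_has_no_cr(self):
        assert aq.cancer_risk(1e-4, 1e-6, aq.DEFAULT_TOXICITY["Ni"]) is None

    def test_csf_must_be_paired(self):
        with pytest.raises(ParameterError):
            aq.ToxicityProfile("X", 0.01, 0.01, csf_drinking=1.0, csf_dermal=None)


class TestClassification:
    def test_concern_above_one(self):
        assert aq.classify_risk(1.37).noncarcinogenic == "concern"

    def test_exactly_one_is_acceptable(self):
        assert aq.classify_risk(1.0).noncarcinogenic == "acceptable"

    def test_cr_below_all_benchmarks(self):
        labels = aq.classify_risk(0.1, cr=4.09e-7)
        assert set(labels.carcinogenic.values()) == {"below"}

    def test_cr_between_benchmarks(self):
        labels = aq.classify_risk(0.1, cr=6e-5)
        assert labels.carcinogenic[1e-6] == "above"
        assert labels.carcinogenic[5e-5] == "above"
        assert labels.carcinogenic[1e-4] == "below"


class TestLinearityAndRatios:
    @given(cw=st.floats(min_value=1e-6, max_value=1e3),
           k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_doses_and_hq_linear_in_concentration(self, cw, k):
        for profile in (aq.ADULT, aq.KID):
            q1 = aq.daily_dose_ingestion(cw, profile)
            q2 = aq.daily_dose_ingestion(k * cw, profile)
            assert q2 == pytest.approx(k * q1, rel=1e-12)
            d1 = aq.daily_dose_dermal(cw, profile)
            d2 = aq.daily_dose_dermal(k * cw, profile)
            assert d2 == pytest.approx(k * d1, rel=1e-12)
            hq1 = aq.hazard_quotient(q1, d1, AS_TOX)
            hq2 = aq.hazard_quotient(q2, d2, AS_TOX)
            assert hq2 == pytest.approx(k * hq1, rel=1e-12)

    @given(cw=st.floats(min_value=1e-6, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_kid_adult_dose_ratios(self, cw):
        # exact evaluation of the parameter ratio (1.0*350*12/(20.08*4380))
        # / (2.2*350*30/(62.4*10950)) = 1.4125, dermal analogue 1.7784
        ing = aq.daily_dose_ingestion(cw, aq.KID) / aq.daily_dose_ingestion(cw, aq.ADULT)
        derm = aq.daily_dose_dermal(cw, aq.KID) / aq.daily_dose_dermal(cw, aq.ADULT)
        assert ing == pytest.approx(1.41253, abs=5e-5)
        assert derm == pytest.approx(1.77842, abs=5e-5)


def _scalar_oracle(cw, profile, tox):
    """Independent scalar evaluation of the exposure/risk equations."""
    q_ing = cw / 1000 * profile.IR * profile.ABS_GI * profile.EF * profile.ED \
        / (profile.BW * profile.AT)
    q_derm = cw / 1000 * profile.KP * profile.SA * profile.EF * profile.ED \
        * profile.ET / (profile.BW * profile.AT) / 1000
    hq = q_ing / tox.rfd_drinking + q_derm / tox.rfd_dermal
    cr = (q_ing * tox.csf_drinking + q_derm * tox.csf_dermal
          if tox.csf_drinking is not None else None)
    return q_ing, q_derm, hq, cr


class TestRiskTable:
    def test_single_site_as_maximum(self):
        table = aq.compute_risk_table(make_table({"As": 8.52}))
        kid = table.summary.query("receptor == 'kid'")
        assert kid["hi"].iloc[0] == pytest.approx(1.37, abs=5e-3)
        assert kid["nc_label"].iloc[0] == "concern"

    def test_empty_table(self):
        table = aq.compute_risk_table(pd.DataFrame(columns=["site_id", "bank", "position"]))
        assert table.long.empty and table.summary.empty
        assert table.bank_summary().empty

    def test_totals_at_mean_concentrations(self, mean_concentration_table):
        table = aq.compute_risk_table(mean_concentration_table)
        totals = table.summary.set_index("receptor")["cr_total"]
        assert totals["adult"] == pytest.approx(5.698e-4, rel=1e-3)
        assert totals["kid"] == pytest.approx(8.058e-4, rel=1e-3)
        assert totals["kid"] / totals["adult"] == pytest.approx(1.41, abs=5e-3)

    def test_hi_is_sum_of_hqs_and_cr_total_sum_of_crs(self, default_table):
        table = aq.compute_risk_table(default_table)
        for (site, _, receptor), grp in table.long.groupby(["site_id", "bank", "receptor"]):
            row = table.summary.query("site_id == @site and receptor == @receptor")
            assert row["hi"].iloc[0] == pytest.approx(grp["hq"].sum(), rel=1e-12)
            assert row["cr_total"].iloc[0] == pytest.approx(grp["cr"].dropna().sum(), rel=1e-12)
            break  # one site per group suffices; full sweep is in the acceptance suite

    def test_missing_toxicity_is_configuration_error(self, mean_concentration_table):
        tox = {k: v for k, v in aq.DEFAULT_TOXICITY.items() if k != "Zn"}
        with pytest.raises(ConfigurationError, match="Zn"):
            aq.compute_risk_table(mean_concentration_table, toxicity=tox)

    def test_matches_independent_scalar_oracle(self, rng):
        """20 random (cw, profile, tox) triples vs independent equations."""
        profiles = [aq.ADULT, aq.KID]
        metals = list(aq.METALS)
        for _ in range(20):
            cw = float(rng.uniform(0.01, 50.0))
            metal = metals[rng.integers(len(metals))]
            profile = profiles[rng.integers(2)]
            tox = aq.DEFAULT_TOXICITY[metal]
            table = aq.compute_risk_table(
                make_table({metal: cw}),
                profiles={profile.receptor_label: profile},
                metals=[metal])
            row = table.long.iloc[0]
            q_ing, q_derm, hq, cr = _scalar_oracle(cw, profile, tox)
            assert row["q_ingestion"] == pytest.approx(q_ing, rel=1e-12)
            assert row["q_dermal"] == pytest.approx(q_derm, rel=1e-12)
            assert row["hq"] == pytest.approx(hq, rel=1e-12)
            if cr is None:
                assert np.isnan(row["cr"])
            else:
                assert row["cr"] == pytest.approx(cr, rel=1e-12)

    def test_bank_summary_rendering(self, default_table):
        table = aq.compute_risk_table(default_table)
        rendered = render_bank_summary(table)
        as_rows = rendered.query("quantity == 'HQ' and metal == 'As'")
        assert (as_rows["scale"] == 1e-2).all()
        assert set(rendered["bank"]) == {"left", "right"}
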