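import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrochem.quality import (
    DEFAULT_WEIGHT_TABLE,
    WeightTable,
    classify_percent_na,
    classify_sar,
    classify_wqi,
    irrigation_indices,
    percent_na,
    relative_weights,
    rsc,
    sar,
    ussl_classify,
    wilcox_classify,
    wqi,
)

from conftest import make_sample, sample_from_meq

# a weight table over directly-reported analytes only, so C_i = S_i is
# realizable by literally setting each concentration to its standard
ION_TABLE = WeightTable(
    weights={"tds": 4, "ca": 3, "mg": 3, "na": 3, "k": 2, "cl": 4, "so4": 4, "hco3": 2, "no3": 5},
    standards={"tds": 1000.0, "ca": 75.0, "mg": 50.0, "na": 200.0, "k": 12.0,
               "cl": 250.0, "so4": 250.0, "hco3": 250.0, "no3": 20.0},
)


def sample_at_standards(table: WeightTable, factor: float = 1.0):
    conc = {p: s * factor for p, s in table.standards.items()}
    tds = conc.pop("tds")
    return make_sample(tds=tds, **conc)


class TestRelativeWeights:
    def test_equal_weights(self):
        t = WeightTable(weights={c: 1 for c in "abcd"}, standards={c: 1.0 for c in "abcd"})
        assert all(w == pytest.approx(0.25) for w in relative_weights(t).values())

    def test_single_parameter(self):
        t = WeightTable(weights={"a": 7}, standards={"a": 3.0})
        assert relative_weights(t) == {"a": 1.0}

    def test_proportions(self):
        t = WeightTable(weights={"a": 5, "b": 3, "c": 2}, standards={"a": 1, "b": 1, "c": 1})
        assert relative_weights(t) == pytest.approx({"a": 0.5, "b": 0.3, "c": 0.2})

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="nonpositive weight"):
            WeightTable(weights={"a": 0}, standards={"a": 1.0})


class TestWQI:
    def test_identity_at_standards(self):
        res = wqi(sample_at_standards(ION_TABLE), ION_TABLE)
        assert res.wqi == pytest.approx(100.0, abs=1e-9)

    def test_zero_water_is_excellent(self):
        res = wqi(make_sample(tds=0.0), ION_TABLE)
        assert res.wqi == 0.0
        assert res.wqi_class == "excellent"

    def test_effective_weight_split(self):
        # two parameters, equal weights, ratings 0.5 and 1.5
        t = WeightTable(weights={"cl": 1, "no3": 1}, standards={"cl": 100.0, "no3": 100.0})
        res = wqi(make_sample(cl=50.0, no3=150.0), t)
        assert res.wqi == pytest.approx(100.0)
        assert res.effective_weights["cl"] == pytest.approx(25.0)
        assert res.effective_weights["no3"] == pytest.approx(75.0)

    def test_effective_weights_sum_to_100(self, random_samples):
        for s in random_samples[:50]:
            res = wqi(s, DEFAULT_WEIGHT_TABLE)
            assert sum(res.effective_weights.values()) == pytest.approx(100.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(factor=st.floats(0.1, 10.0))
    def test_invariant_under_joint_scaling(self, factor):
        # scaling every C_i and S_i together leaves the index unchanged
        scaled = WeightTable(
            weights=dict(ION_TABLE.weights),
            standards={p: s * factor for p, s in ION_TABLE.standards.items()},
        )
        res = wqi(sample_at_standards(ION_TABLE, factor), scaled)
        assert res.wqi == pytest.approx(100.0, rel=1e-9)

    def test_all_parameters_missing_raises(self):
        t = WeightTable(weights={"ec": 1}, standards={"ec": 1000.0})
        with pytest.raises(ValueError, match="no WQI parameter"):
            wqi(make_sample(), t)


class TestWQIClasses:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (9.96, "excellent"),
            (266.10, "very_poor"),
            (50.0, "good"),
            (100.0, "poor"),
            (300.0, "non_drinkable"),
        ],
    )
    def test_bands(self, value, expected):
        assert classify_wqi(value) == expected

    @settings(derandomize=True, max_examples=100)
    @given(value=st.floats(0, 1e4, allow_nan=False))
    def test_total_over_finite_scores(self, value):
        assert classify_wqi(value) in {"excellent", "good", "poor", "very_poor", "non_drinkable"}


class TestIrrigationIndices:
    def test_sar_unit_case(self):
        assert sar(sample_from_meq(na=1.0, ca=1.0, mg=1.0)) == pytest.approx(1.0)

    def test_sar_zero_na(self):
        assert sar(sample_from_meq(ca=2.0)) == 0.0

    def test_sar_direct(self):
        assert sar(sample_from_meq(na=2.0, ca=1.0, mg=1.0)) == pytest.approx(2.0)

    def test_sar_undefined_without_ca_mg(self):
        assert math.isnan(sar(sample_from_meq(na=1.0)))

    def test_percent_na_cases(self):
        assert percent_na(sample_from_meq(na=1, k=1, ca=1, mg=1)) == pytest.approx(50.0)
        assert percent_na(sample_from_meq(na=1, k=1)) == pytest.approx(100.0)
        assert percent_na(sample_from_meq(na=0.5, k=0.5, ca=2, mg=1)) == pytest.approx(25.0)

    def test_rsc_cases(self):
        assert rsc(sample_from_meq(hco3=2.0, ca=1.0, mg=1.0)) == pytest.approx(0.0)
        assert rsc(make_sample()) == 0.0
        assert rsc(sample_from_meq(hco3=3.0, ca=1.0)) == pytest.approx(2.0)

    def test_oracle_equivalence(self, random_samples):
        # independent hand calculator on meq/L with its own constants
        mm = {"na": 22.990, "k": 39.098, "ca": 40.078, "mg": 24.305,
              "hco3": 61.016, "co3": 60.008}
        z = {"na": 1, "k": 1, "ca": 2, "mg": 2, "hco3": 1, "co3": 2}
        for s in random_samples[:100]:
            meq = {i: getattr(s, i) * z[i] / mm[i] for i in mm}
            exp_sar = meq["na"] / math.sqrt((meq["ca"] + meq["mg"]) / 2)
            exp_pna = 100 * (meq["na"] + meq["k"]) / (meq["na"] + meq["k"] + meq["ca"] + meq["mg"])
            exp_rsc = (meq["co3"] + meq["hco3"]) - (meq["ca"] + meq["mg"])
            assert sar(s) == pytest.approx(exp_sar, rel=1e-9)
            assert percent_na(s) == pytest.approx(exp_pna, rel=1e-9)
            assert rsc(s) == pytest.approx(exp_rsc, rel=1e-9)


class TestBands:
    @pytest.mark.parametrize("value,band", [(3.6, "<10"), (10.0, "10–18"), (26.0, ">26")])
    def test_sar_bands(self, value, band):
        assert classify_sar(value) == band

    @pytest.mark.parametrize(
        "value,band", [(10.28, "<20"), (20.0, "20–40"), (82.36, ">80"), (60.0, "60–80")]
    )
    def test_percent_na_bands(self, value, band):
        assert classify_percent_na(value) == band


class TestWilcox:
    def test_low_salinity_low_sodium(self):
        assert wilcox_classify(100.0, 10.0) == "excellent_to_good"

    def test_extreme_corner(self):
        assert wilcox_classify(5000.0, 90.0) == "unsuitable"

    def test_boundary_falls_to_safer_class(self):
        # a vertex of the first region polygon is not strictly inside it
        assert wilcox_classify(0.0, 80.0) != "excellent_to_good"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilcox_classify(-1.0, 50.0)
        with pytest.raises(ValueError):
            wilcox_classify(100.0, 150.0)


class TestUSSL:
    @pytest.mark.parametrize(
        "ec,sar_value,expected",
        [
            (200.0, 1.2, "S1C1"),
            (444.82, 1.23, "S1C2"),
            (3000.0, 30.0, "S4C4"),
            (250.0, 10.0, "S2C2"),  # lower bounds inclusive
        ],
    )
    def test_fixed_bands(self, ec, sar_value, expected):
        assert ussl_classify(ec, sar_value) == expected

    def test_sloped_mode_tightens_at_high_ec(self):
        # SAR 9 is S1 at low EC but the sloped S1 line drops below 9 at high EC
        assert ussl_classify(150.0, 9.0, sloped=True).startswith("S1")
        assert ussl_classify(5000.0, 9.0, sloped=True).startswith("S3")


class TestIrrigationReportRow:
    def test_ec_fallback_flagged(self):
        s = sample_from_meq(tds=640.0, na=2.0, ca=1.0, mg=1.0, hco3=2.0, cl=2.0)
        irr = irrigation_indices(s)
        assert irr.ec_estimated
        assert irr.ussl_class.endswith("C3")  # 640/0.64 = 1000 uS/cm
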