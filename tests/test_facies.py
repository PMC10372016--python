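import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrochem.chemistry import from_meq
from hydrochem.facies import (
    cai_indices,
    cation_exchange_slope,
    gibbs_classify,
    nitrate_exceedance,
    pearson_matrix,
    piper_coordinates,
    ratio_diagnostics,
    shchukarev_classify,
)

from conftest import make_sample, sample_from_meq


class TestPiper:
    def test_pure_ca_hco3_vertex(self):
        s = sample_from_meq(ca=2.0, hco3=2.0)
        pp = piper_coordinates(s)
        assert pp.cation_fractions == pytest.approx((100.0, 0.0, 0.0))
        assert pp.anion_fractions == pytest.approx((100.0, 0.0, 0.0))

    def test_equal_cations_symmetric(self):
        s = sample_from_meq(ca=1.0, mg=1.0, na=1.0, hco3=3.0)
        assert piper_coordinates(s).cation_fractions == pytest.approx((100 / 3,) * 3)

    def test_half_ca_half_mg(self):
        s = sample_from_meq(ca=1.0, mg=1.0, hco3=2.0)
        assert piper_coordinates(s).cation_fractions == pytest.approx((50.0, 50.0, 0.0))

    def test_zero_ionic_strength_raises(self):
        with pytest.raises(ValueError, match="zero ionic strength"):
            piper_coordinates(make_sample())

    def test_fractions_sum_to_100(self, synthetic_cohort):
        for s in synthetic_cohort:
            pp = piper_coordinates(s)
            assert sum(pp.cation_fractions) == pytest.approx(100.0, abs=1e-9)
            assert sum(pp.anion_fractions) == pytest.approx(100.0, abs=1e-9)

    def test_diamond_projection_for_vertex_water(self):
        # 100% (Na+K) cations and 100% Cl anions project to the diamond's
        # right corner (1.6, 1.2*sqrt(3)/2) under the unit construction
        s = sample_from_meq(na=2.0, cl=2.0)
        pp = piper_coordinates(s)
        assert pp.diamond_xy == pytest.approx((1.6, 1.2 * math.sqrt(3) / 2), abs=1e-9)


def _shchukarev_oracle(anion_fracs, cation_fracs):
    """Independent threshold-and-sort reference on stated % fractions."""
    keep = []
    for fracs in (anion_fracs, cation_fracs):
        names = sorted((f for f in fracs if fracs[f] >= 25.0), key=lambda f: -fracs[f])
        keep.extend(names)
    return "–".join(keep)


class TestShchukarev:
    def test_mixed_type_matches_oracle(self):
        # anions 50% HCO3 / 30% Cl / 20% SO4; cations 70% Na / 20% Ca / 10% Mg
        s = sample_from_meq(hco3=5.0, cl=3.0, so4=2.0, na=7.0, ca=2.0, mg=1.0)
        expected = _shchukarev_oracle(
            {"HCO3": 50, "Cl": 30, "SO4": 20}, {"Na": 70, "Ca": 20, "Mg": 10}
        )
        assert shchukarev_classify(s) == expected == "HCO3–Cl–Na"

    def test_single_ion_type(self):
        s = sample_from_meq(hco3=3.0, ca=3.0)
        assert shchukarev_classify(s) == "HCO3–Ca"

    def test_every_ion_above_threshold(self):
        s = sample_from_meq(hco3=4.0, cl=3.5, so4=2.5, na=4.0, ca=3.5, mg=2.5)
        expected = _shchukarev_oracle(
            {"HCO3": 40, "Cl": 35, "SO4": 25}, {"Na": 40, "Ca": 35, "Mg": 25}
        )
        assert shchukarev_classify(s) == expected == "HCO3–Cl–SO4–Na–Ca–Mg"

    def test_potassium_grouped_with_sodium(self):
        s = sample_from_meq(hco3=2.0, na=0.6, k=0.6, ca=0.8)
        assert shchukarev_classify(s).startswith("HCO3")
        assert "Na" in shchukarev_classify(s)

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_to_uniform_scaling(self, scale):
        # fractions kept clear of the 25% threshold so rounding cannot flip
        base = dict(hco3=3.0, cl=2.0, so4=1.0, na=2.6, ca=2.0, mg=1.4)
        s1 = sample_from_meq(**base)
        s2 = sample_from_meq(**{k: v * scale for k, v in base.items()})
        assert shchukarev_classify(s1) == shchukarev_classify(s2)


class TestGibbs:
    @pytest.mark.parametrize(
        "tds,na,ca,expected",
        [
            (300.0, 3.0, 7.0, "rock_dominance"),  # ratio 0.3
            (30.0, 9.0, 1.0, "precipitation_dominance"),  # ratio 0.9
            (50000.0, 98.0, 2.0, "evaporation_dominance"),  # seawater limit
            (300.0, 9.0, 1.0, "outside"),  # high ratio at rock TDS
        ],
    )
    def test_region_assignment(self, tds, na, ca, expected):
        s = sample_from_meq(tds=tds, na=na, ca=ca, hco3=na + ca)
        assert gibbs_classify(s) == expected

    def test_ratios_within_unit_interval(self, synthetic_cohort):
        for s in synthetic_cohort:
            d = ratio_diagnostics(s)
            assert 0.0 <= d.gibbs_cation <= 1.0
            assert 0.0 <= d.gibbs_anion <= 1.0


class TestRatioDiagnostics:
    def test_carbonate_boundary(self):
        s = sample_from_meq(ca=1.0, mg=1.0, hco3=2.0)
        d = ratio_diagnostics(s)
        assert d.carb_index == pytest.approx(1.0)
        assert d.carb_label == "boundary"

    def test_na_cl_one_to_one_line(self):
        s = sample_from_meq(na=2.0, cl=2.0, ca=1.0, hco3=1.0)
        d = ratio_diagnostics(s)
        assert d.exch_x == pytest.approx(0.0, abs=1e-12)

    def test_exchange_line_point(self):
        # Na+K-Cl = 2 against Mg+Ca-SO4-HCO3 = -2: on the -1 line
        s = sample_from_meq(na=3.0, cl=1.0, ca=1.0, hco3=3.0)
        d = ratio_diagnostics(s)
        assert d.exch_x == pytest.approx(2.0)
        assert d.exch_y == pytest.approx(-2.0)

    def test_undefined_ratio_is_nan(self):
        s = sample_from_meq(ca=1.0, hco3=1.0)  # na = 0
        assert math.isnan(ratio_diagnostics(s).cl_na)


class TestCationExchangeSlope:
    def test_exact_exchange_line(self):
        samples = [
            sample_from_meq(na=1.0 + x, cl=1.0, ca=1.0, hco3=1.0 + x)
            for x in (0.0, 0.5, 1.0, 2.0)
        ]
        slope, _ = cation_exchange_slope(samples)
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_flat_line(self):
        samples = [
            sample_from_meq(na=1.0 + x, cl=1.0, ca=1.0, hco3=1.0)
            for x in (0.0, 0.5, 1.5)
        ]
        slope, _ = cation_exchange_slope(samples)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_noisy_line_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 3.0, size=20)
        y = -x + rng.normal(0, 0.01, size=20)
        samples = []
        for xi, yi in zip(x, y):
            # exch_x = na - cl = xi (k=0); exch_y = ca - hco3 = yi
            samples.append(
                sample_from_meq(na=xi + 1.0, cl=1.0, ca=5.0 + yi, hco3=5.0)
            )
        slope, intercept = cation_exchange_slope(samples)
        # closed-form OLS oracle
        bx = x - x.mean()
        expected = float(bx @ (y - y.mean()) / (bx @ bx))
        assert slope == pytest.approx(expected, abs=1e-9)
        assert -1.05 <= slope <= -0.95

    def test_degenerate_x_raises(self):
        samples = [sample_from_meq(na=1.0, cl=1.0, ca=1.0, hco3=1.0 + x) for x in (0, 1, 2)]
        with pytest.raises(ValueError, match="degenerate"):
            cation_exchange_slope(samples)


class TestCAI:
    def test_balanced_gives_zero(self):
        s = sample_from_meq(na=1.0, cl=1.0, hco3=2.0, ca=2.0)
        res = cai_indices(s)
        assert res.cai_1 == pytest.approx(0.0, abs=1e-12)
        assert res.direction == "none"

    def test_reverse_exchange_values(self):
        s = sample_from_meq(cl=2.0, na=1.0, hco3=4.0)
        res = cai_indices(s)
        assert res.cai_1 == pytest.approx(0.5)
        assert res.cai_2 == pytest.approx(0.25)
        assert res.direction == "reverse_exchange"

    def test_forward_exchange_values(self):
        s = sample_from_meq(cl=1.0, na=3.0, hco3=2.0)
        res = cai_indices(s)
        assert res.cai_1 == pytest.approx(-2.0)
        assert res.cai_2 == pytest.approx(-1.0)
        assert res.direction == "forward_exchange"

    def test_sign_agreement(self, synthetic_cohort):
        for s in synthetic_cohort:
            res = cai_indices(s)
            if math.isnan(res.cai_1) or math.isnan(res.cai_2):
                continue
            if res.cai_1 != 0 and res.cai_2 != 0:
                assert math.copysign(1, res.cai_1) == math.copysign(1, res.cai_2)


class TestPearson:
    def test_exact_linear_relation(self):
        import pandas as pd

        x = np.arange(10, dtype=float)
        r, p, stars = pearson_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}), ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert stars.loc["x", "y"] == "***"

    def test_matches_two_pass_covariance_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        r, _, _ = pearson_matrix(df, ["a", "b", "c"])
        for u in "abc":
            for v in "abc":
                x, y = df[u].to_numpy(), df[v].to_numpy()
                cov = np.sum((x - x.mean()) * (y - y.mean()))
                oracle = cov / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert r.loc[u, v] == pytest.approx(oracle, abs=1e-12)

    def test_independent_pairs_near_zero(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        r, _, _ = pearson_matrix(df, ["a", "b"])
        assert abs(r.loc["a", "b"]) < 0.1

    def test_zero_variance_flagged_nan(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        r, _, stars = pearson_matrix(df, ["a", "b"])
        assert math.isnan(r.loc["a", "b"])
        assert stars.loc["a", "b"] == ""


class TestNitrateExceedance:
    def test_all_below(self):
        samples = [make_sample(no3=0.0, na=1.0, cl=1.0) for _ in range(4)]
        assert nitrate_exceedance(samples) == (0, 0.0)

    def test_one_of_four(self):
        samples = [make_sample(no3=v, na=1.0, cl=1.0) for v in (25.0, 1.0, 2.0, 3.0)]
        assert nitrate_exceedance(samples) == (1, 25.0)

    def test_boundary_is_strict(self):
        samples = [make_sample(no3=20.0, na=1.0, cl=1.0)]
        assert nitrate_exceedance(samples, threshold=20.0) == (0, 0.0)
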