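import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmhia.crf import CRFSpec
from pmhia.errors import ConfigurationError, EmptyInputError, ParameterError, ValidationError
from pmhia.exposure import ExposureCategory, bin_distribution
from pmhia.hia import (
    attributable_proportion,
    attributable_rate,
    excess_cases,
    results_frame,
    run_hia,
)
from pmhia.io_ingest import EndpointRow, EndpointTable, PopulationSpec

from conftest import daily_from_values


def categories(concs, props):
    return [
        ExposureCategory(lower=c, upper=c, midpoint=c, proportion=p)
        for c, p in zip(concs, props)
    ]


def implied(ap):
    return CRFSpec(form="implied_ap", ap_value=ap)


LOG_LINEAR = CRFSpec(
    form="log_linear", rr_central=1.062, rr_low=1.04, rr_high=1.083,
    increment=10.0, cutoff=10.0,
)


class TestAttributableProportion:
    def test_null_effect_gives_zero(self):
        ap = attributable_proportion(categories([5.0], [1.0]), LOG_LINEAR)
        assert ap == (0.0, 0.0, 0.0)

    def test_single_category_is_rr_minus_one_over_rr(self):
        # RR = 1.25 from the implied-AP inversion of 0.2
        ap = attributable_proportion(categories([30.0], [1.0]), implied(0.2))
        assert ap.central == pytest.approx(0.2, abs=1e-15)

    def test_two_category_hand_evaluation(self):
        # RR = {1.1, 1.3}, P = {0.5, 0.5}:
        # num = 0.1*0.5 + 0.3*0.5 = 0.2; den = 0.55 + 0.65 = 1.2
        spec = CRFSpec(
            form="log_linear", rr_central=1.1, increment=10.0, cutoff=0.0
        )
        rr2 = 1.3
        c2 = 10.0 * math.log(rr2) / math.log(1.1)  # concentration where RR = 1.3
        ap = attributable_proportion(categories([10.0, c2], [0.5, 0.5]), spec)
        assert ap.central == pytest.approx(0.2 / 1.2, abs=1e-12)

    def test_empty_category_list_rejected(self):
        with pytest.raises(EmptyInputError):
            attributable_proportion([], LOG_LINEAR)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            k = rng.integers(1, 8)
            concs = rng.uniform(0, 120, k)
            props = rng.dirichlet(np.ones(k))
            cats = categories(concs, props)
            ap = attributable_proportion(cats, LOG_LINEAR)
            # independent evaluation from scratch (own RR formula)
            num = den = 0.0
            for c, p in zip(concs, props):
                rr = math.exp(math.log(1.062) / 10.0 * max(0.0, c - 10.0))
                num += (rr - 1.0) * p
                den += rr * p
            assert ap.central == pytest.approx(num / den, abs=1e-12)

    def test_strictly_increasing_in_concentration(self):
        grid = np.linspace(12, 120, 30)
        aps = [
            attributable_proportion(categories([c], [1.0]), LOG_LINEAR).central
            for c in grid
        ]
        assert np.all(np.diff(aps) > 0)


class TestRateAndCases:
    @pytest.mark.parametrize(
        "incidence, ap, expected",
        [
            (817.0, 0.1232, 100.65),  # Ahvaz all-cause
            (125.13, 0.1526, 19.10),  # Esfahan IHD
            (85.46, 0.146, 12.48),  # Arak stroke
        ],
    )
    def test_published_rate_examples(self, incidence, ap, expected):
        assert attributable_rate(incidence, ap) == pytest.approx(expected, abs=0.02)

    def test_zero_ap_gives_zero_rate(self):
        assert attributable_rate(500.0, 0.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            attributable_rate(-1.0, 0.1)
        with pytest.raises(ParameterError):
            attributable_rate(100.0, 1.0)

    def test_excess_cases_scales_per_100k(self):
        assert excess_cases(50.0, 200_000) == pytest.approx(100.0)
        assert excess_cases(123.4, 0) == 0.0

    def test_excess_cases_back_computed_population_roundtrip(self):
        # published (per-100k, excess cases) pair: N implied by their ratio
        ie, ne = 100.65, 1092
        n = ne / ie * 1e5
        assert n == pytest.approx(1_084_948, abs=1)  # ~1.08 million at risk
        assert round(excess_cases(ie, n)) == ne

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            excess_cases(10.0, -5)


def _study(ap_by_city):
    endpoints = EndpointTable(
        [
            EndpointRow("Ahvaz", "ihd", ">=25", 155.06, "crf_ahvaz"),
            EndpointRow("Arak", "stroke", ">=25", 85.46, "crf_arak"),
        ]
    )
    populations = [
        PopulationSpec("Ahvaz", 1_300_000, {">=25": 697_501}),
        PopulationSpec("Arak", 600_000, {">=25": 336_538}),
    ]
    crfs = {
        "crf_ahvaz": implied(ap_by_city["Ahvaz"]),
        "crf_arak": implied(ap_by_city["Arak"]),
    }
    exposure = {
        "Ahvaz": daily_from_values([43.33] * 5),
        "Arak": daily_from_values([24.12] * 5),
    }
    return exposure, endpoints, populations, crfs


class TestRunHIA:
    def test_reproduces_published_rates_via_implied_ap(self):
        exposure, endpoints, populations, crfs = _study(
            {"Ahvaz": 0.1729, "Arak": 0.146}
        )
        frame = results_frame(
            run_hia(exposure, endpoints, populations, crfs, mode="annual_mean")
        )
        by_city = frame.set_index("city")
        assert by_city.loc["Ahvaz", "ie"] == pytest.approx(26.81, abs=0.01)
        assert by_city.loc["Arak", "ie"] == pytest.approx(12.48, abs=0.01)

    def test_zero_ap_everywhere_gives_zero_cases(self):
        exposure, endpoints, populations, crfs = _study({"Ahvaz": 0.0, "Arak": 0.0})
        frame = results_frame(run_hia(exposure, endpoints, populations, crfs))
        assert (frame[["ne_low", "ne", "ne_high"]] == 0).all().all()

    def test_missing_population_names_city(self):
        exposure, endpoints, populations, crfs = _study({"Ahvaz": 0.1, "Arak": 0.1})
        with pytest.raises(ConfigurationError, match="Arak"):
            run_hia(exposure, endpoints, populations[:1], crfs)

    def test_bounds_ordered_through_whole_chain(self):
        endpoints = EndpointTable(
            [EndpointRow("Ahvaz", "natural", ">=30", 817.0, "crf")]
        )
        populations = [PopulationSpec("Ahvaz", 1_300_000, {">=30": 650_000})]
        rng = np.random.default_rng(5)
        exposure = {"Ahvaz": daily_from_values(rng.gamma(6, 7, 200))}
        frame = results_frame(
            run_hia(exposure, endpoints, populations, {"crf": LOG_LINEAR}),
            rounded=False,
        )
        row = frame.iloc[0]
        assert row["ap_low"] <= row["ap"] <= row["ap_high"]
        assert row["ie_low"] <= row["ie"] <= row["ie_high"]
        assert row["ne_low"] <= row["ne"] <= row["ne_high"]

    def test_binned_and_annual_mean_modes_agree_for_constant_exposure(self):
        exposure, endpoints, populations, crfs = _study(
            {"Ahvaz": 0.12, "Arak": 0.12}
        )
        a = results_frame(run_hia(exposure, endpoints, populations, crfs, mode="binned"))
        b = results_frame(
            run_hia(exposure, endpoints, populations, crfs, mode="annual_mean")
        )
        assert a[["ap", "ie", "ne"]].equals(b[["ap", "ie", "ne"]])

    def test_rounding_only_at_emission(self):
        exposure, endpoints, populations, crfs = _study(
            {"Ahvaz": 0.1729, "Arak": 0.146}
        )
        raw = results_frame(
            run_hia(exposure, endpoints, populations, crfs), rounded=False
        )
        # the unrounded rate keeps full precision: 155.06 * 0.1729
        assert raw.set_index("city").loc["Ahvaz", "ie"] == pytest.approx(
            155.06 * 0.1729, abs=1e-12
        )


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=0.0, max_value=0.9), st.floats(min_value=0.0, max_value=2000.0))
def test_rate_chain_monotone_in_ap_and_incidence(ap, incidence):
    ie = attributable_rate(incidence, ap)
    assert 0 <= ie <= incidence
    assert excess_cases(ie, 100_000) == pytest.approx(ie)
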