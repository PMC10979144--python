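"""Published reference values for the seven-city Iranian PM2.5 study
(2019–2020) that this package's analyses reproduce.

Three blocks of published numbers are bundled here as machine-readable
inputs:

* ``BASELINE_INCIDENCE`` — WHO AirQ+ baseline incidences (cases per
  100,000 per year) per city and long-term mortality endpoint, with the
  age group each endpoint applies to.
* ``ALL_CAUSE_RR`` — the published all-cause log-linear relative risk
  per 10 µg/m³, 1.062 (95% CI 1.04–1.083).
* ``EXPOSURE_SUMMARY`` — published annual mean ± SD (and min/max) of
  the daily PM2.5 concentration per city, µg/m³.
* ``PUBLISHED_IMPACT`` — published attributable proportion (percent),
  excess-case count and attributable cases per 100,000 at risk, per
  city × endpoint.

These are *inputs* (the study's raw hourly feeds were never released);
the package's synthetic generator stands in for the feeds, while these
tables anchor the impact-assessment arithmetic to published values.
"""

from __future__ import annotations

from .crf import CRFSpec
from .io_ingest import EndpointRow, EndpointTable

__all__ = [
    "CITIES",
    "ENDPOINTS",
    "AGE_GROUPS",
    "BASELINE_INCIDENCE",
    "ALL_CAUSE_RR",
    "EXPOSURE_SUMMARY",
    "PUBLISHED_IMPACT",
    "endpoint_table",
]

CITIES = ("Arak", "Esfahan", "Ahvaz", "Tabriz", "Shiraz", "Karaj", "Mashhad")

#: endpoint name -> age group it applies to
AGE_GROUPS = {
    "natural": ">=30",  # all-cause (natural) mortality
    "copd": ">=30",
    "lc": ">=30",  # lung cancer
    "ihd": ">=25",  # ischemic heart disease
    "stroke": ">=25",
    "alri": "<=5",  # acute lower respiratory infection
}

ENDPOINTS = tuple(AGE_GROUPS)

#: city -> endpoint -> baseline incidence, cases per 100,000 per year
BASELINE_INCIDENCE = {
    "Arak":    {"natural": 966.0,  "copd": 18.73, "lc": 15.60, "ihd": 157.45, "stroke": 85.46, "alri": 13.24},
    "Esfahan": {"natural": 777.40, "copd": 12.63, "lc": 9.62,  "ihd": 125.13, "stroke": 53.05, "alri": 23.89},
    "Ahvaz":   {"natural": 817.0,  "copd": 8.39,  "lc": 12.01, "ihd": 155.06, "stroke": 61.5,  "alri": 14.09},
    "Tabriz":  {"natural": 1003.0, "copd": 20.0,  "lc": 19.97, "ihd": 98.18,  "stroke": 48.0,  "alri": 20.0},
    "Shiraz":  {"natural": 797.0,  "copd": 13.0,  "lc": 12.46, "ihd": 107.0,  "stroke": 62.77, "alri": 15.21},
    "Karaj":   {"natural": 549.0,  "copd": 7.17,  "lc": 10.52, "ihd": 131.33, "stroke": 31.42, "alri": 11.28},
    "Mashhad": {"natural": 936.4,  "copd": 15.06, "lc": 16.8,  "ihd": 114.0,  "stroke": 65.93, "alri": 11.34},
}

#: published all-cause RR per 10 µg/m³ with 95% CI, log-linear form
ALL_CAUSE_RR = CRFSpec(
    form="log_linear",
    rr_central=1.062, rr_low=1.04, rr_high=1.083,
    increment=10.0, cutoff=10.0,
    name="all_cause_loglinear",
)

#: city -> (mean, sd, min, max) of daily PM2.5, µg/m³
EXPOSURE_SUMMARY = {
    "Arak":    (24.12, 6.35,  7.54,  73.92),
    "Esfahan": (27.93, 8.79,  11.01, 84.02),
    "Ahvaz":   (43.33, 19.23, 14.94, 170.69),
    "Tabriz":  (32.80, 17.86, 6.5,   87.45),
    "Shiraz":  (30.85, 16.87, 10.85, 81.33),
    "Karaj":   (26.75, 11.51, 9.91,  84.42),
    "Mashhad": (28.57, 9.11,  14.28, 86.49),
}

#: city -> endpoint -> (AP percent, excess cases, cases per 100,000 at risk)
PUBLISHED_IMPACT = {
    "Arak": {
        "natural": (7.39, 353, 71.43), "lc": (8.39, 4, 1.31),
        "copd": (10.43, 6, 1.95), "alri": (12.21, 1, 1.62),
        "ihd": (14.6, 78, 22.98), "stroke": (14.6, 42, 12.48),
    },
    "Esfahan": {
        "natural": (8.61, 389, 66.88), "lc": (10.16, 13, 0.98),
        "copd": (12.37, 20, 1.56), "alri": (14.63, 5, 3.49),
        "ihd": (15.26, 278, 19.10), "stroke": (15.56, 120, 8.25),
    },
    "Ahvaz": {
        "natural": (12.32, 1092, 100.65), "lc": (16.48, 12, 1.98),
        "copd": (18.91, 9, 1.59), "alri": (22.79, 3, 3.21),
        "ihd": (17.29, 187, 26.81), "stroke": (18.54, 79, 11.40),
    },
    "Tabriz": {
        "natural": (9.92, 1573, 99.46), "lc": (12.24, 24, 2.44),
        "copd": (14.58, 28, 2.92), "alri": (17.4, 4, 3.48),
        "ihd": (15.98, 170, 15.69), "stroke": (16.6, 86, 7.97),
    },
    "Shiraz": {
        "natural": (9.42, 1291, 75.05), "lc": (11.43, 15, 1.42),
        "copd": (13.73, 19, 1.78), "alri": (16.33, 3, 2.48),
        "ihd": (15.71, 201, 16.81), "stroke": (16.21, 22, 10.17),
    },
    "Karaj": {
        "natural": (8.25, 857, 45.28), "lc": (9.63, 12, 1.01),
        "copd": (11.79, 10, 0.85), "alri": (13.91, 2, 1.57),
        "ihd": (15.07, 258, 19.79), "stroke": (15.28, 63, 4.80),
    },
    "Mashhad": {
        "natural": (8.89, 2479, 83.23), "lc": (10.62, 9, 1.78),
        "copd": (12.84, 31, 1.93), "alri": (15.22, 5, 1.73),
        "ihd": (15.42, 332, 17.58), "stroke": (15.78, 197, 10.41),
    },
}


#: twelve representative (city, endpoint) worked examples whose published
#: attributable proportion and per-100,000 rate are mutually consistent at
#: the printed precision (the all-cause rows of four cities are not: with
#: I ≈ 1000, rounding AP to two decimals moves I × AP by up to ±0.05).
WORKED_EXAMPLES = (
    ("Ahvaz", "natural"),
    ("Karaj", "natural"),
    ("Mashhad", "natural"),
    ("Esfahan", "ihd"),
    ("Ahvaz", "ihd"),
    ("Mashhad", "ihd"),
    ("Arak", "stroke"),
    ("Karaj", "stroke"),
    ("Esfahan", "alri"),
    ("Tabriz", "copd"),
    ("Shiraz", "lc"),
    ("Ahvaz", "lc"),
)


def endpoint_table(cities: tuple[str, ...] = CITIES) -> EndpointTable:
    """Build the published baseline-incidence table as an EndpointTable.

    All endpoints reference a CRF named ``all_cause_loglinear`` for the
    all-cause rows and ``<endpoint>_ier`` for cause-specific rows; the
    caller supplies matching CRFSpec definitions.
    """
    rows = [
        EndpointRow(
            city=city,
            endpoint=ep,
            age_group=AGE_GROUPS[ep],
            baseline_incidence=BASELINE_INCIDENCE[city][ep],
            crf="all_cause_loglinear" if ep == "natural" else f"{ep}_ier",
        )
        for city in cities
        for ep in ENDPOINTS
    ]
    return EndpointTable(rows)
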