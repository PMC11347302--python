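"""Published descriptive counts for sacubitril/valsartan reports in FAERS.

Category counts of the 99,651 FAERS reports (2015Q3-2023Q4) naming
sacubitril/valsartan as the primary suspect drug, as printed in the
public descriptive table of that corpus.  They serve as a worked input
for :func:`pvsignal.descriptives.category_percentages`: feeding each
characteristic's counts through the percentage routine must reproduce
the published percentages to two decimals (e.g. 59,744 males out of
99,651 reports -> 59.95%).

Within each characteristic the percentage denominator is the sum of its
category counts: the full report total (99,651) for sex, age, reporter,
country, route and report year; the number of serious-outcome *entries*
(56,489; a report may carry several outcomes) for outcomes; and the
number of reports with therapy-date information (33,363) for onset.
"""

from __future__ import annotations

N_TARGET_REPORTS = 99_651

#: characteristic -> list of (category, report or entry count)
DESCRIPTIVE_COUNTS: dict[str, list[tuple[str, int]]] = {
    "sex": [
        ("Female", 33_198),
        ("Male", 59_744),
        ("Unknown", 6_709),
    ],
    "age": [
        ("<20", 67),
        ("20-30", 171),
        ("30-40", 662),
        ("40-50", 1_860),
        ("50-60", 4_990),
        ("60-70", 8_077),
        ("70-80", 7_540),
        (">=80", 5_482),
        ("Unknown", 70_802),
    ],
    "reporter": [
        ("Consumer", 71_751),
        ("Physician", 15_704),
        ("Other health-professional", 7_013),
        ("Pharmacist", 5_099),
        ("Unknown", 81),
        ("Lawyer", 3),
    ],
    "country": [
        ("United States", 52_831),
        ("Others", 42_491),
        ("Japan", 2_086),
        ("Philippines", 1_144),
        ("Germany", 1_099),
    ],
    "route": [
        ("Oral", 51_707),
        ("Others", 47_895),
        ("Ophthalmic", 29),
        ("Parenteral", 10),
        ("Subcutaneous", 10),
    ],
    "serious_outcomes": [
        ("Other serious", 25_745),
        ("Hospitalization", 14_469),
        ("Death", 13_931),
        ("Life threatening", 1_556),
        ("Disability", 751),
        ("Required intervention", 25),
        ("Congenital anomaly", 12),
    ],
    "onset_days": [
        ("<7", 4_714),
        ("7-14", 704),
        ("14-28", 927),
        ("28-60", 1_204),
        (">=60", 3_565),
        ("Unknown", 22_249),
    ],
    "report_year": [
        ("2015", 796),
        ("2016", 5_859),
        ("2017", 7_502),
        ("2018", 11_232),
        ("2019", 12_763),
        ("2020", 11_314),
        ("2021", 15_400),
        ("2022", 19_002),
        ("2023", 15_783),
    ],
}

#: (median, Q1, Q3) of age in years and of onset in days in the same corpus.
AGE_QUARTILES = (68.00, 59.00, 77.00)
ONSET_QUARTILES = (14.50, 0.00, 97.00)
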