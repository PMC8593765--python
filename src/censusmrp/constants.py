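"""Shared constants: the study window, age bins, and categorical codings.

The study window is 22 calendar months, January 2019 (month 1) through
October 2020 (month 22).  The in-person census takes place at the start of
month 13 (January 2020); the two telephone rounds are fielded around months
17 (May 2020) and 23 (November 2020), so round 1 covers deaths through
month 16 (April 2020) and round 2 covers the full window.
"""

N_MONTHS = 22
CENSUS_MONTH = 13          # January 2020, start-of-month census snapshot
ROUND1_COVERS_THROUGH = 16  # April 2020
ROUND2_COVERS_THROUGH = 22  # October 2020
DEFAULT_ONSET_MONTH = 14    # February 2020

AGE_BIN_LABELS = (
    "0-9", "10-19", "20-29", "30-39", "40-49",
    "50-59", "60-69", "70-79", "80+",
)
N_AGE_BINS = len(AGE_BIN_LABELS)

SEX_LABELS = ("female", "male")
N_SEX = 2

# Household education bands: 0 = no schooling, 1 = primary, 2 = secondary+.
EDU_LABELS = (0, 1, 2)
N_EDU = 3

CAUSE_LABELS = ("stroke_heart", "cancer", "liver", "lung", "injury", "other")

SYMPTOM_LABELS = (
    "fever", "headache", "cough", "sore throat", "breathing difficulty",
    "loss of smell", "muscle aches", "chills",
)


def month_of_year(month: int) -> int:
    """Calendar month of year (1-12) for a study-month index (1-22)."""
    return (month - 1) % 12 + 1


def year_of_month(month: int) -> int:
    """Calendar year of a study-month index: months 1-12 are 2019."""
    return 2019 if month <= 12 else 2020
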