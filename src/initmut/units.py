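"""Time-unit conventions.

All internal computation is in days. Cohort tables carry survival in months
and clone times in years; these constants are the single place where the
conversions live. Mutation rates of ~0.02 are dimensionally consistent only
with per-day units (N = 49 mutations at 0.0192/day is about 7 years).
"""

DAYS_PER_MONTH: float = 30.4375
DAYS_PER_YEAR: float = 365.25


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def years_to_days(years: float) -> float:
    return years * DAYS_PER_YEAR


def days_to_years(days: float) -> float:
    return days / DAYS_PER_YEAR
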