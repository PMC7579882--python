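"""Time-unit conventions shared across the package.

All stored event times are integer day offsets from study start (day 0).
Month-valued planning inputs are converted at the mean Gregorian month
length so that 12 months is exactly 365.25 days.
"""

DAYS_PER_MONTH: float = 30.4375


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH
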