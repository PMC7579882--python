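"""Closed-form site-months arithmetic for multicentre trial planning.

A *site-month* is one site open to recruitment for one month.  A trial
that must enrol ``sample_size`` patients inside a fixed accrual window
needs enough site-months of open capacity, but every site spends an
initial *latency* (ethical approval to opening, typically ~6 months in
UK experience) contributing nothing.  The planning identity is

    required sites = ceil( sample_size /
        (eligible_per_site_per_month * recruitment_rate
         * (accrual_months - latency_months)) )

and its companions: capacity in site-months, the shortfall between an
optimistic plan and a realistic one, and the number of top-up sites a
mid-trial amendment must add once both the recognition delay and the
opening delay have eaten into the remaining window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "TrialPlan",
    "SiteMonthsLedger",
    "site_months_capacity",
    "required_sites",
    "shortfall",
    "topup_sites",
    "plan_report",
]

# guard against float noise pushing an exact ratio over the next integer
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class TrialPlan:
    """Inputs of the required-sites formula.

    Parameters
    ----------
    sample_size : int
        Target number of patients to be recruited.
    eligible_per_site_per_month : float
        Eligible patients presenting per site per month.
    recruitment_rate : float
        Fraction of eligible patients actually randomised, in (0, 1].
        The formula only ever uses the product ``eligible * rate`` as a
        single per-site-month recruitment intensity; both readings of
        "recruitment rate" (consent fraction vs. absolute rate) are
        therefore supported by folding the other factor into 1.
    accrual_months : float
        Months available for recruitment within the funding envelope.
    latency_months : float, default 6.0
        Average months from a site's ethical approval to opening.
    """

    sample_size: int
    eligible_per_site_per_month: float
    recruitment_rate: float
    accrual_months: float
    latency_months: float = 6.0

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.eligible_per_site_per_month <= 0:
            raise ValueError("eligible_per_site_per_month must be positive")
        if not 0 < self.recruitment_rate <= 1:
            raise ValueError("recruitment_rate must be in (0, 1]")
        if self.latency_months < 0:
            raise ValueError("latency_months must be non-negative")
        if self.accrual_months <= self.latency_months:
            raise ValueError(
                "accrual_months must exceed latency_months "
                f"({self.accrual_months} <= {self.latency_months})"
            )

    @property
    def per_site_rate(self) -> float:
        """Patients recruited per open site per month."""
        return self.eligible_per_site_per_month * self.recruitment_rate


@dataclass(frozen=True)
class SiteMonthsLedger:
    """Comparison of planned (optimistic) vs achievable site-months.

    ``topup_sites`` is ``None`` when a shortfall exists but no recruiting
    window remains once both mid-trial latencies are spent — no number of
    top-up sites can recover the capacity.
    """

    planned_sites: int
    required_site_months: float
    achievable_site_months: float
    shortfall: float
    capacity_fraction: float
    topup_sites: Optional[int]

    def __post_init__(self) -> None:
        expected_short = max(0.0, self.required_site_months - self.achievable_site_months)
        if not math.isclose(self.shortfall, expected_short, abs_tol=1e-9):
            raise ValueError("shortfall must equal max(0, required - achievable)")
        if self.required_site_months > 0 and not math.isclose(
            self.capacity_fraction,
            self.achievable_site_months / self.required_site_months,
            abs_tol=1e-9,
        ):
            raise ValueError("capacity_fraction must equal achievable/required")


def _ceil(x: float) -> int:
    return math.ceil(x - _CEIL_EPS)


def site_months_capacity(
    n_sites: int, accrual_months: float, latency_months: float
) -> float:
    """Site-months of open recruitment capacity.

    Each of ``n_sites`` contributes the accrual window minus the average
    opening latency: ``n_sites * (accrual_months - latency_months)``.
    """
    if latency_months < 0:
        raise ValueError("latency_months must be non-negative")
    if accrual_months < latency_months:
        raise ValueError(
            f"latency_months ({latency_months}) exceeds accrual_months ({accrual_months})"
        )
    return n_sites * (accrual_months - latency_months)


def required_sites(plan: TrialPlan) -> int:
    """Number of sites to open from the start, rounded up to whole sites."""
    window = plan.accrual_months - plan.latency_months
    denom = plan.per_site_rate * window
    if denom <= 0:
        raise ValueError("non-positive recruiting capacity per site")
    return max(1, _ceil(plan.sample_size / denom))


def shortfall(required: float, achievable: float) -> float:
    """Site-months missing from the plan; surplus clamps to zero."""
    if required < 0 or achievable < 0:
        raise ValueError("site-months must be non-negative")
    return max(0.0, required - achievable)


def topup_sites(
    shortfall: float,
    accrual_months: float,
    recognition_latency_months: float,
    opening_latency_months: float,
) -> int:
    """Sites a mid-trial amendment must add to cover ``shortfall``.

    Top-up sites recruit only in the window left after the trial team
    has *recognised* the need for more sites (``recognition_latency``)
    and the new sites have themselves *opened* (``opening_latency``).
    """
    if shortfall < 0:
        raise ValueError("shortfall must be non-negative")
    if shortfall == 0:
        return 0
    window = accrual_months - recognition_latency_months - opening_latency_months
    if window <= 0:
        raise ValueError(
            "no recruitment window remains after recognition latency "
            f"({recognition_latency_months} mo) plus opening latency "
            f"({opening_latency_months} mo) within {accrual_months} accrual months"
        )
    return _ceil(shortfall / window)


def plan_report(plan: TrialPlan, optimistic_latency_months: float) -> SiteMonthsLedger:
    """Ledger contrasting the grant's optimistic latency with the plan's.

    ``planned_sites`` is the site count the optimistic latency implies;
    the ledger then reports the site-months that plan *assumed*, the
    site-months those sites can *achieve* under the realistic latency,
    the shortfall, the capacity fraction, and the top-up sites needed if
    the shortfall is only recognised after one realistic latency and the
    new sites take another to open.
    """
    if optimistic_latency_months < 0:
        raise ValueError("optimistic_latency_months must be non-negative")
    optimistic_plan = TrialPlan(
        sample_size=plan.sample_size,
        eligible_per_site_per_month=plan.eligible_per_site_per_month,
        recruitment_rate=plan.recruitment_rate,
        accrual_months=plan.accrual_months,
        latency_months=optimistic_latency_months,
    )
    planned = required_sites(optimistic_plan)
    required_sm = site_months_capacity(planned, plan.accrual_months, optimistic_latency_months)
    achievable_sm = site_months_capacity(planned, plan.accrual_months, plan.latency_months)
    short = shortfall(required_sm, achievable_sm)
    topup: Optional[int]
    if short == 0:
        topup = 0
    elif plan.accrual_months - 2 * plan.latency_months > 0:
        topup = topup_sites(short, plan.accrual_months, plan.latency_months, plan.latency_months)
    else:
        topup = None  # window exhausted: no top-up count can recover it

    return SiteMonthsLedger(
        planned_sites=planned,
        required_site_months=required_sm,
        achievable_site_months=achievable_sm,
        shortfall=short,
        capacity_fraction=achievable_sm / required_sm if required_sm > 0 else 1.0,
        topup_sites=topup,
    )
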