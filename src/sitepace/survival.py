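"""Product-limit (Kaplan-Meier) estimation of site set-up delays.

Site opening, and first-patient recruitment, are time-to-event outcomes:
a site that has not opened (or not recruited) by study close contributes
its observed waiting time without an event — right censoring.  This
module implements the product-limit estimator with Greenwood variance,
a median with a 95% confidence interval obtained by inverting pointwise
log(-log) confidence bands (the Brookmeyer-Crowley construction), and
the two-sample Mantel-Cox log-rank test, all from first principles.

The estimator follows scikit-learn conventions (``fit``, ``predict``,
trailing-underscore fitted attributes) so it composes with sklearn
tooling; ``km_fit``/``km_median_ci``/``logrank_test`` are thin
functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "AllCensoredError",
    "SurvivalSample",
    "KMCurve",
    "MedianEstimate",
    "LogRankResult",
    "KaplanMeierEstimator",
    "km_fit",
    "km_median_ci",
    "logrank_test",
    "combine_delays",
]


class AllCensoredError(ValueError):
    """Raised when a non-empty sample contains no observed events."""


@dataclass(frozen=True)
class SurvivalSample:
    """Durations with event indicators and optional group/site labels."""

    durations: np.ndarray
    event_observed: np.ndarray
    group: Optional[np.ndarray] = None
    site_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        e = np.asarray(self.event_observed, dtype=bool)
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "event_observed", e)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("durations must be a non-empty 1-d array")
        if e.shape != d.shape:
            raise ValueError("event_observed must match durations in length")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("durations must be finite and non-negative")
        for name in ("group", "site_ids"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                object.__setattr__(self, name, v)
                if v.shape != d.shape:
                    raise ValueError(f"{name} must match durations in length")

    def __len__(self) -> int:
        return self.durations.size


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    #: cumulative sum d/(n(n-d)) — the Greenwood term on the hazard scale,
    #: needed for log(-log) bands
    cum_hazard_var: np.ndarray


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival time with a confidence interval.

    ``None`` marks a median the curve never reaches or a CI bound whose
    confidence band never crosses one half ("not reached").
    """

    median: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    level: float = 0.95

    def __post_init__(self) -> None:
        vals = [v for v in (self.ci_low, self.median, self.ci_high) if v is not None]
        if vals != sorted(vals):
            raise ValueError("median CI must be ordered ci_low <= median <= ci_high")


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _km_arrays(durations: np.ndarray, events: np.ndarray):
    """Risk-set table at distinct event times (events precede censorings)."""
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    e = events[order]
    event_times = np.unique(t[e])
    # at risk at time u: subjects with duration >= u; censorings tied with
    # events stay in the risk set for that time (events-first convention)
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    d = np.array([np.count_nonzero((t == u) & e) for u in event_times])
    return event_times, n_at_risk.astype(np.int64), d.astype(np.int64)


class KaplanMeierEstimator(BaseEstimator):
    """Non-parametric survival curve estimator for right-censored delays.

    Parameters
    ----------
    conf_level : float, default 0.95
        Level of the pointwise confidence band and of the median CI.

    Attributes
    ----------
    event_times_ : ndarray
        Distinct times at which at least one event was observed.
    survival_ : ndarray
        ``S(t_i) = prod_{t_j <= t_i} (1 - d_j / n_j)``.
    at_risk_, n_events_ : ndarray
        Risk-set size and event count at each event time.
    greenwood_var_ : ndarray
        Greenwood estimate of ``Var[S(t_i)]``.
    median_ : MedianEstimate
        Median (earliest event time with ``S <= 0.5``) with its CI from
        inverting the log(-log) confidence band.
    """

    def __init__(self, conf_level: float = 0.95):
        self.conf_level = conf_level

    def fit(self, durations, event_observed=None) -> "KaplanMeierEstimator":
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")
        d = np.asarray(durations, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("empty sample: no durations supplied")
        e = (
            np.ones(d.size, dtype=bool)
            if event_observed is None
            else np.asarray(event_observed, dtype=bool).ravel()
        )
        if e.shape != d.shape:
            raise ValueError("event_observed must match durations in length")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("durations must be finite and non-negative")
        if not e.any():
            raise AllCensoredError(
                "all observations are censored: the product-limit curve is undefined"
            )

        times, n, dd = _km_arrays(d, e)
        frac = 1.0 - dd / n
        surv = np.cumprod(frac)
        # Greenwood: Var[S] = S^2 * cumsum d / (n (n - d)); the summand is
        # +inf where d == n (curve hits zero), giving variance nan*0 -> set 0
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = dd / (n * (n - dd)).astype(float)
            cumvar = np.cumsum(terms)
            gvar = surv**2 * cumvar
        gvar = np.where(np.isfinite(gvar), gvar, 0.0)

        self.n_subjects_ = d.size
        self.event_times_ = times
        self.survival_ = surv
        self.at_risk_ = n
        self.n_events_ = dd
        self.greenwood_var_ = gvar
        self.cum_hazard_var_ = cumvar
        self.median_ = self._median_ci()
        return self

    def predict(self, times) -> np.ndarray:
        """Evaluate the step-function estimate ``S(t)``; S = 1 before the
        first event and right-continuous thereafter."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times_, t, side="right")
        out = np.where(idx == 0, 1.0, self.survival_[np.maximum(idx - 1, 0)])
        return out if t.ndim else float(out)

    def confidence_band(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise band on the log(-log S) scale at the event times.

        ``theta = log(-log S)`` has standard error
        ``sqrt(cum_hazard_var) / |log S|``; back-transforming
        ``theta -/+ z * se`` gives ``S ** exp(-/+ z * se)``, which stays
        inside [0, 1] by construction.  Where S is 0 or 1 the band is
        degenerate at S.
        """
        z = stats.norm.ppf(0.5 + self.conf_level / 2.0)
        s = self.survival_
        lower = np.array(s)
        upper = np.array(s)
        interior = (s > 0) & (s < 1)
        logs = np.log(s[interior])
        se = np.sqrt(self.cum_hazard_var_[interior]) / np.abs(logs)
        lower[interior] = s[interior] ** np.exp(z * se)
        upper[interior] = s[interior] ** np.exp(-z * se)
        return lower, upper

    @staticmethod
    def _first_crossing(times: np.ndarray, values: np.ndarray) -> Optional[float]:
        # 1e-12 absorbs cumprod round-off when S sits exactly on one half
        below = np.nonzero(values <= 0.5 + 1e-12)[0]
        return float(times[below[0]]) if below.size else None

    def _median_ci(self) -> MedianEstimate:
        med = self._first_crossing(self.event_times_, self.survival_)
        lower, upper = self.confidence_band()
        # the lower band reaches 0.5 earliest -> lower CI bound; the upper
        # band last -> upper CI bound
        ci_low = self._first_crossing(self.event_times_, lower)
        ci_high = self._first_crossing(self.event_times_, upper)
        return MedianEstimate(median=med, ci_low=ci_low, ci_high=ci_high, level=self.conf_level)

    def curve_frame(self):
        """Step-function table (time, survival, at-risk, events, band)."""
        import pandas as pd

        lower, upper = self.confidence_band()
        return pd.DataFrame(
            {
                "time": self.event_times_,
                "survival": self.survival_,
                "at_risk": self.at_risk_,
                "n_events": self.n_events_,
                "ci_low": lower,
                "ci_high": upper,
            }
        )


def km_fit(sample: SurvivalSample) -> KMCurve:
    """Product-limit estimate of a right-censored sample."""
    est = KaplanMeierEstimator().fit(sample.durations, sample.event_observed)
    return KMCurve(
        event_times=est.event_times_,
        survival=est.survival_,
        at_risk=est.at_risk_,
        n_events=est.n_events_,
        greenwood_var=est.greenwood_var_,
        cum_hazard_var=est.cum_hazard_var_,
    )


def km_median_ci(curve: KMCurve, level: float = 0.95) -> MedianEstimate:
    """Median survival with a band-inversion confidence interval."""
    est = KaplanMeierEstimator(conf_level=level)
    est.event_times_ = curve.event_times
    est.survival_ = curve.survival
    est.cum_hazard_var_ = curve.cum_hazard_var
    return est._median_ci()


def logrank_test(sample: SurvivalSample) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test.

    At each distinct pooled event time the observed group-1 events are
    compared with their hypergeometric expectation given the margins;
    the squared standardised sum is referred to chi-square with 1 df.
    """
    if sample.group is None:
        raise ValueError("sample must carry a group label per subject")
    labels = np.unique(sample.group)
    if labels.size != 2:
        raise ValueError(f"log-rank test requires exactly two groups, got {labels.size}")
    in_g1 = sample.group == labels[0]
    d = sample.durations
    e = sample.event_observed

    event_times = np.unique(d[e])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = d >= u
        n = np.count_nonzero(at_risk)
        n1 = np.count_nonzero(at_risk & in_g1)
        dead = (d == u) & e
        dt = np.count_nonzero(dead)
        d1 = np.count_nonzero(dead & in_g1)
        o_minus_e += d1 - dt * n1 / n
        if n > 1:
            var += dt * (n1 / n) * (1 - n1 / n) * (n - dt) / (n - 1)
    if var == 0:
        # no between-group information (e.g. identical curves degenerate)
        return LogRankResult(chi_square=0.0, df=1, p_value=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(chi_square=float(chi2), df=1, p_value=float(stats.chi2.sf(chi2, 1)))


def combine_delays(
    approval_to_open: SurvivalSample, open_to_first_patient: SurvivalSample
) -> SurvivalSample:
    """Per-site total delay from approval to first patient.

    Durations add site-wise; the combined event is observed only when
    both component events were observed, otherwise the site is censored
    at its total observed time.  When both samples carry ``site_ids``
    the second is aligned to the first; mismatched site sets are an
    error, as are bare samples of unequal length.
    """
    a, b = approval_to_open, open_to_first_patient
    if a.site_ids is not None and b.site_ids is not None:
        if set(a.site_ids.tolist()) != set(b.site_ids.tolist()):
            raise ValueError("site sets of the two delay samples do not match")
        pos = {s: i for i, s in enumerate(b.site_ids.tolist())}
        perm = np.array([pos[s] for s in a.site_ids.tolist()])
        b = SurvivalSample(
            durations=b.durations[perm],
            event_observed=b.event_observed[perm],
            group=None if b.group is None else b.group[perm],
            site_ids=b.site_ids[perm],
        )
    elif len(a) != len(b):
        raise ValueError(
            f"cannot align delay samples of lengths {len(a)} and {len(b)} without site ids"
        )
    return SurvivalSample(
        durations=a.durations + b.durations,
        event_observed=a.event_observed & b.event_observed,
        group=a.group,
        site_ids=a.site_ids,
    )
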