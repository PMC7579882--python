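"""Site-table CSV dialect, JSON configs, and survival-sample builders.

The site table is comma-separated UTF-8 with a mandatory header, one row
per site, times as integer day offsets from study start (day 0) and the
literal string ``NA`` for censored or absent values.  Column order is
fixed:

    site_id, region, approval_day, pharmacy_day, pharmacy_delayed,
    opened, opening_day, first_patient_day, recruited_total
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .planner import TrialPlan
from .simulate import FixedDelay, LognormalDelay, SimulationConfig
from .survival import SurvivalSample
from .synthetic import SiteGenerationConfig, SiteRecord

__all__ = [
    "SITE_TABLE_COLUMNS",
    "SiteTableError",
    "write_site_table",
    "read_site_table",
    "read_generation_config",
    "read_trial_plan",
    "read_simulation_config",
    "opening_delay_sample",
    "first_patient_sample",
    "combined_delay_sample",
]

SITE_TABLE_COLUMNS = (
    "site_id",
    "region",
    "approval_day",
    "pharmacy_day",
    "pharmacy_delayed",
    "opened",
    "opening_day",
    "first_patient_day",
    "recruited_total",
)

_NA = "NA"


class SiteTableError(ValueError):
    """Malformed site table; message carries the offending line number."""


def write_site_table(records: Sequence[SiteRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "site_id": r.site_id,
                "region": r.region,
                "approval_day": r.approval_day,
                "pharmacy_day": r.pharmacy_day,
                "pharmacy_delayed": int(r.pharmacy_delayed),
                "opened": int(r.opened),
                "opening_day": _NA if r.opening_day is None else r.opening_day,
                "first_patient_day": _NA if r.first_patient_day is None else r.first_patient_day,
                "recruited_total": r.recruited_total,
            }
        )
    pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS)).to_csv(path, index=False)


def _opt_int(value, column: str, line: int) -> Optional[int]:
    if pd.isna(value):
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        raise SiteTableError(f"line {line}: column {column!r} has non-integer value {value!r}")


def read_site_table(path: Union[str, Path]) -> list[SiteRecord]:
    """Parse and validate a site-table CSV.

    Raises :class:`SiteTableError` naming the missing column or the
    1-based file line of the first invalid row (the header is line 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, na_values=[_NA], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SiteTableError(f"{path}: empty site table (no header)")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SiteTableError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise SiteTableError(f"{path}: site table has a header but no rows")

    records = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            records.append(
                SiteRecord(
                    site_id=str(row["site_id"]),
                    approval_day=int(row["approval_day"]),
                    opened=bool(int(row["opened"])),
                    opening_day=_opt_int(row["opening_day"], "opening_day", line),
                    pharmacy_day=int(row["pharmacy_day"]),
                    pharmacy_delayed=bool(int(row["pharmacy_delayed"])),
                    first_patient_day=_opt_int(
                        row["first_patient_day"], "first_patient_day", line
                    ),
                    region=str(row["region"]),
                    recruited_total=int(row["recruited_total"]),
                )
            )
        except SiteTableError:
            raise
        except (TypeError, ValueError) as exc:
            raise SiteTableError(f"line {line}: {exc}") from exc
    return records


def _load_json(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def read_generation_config(path: Union[str, Path], seed: Optional[int] = None) -> SiteGenerationConfig:
    data = _load_json(path)
    if "pharmacy_holdup_range_days" in data:
        data["pharmacy_holdup_range_days"] = tuple(data["pharmacy_holdup_range_days"])
    if seed is not None:
        data["seed"] = seed
    return SiteGenerationConfig(**data)


def read_trial_plan(path: Union[str, Path]) -> TrialPlan:
    return TrialPlan(**_load_json(path))


def read_simulation_config(
    path: Union[str, Path],
    seed: Optional[int] = None,
    n_replicates: Optional[int] = None,
) -> SimulationConfig:
    """Simulation config JSON; ``delay_model`` is a tagged object, e.g.
    ``{"kind": "fixed", "delay_days": 182}`` or
    ``{"kind": "lognormal", "median_days": 182, "log_sd": 0.62}``."""
    data = _load_json(path)
    model = dict(data.pop("delay_model"))
    kind = model.pop("kind")
    if kind == "fixed":
        data["delay_model"] = FixedDelay(**model)
    elif kind == "lognormal":
        data["delay_model"] = LognormalDelay(**model)
    else:
        raise ValueError(f"unknown delay model kind {kind!r}")
    if seed is not None:
        data["seed"] = seed
    if n_replicates is not None:
        data["n_replicates"] = n_replicates
    return SimulationConfig(**data)


def _infer_study_end(records: Sequence[SiteRecord]) -> int:
    days = [r.approval_day for r in records]
    days += [r.opening_day for r in records if r.opening_day is not None]
    days += [r.first_patient_day for r in records if r.first_patient_day is not None]
    days += [r.pharmacy_day for r in records]
    return max(days)


def opening_delay_sample(
    records: Sequence[SiteRecord], study_end_day: Optional[int] = None
) -> SurvivalSample:
    """Approval-to-opening durations; unopened sites censored at study end.

    When ``study_end_day`` is omitted it is taken as the latest day
    appearing anywhere in the table (a conservative stand-in).
    """
    end = _infer_study_end(records) if study_end_day is None else study_end_day
    durations, events, groups, ids = [], [], [], []
    for r in records:
        if r.opened:
            durations.append(r.opening_day - r.approval_day)
            events.append(True)
        else:
            durations.append(max(0, end - r.approval_day))
            events.append(False)
        groups.append(r.region)
        ids.append(r.site_id)
    return SurvivalSample(
        durations=np.array(durations, dtype=float),
        event_observed=np.array(events),
        group=np.array(groups),
        site_ids=np.array(ids),
    )


def first_patient_sample(
    records: Sequence[SiteRecord],
    study_end_day: Optional[int] = None,
    include_unopened: bool = False,
) -> SurvivalSample:
    """Opening-to-first-patient durations for open sites.

    With ``include_unopened=True`` never-opened sites contribute zero
    observed time, censored — the alignment needed to combine this
    sample with the opening-delay sample over the full site set.
    """
    end = _infer_study_end(records) if study_end_day is None else study_end_day
    durations, events, groups, ids = [], [], [], []
    for r in records:
        if r.opened:
            if r.first_patient_day is not None:
                durations.append(r.first_patient_day - r.opening_day)
                events.append(True)
            else:
                durations.append(max(0, end - r.opening_day))
                events.append(False)
        elif include_unopened:
            durations.append(0.0)
            events.append(False)
        else:
            continue
        groups.append(r.region)
        ids.append(r.site_id)
    if not durations:
        raise ValueError("no opened sites in table")
    return SurvivalSample(
        durations=np.array(durations, dtype=float),
        event_observed=np.array(events),
        group=np.array(groups),
        site_ids=np.array(ids),
    )


def combined_delay_sample(
    records: Sequence[SiteRecord], study_end_day: Optional[int] = None
) -> SurvivalSample:
    """Total approval-to-first-patient time over the full site set."""
    from .survival import combine_delays

    a = opening_delay_sample(records, study_end_day)
    b = first_patient_sample(records, study_end_day, include_unopened=True)
    return combine_delays(a, b)
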