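"""Kaplan-Meier estimation and two-group log-rank comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from lifelines.statistics import logrank_test

from .profiles import PatientProfile, RiskStratum, Scheme, stratify

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "StrataComparison",
    "km_estimate",
    "log_rank",
    "compare_strata",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = death, 0 = censored

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) immediately after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Product-limit survival estimate.

    S(t) multiplies (1 - d_i/n_i) over event times <= t.  At a tied time,
    deaths are counted before censorings leave the risk set.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)

    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    n_events = []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        n_events.append(d_i)
        surv.append(s)
    return KmCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
    )


def log_rank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df.

    Raises when either group is empty or no events occurred at all.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        raise ValueError("log-rank undefined with zero events")
    res = logrank_test(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StrataComparison:
    scheme: Scheme
    group_a: RiskStratum
    group_b: RiskStratum
    curve_a: Optional[KmCurve]
    curve_b: Optional[KmCurve]
    chi_square: Optional[float]
    p_value: Optional[float]
    excluded: list[str]
    flags: list[str]


def compare_strata(
    profiles: Sequence[PatientProfile],
    survival_table: Mapping[str, SurvivalRecord],
    scheme: Scheme | str,
) -> StrataComparison:
    """KM curves plus a log-rank test for one stratification scheme.

    Patients without survival records are excluded and reported; groups
    of size < 2 are flagged under-powered, and an empty group suppresses
    the test rather than failing.
    """
    scheme = Scheme(scheme)
    stratum_a, stratum_b, excluded = stratify(profiles, scheme)
    flags: list[str] = []

    def records_for(stratum: RiskStratum) -> list[SurvivalRecord]:
        recs = []
        for pid in stratum.patient_ids:
            rec = survival_table.get(pid)
            if rec is None:
                excluded.append(pid)
            else:
                recs.append(rec)
        return recs

    recs_a = records_for(stratum_a)
    recs_b = records_for(stratum_b)
    curve_a = km_estimate(recs_a) if recs_a else None
    curve_b = km_estimate(recs_b) if recs_b else None

    chi, p = None, None
    if not recs_a or not recs_b:
        flags.append("empty_group_no_test")
    else:
        if min(len(recs_a), len(recs_b)) < 2:
            flags.append("under_powered")
        try:
            chi, p = log_rank(recs_a, recs_b)
        except ValueError as exc:
            flags.append(f"test_undefined: {exc}")

    return StrataComparison(
        scheme=scheme,
        group_a=RiskStratum(stratum_a.label, [r.patient_id for r in recs_a]),
        group_b=RiskStratum(stratum_b.label, [r.patient_id for r in recs_b]),
        curve_a=curve_a,
        curve_b=curve_b,
        chi_square=chi,
        p_value=p,
        excluded=excluded,
        flags=flags,
    )
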