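"""Longitudinal score timelines, change-threshold scans, molecular lead
time, and survival comparisons (Kaplan-Meier, log-rank, delegated Cox).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import SCHEDULE, ClinicalTable

DEFAULT_CHANGE_GRID = tuple(range(50, -60, -10))  # +50 ... -50 in 10% steps
DEFAULT_PAIRS = (
    ("BL", "F5"), ("BL", "F10"), ("BL", "END"),
    ("F5", "F10"), ("F5", "END"), ("F10", "END"),
)


@dataclass
class ScoreTimeline:
    """Ordered scores for one patient plus clinical anchors.

    ``points`` columns: timepoint, months, score, threshold, positive.
    """

    patient_id: str
    points: pd.DataFrame
    pd_months: tuple[float, ...]
    pfs_months: float
    event: bool

    def __post_init__(self) -> None:
        months = self.points["months"].to_numpy(dtype=float)
        if np.any(np.diff(months) <= 0):
            raise ValueError(f"{self.patient_id}: months must be strictly increasing")

    def score_at(self, timepoint: str) -> float | None:
        hit = self.points[self.points["timepoint"] == timepoint]
        if hit.empty:
            return None
        return float(hit["score"].iloc[0])

    def positive_at(self, timepoint: str) -> bool | None:
        hit = self.points[self.points["timepoint"] == timepoint]
        if hit.empty:
            return None
        return bool(hit["positive"].iloc[0])


@dataclass
class SurvivalResult:
    labels: tuple[str, str]
    km: dict[str, pd.DataFrame]
    statistic: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    n: tuple[int, int]


def build_timelines(scores: pd.DataFrame, clinical: ClinicalTable) -> list[ScoreTimeline]:
    """Assemble per-patient timelines from a scores table (columns: sample,
    patient, timepoint, cpa, cpa_threshold, cpa_positive, ctcpa,
    ctcpa_threshold, ctcpa_positive, ...).

    The monitored score is ctCPA when available for the sample and CPA
    otherwise, with the matching threshold and flag.
    """
    scores = scores[scores["patient"].notna() & (scores["patient"] != "")]
    out = []
    for pid, grp in scores.groupby("patient", sort=True):
        rows = []
        for r in grp.itertuples(index=False):
            use_ct = np.isfinite(r.ctcpa) if "ctcpa" in grp.columns else False
            score = r.ctcpa if use_ct else r.cpa
            thr = r.ctcpa_threshold if use_ct else r.cpa_threshold
            pos = r.ctcpa_positive if use_ct else r.cpa_positive
            rows.append((r.timepoint, SCHEDULE[r.timepoint], score, thr, bool(pos)))
        pts = pd.DataFrame(
            rows, columns=["timepoint", "months", "score", "threshold", "positive"]
        ).sort_values("months", ignore_index=True)
        clin = clinical.table.loc[pid]
        out.append(
            ScoreTimeline(
                patient_id=str(pid),
                points=pts,
                pd_months=tuple(clin["pd_months"]),
                pfs_months=float(clin["pfs_months"]),
                event=bool(clin["event"]),
            )
        )
    return out


def relative_change(score_early: float, score_late: float) -> float:
    """Percent change 100 * (late - early) / |early|; undefined at
    early == 0."""
    if score_early == 0:
        raise ValueError("relative change undefined for a zero early score")
    return 100.0 * (score_late - score_early) / abs(score_early)


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimator.

    Returns one row per distinct event/censor time with columns time,
    at_risk, events, censored, survival; survival is right-continuous and
    non-increasing, starting from 1 at time 0.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n_at_risk = t.size
    for u in np.unique(t):
        mask = t == u
        d = int(e[mask].sum())
        c = int((~e[mask]).sum())
        if d > 0:
            surv *= 1.0 - d / n_at_risk
        rows.append((float(u), n_at_risk, d, c, surv))
        n_at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "survival"])


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-sided log-rank test: chi-square statistic (1 df) and p-value."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event")
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        n_a = int((ta >= u).sum())
        n_b = int((tb >= u).sum())
        d_a = int(((ta == u) & ea).sum())
        d_b = int(((tb == u) & eb).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n_a == 0 or n_b == 0 or n <= 1:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _cox_hr(durations, events, groups) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of group=1 vs group=0 from a delegated single-covariate
    Cox fit; (nan, (nan, nan)) when the fit is not estimable."""
    try:
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {"duration": durations, "event": np.asarray(events, dtype=int),
             "group": np.asarray(groups, dtype=int)}
        )
        with warnings.catch_warnings(), np.errstate(over="ignore"):
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="duration", event_col="event")
            hr = float(np.exp(cph.params_["group"]))
            lo, hi = np.exp(cph.confidence_intervals_.loc["group"]).to_numpy(dtype=float)
        return hr, (float(lo), float(hi))
    except Exception:
        return float("nan"), (float("nan"), float("nan"))


def compare_groups(
    durations_a, events_a, durations_b, events_b, labels=("A", "B")
) -> SurvivalResult:
    stat, p = logrank_test(durations_a, events_a, durations_b, events_b)
    durations = np.concatenate([durations_a, durations_b])
    events = np.concatenate([np.asarray(events_a, bool), np.asarray(events_b, bool)])
    groups = np.concatenate([np.zeros(len(durations_a)), np.ones(len(durations_b))])
    hr, ci = _cox_hr(durations, events, groups)
    return SurvivalResult(
        labels=tuple(labels),
        km={labels[0]: km_estimate(durations_a, events_a),
            labels[1]: km_estimate(durations_b, events_b)},
        statistic=stat, p_value=p, hazard_ratio=hr, hr_ci=ci,
        n=(len(durations_a), len(durations_b)),
    )


def positivity_vs_pfs(
    timelines: list[ScoreTimeline],
    clinical: ClinicalTable,
    timepoint: str,
    horizon: str | None = None,
) -> SurvivalResult:
    """PFS of ctDNA-positive versus -negative patients at one sampling
    timepoint (scores must have been computed with the matching horizon)."""
    horizon = horizon or timepoint
    if SCHEDULE[horizon] < SCHEDULE[timepoint]:
        raise ValueError("horizon cannot precede the evaluated timepoint")
    pos_d, pos_e, neg_d, neg_e = [], [], [], []
    for tl in timelines:
        flag = tl.positive_at(timepoint)
        if flag is None:
            continue
        (pos_d if flag else neg_d).append(tl.pfs_months)
        (pos_e if flag else neg_e).append(tl.event)
    if not pos_d or not neg_d:
        empty = pd.DataFrame(
            columns=["time", "at_risk", "events", "censored", "survival"]
        )
        return SurvivalResult(
            labels=("negative", "positive"),
            km={"negative": km_estimate(neg_d, neg_e) if neg_d else empty,
                "positive": km_estimate(pos_d, pos_e) if pos_d else empty},
            statistic=float("nan"), p_value=float("nan"),
            hazard_ratio=float("nan"), hr_ci=(float("nan"), float("nan")),
            n=(len(neg_d), len(pos_d)),
        )
    return compare_groups(neg_d, neg_e, pos_d, pos_e, labels=("negative", "positive"))


def scan_change_thresholds(
    timelines: list[ScoreTimeline],
    clinical: ClinicalTable,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    grid: Sequence[float] = DEFAULT_CHANGE_GRID,
) -> pd.DataFrame:
    """Scan relative-change cut-offs over timepoint pairs.

    For every (pair, cut) the cohort is split into change <= cut versus the
    rest and compared by log-rank; no detectability cut-off is applied.
    Rows with a group of fewer than 2 patients carry p = NaN.  A Bonferroni
    column (p times number of tested rows) is reported alongside the raw p.
    """
    rows = []
    for early_tp, late_tp in pairs:
        changes = {}
        for tl in timelines:
            e = tl.score_at(early_tp)
            l = tl.score_at(late_tp)
            if e is None or l is None or not np.isfinite(e) or not np.isfinite(l):
                continue
            if e == 0:
                continue  # undefined change; flagged by omission
            changes[tl.patient_id] = relative_change(e, l)
        for cut in grid:
            in_a = [p for p, c in changes.items() if c <= cut]
            in_b = [p for p, c in changes.items() if c > cut]
            if len(in_a) < 2 or len(in_b) < 2:
                rows.append((f"{early_tp}->{late_tp}", cut, len(in_a), len(in_b),
                             np.nan, np.nan, np.nan, np.nan))
                continue
            clin = clinical.table
            res = compare_groups(
                clin.loc[in_a, "pfs_months"], clin.loc[in_a, "event"],
                clin.loc[in_b, "pfs_months"], clin.loc[in_b, "event"],
                labels=("le_cut", "gt_cut"),
            )
            rows.append((f"{early_tp}->{late_tp}", cut, len(in_a), len(in_b),
                         res.p_value, res.hazard_ratio, *res.hr_ci))
    df = pd.DataFrame(
        rows,
        columns=["pair", "cut_pct", "n_le_cut", "n_gt_cut", "logrank_p",
                 "hazard_ratio", "hr_lo", "hr_hi"],
    )
    df["bonferroni_p"] = np.clip(df["logrank_p"] * len(df), 0, 1)
    return df


def molecular_lead_time(tl: ScoreTimeline) -> float | None:
    """Months by which a ctDNA rise precedes radiographic progression.

    The rise is the first timepoint after the score nadir where the score
    exceeds the previous sample's and the sample is ctDNA-positive; only
    samples collected before the first PD date count.  None when there is
    no PD date or no qualifying rise.  Never negative.
    """
    if not tl.pd_months:
        return None
    pd_month = tl.pd_months[0]
    pts = tl.points[tl.points["months"] < pd_month]
    if len(pts) < 2:
        return None
    scores = pts["score"].to_numpy(dtype=float)
    months = pts["months"].to_numpy(dtype=float)
    positive = pts["positive"].to_numpy(dtype=bool)
    nadir = int(np.nanargmin(scores))
    for i in range(nadir + 1, len(pts)):
        if scores[i] > scores[i - 1] and positive[i]:
            return float(pd_month - months[i])
    return None
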