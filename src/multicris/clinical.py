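"""Clinical and biological association of subtype calls.

Survival: Kaplan-Meier product-limit curves and the two-group log-rank test,
both computed after recoding every follow-up time beyond the horizon
(default 36 months) as censored at the horizon — patients still disease-free
past the horizon count as disease-free at the endpoint.

Enrichment: Fisher exact tests with odds ratios over four cohort
constructions per target class (single-label; primary excluding
secondary-carrying controls; secondary only; primary plus secondary), always
contrasting against samples not assigned to the target class at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .types import ClinicalTable, MultiLabelAssignment, NOT_CLASSIFIED, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 36.0

COHORT_MODES = (
    "single_label",
    "primary_only_excluding_secondary",
    "secondary_only",
    "primary_plus_secondary",
)


def recode_horizon(
    times: Sequence[float], events: Sequence[bool], horizon: float = DEFAULT_HORIZON
) -> Tuple[np.ndarray, np.ndarray]:
    """Administrative recoding: any observation with time > horizon becomes
    censored at the horizon; events at or before the horizon are kept."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValidationError("survival times must be nonnegative")
    over = t > horizon
    t = np.where(over, horizon, t)
    e = np.where(over, False, e)
    return t, e


def km_curve(
    times: Sequence[float], events: Sequence[bool], horizon: float = DEFAULT_HORIZON
) -> pd.DataFrame:
    """Kaplan-Meier step function after horizon recoding.

    Returns a frame with columns ``time``, ``survival``, ``at_risk``,
    ``censored`` (number censored at that time).
    """
    t, e = recode_horizon(times, events, horizon)
    if t.size == 0:
        raise ValidationError("cannot estimate a survival curve from an empty group")
    km = KaplanMeierFitter()
    km.fit(t, event_observed=e)
    surv = km.survival_function_
    table = km.event_table
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
        }
    )
    out["at_risk"] = table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    out["censored"] = table["censored"].reindex(surv.index).fillna(0).to_numpy(dtype=float)
    return out


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
    horizon: float = DEFAULT_HORIZON,
) -> Tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance across distinct event
    times) after horizon recoding. Returns ``(chi2 statistic, p-value)``."""
    ta, ea = recode_horizon(times_a, events_a, horizon)
    tb, eb = recode_horizon(times_b, events_b, horizon)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        raise ValidationError("no events in either group; log-rank undefined")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# cohort constructions


@dataclass(frozen=True)
class CohortDefinition:
    """In-group vs out-group for one target class under one construction
    mode. The two groups are disjoint; samples assigned to the target class
    in a way the mode excludes belong to neither."""

    target: str
    mode: str
    in_group: Tuple[str, ...]
    out_group: Tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.in_group) & set(self.out_group):
            raise ValidationError("cohort in/out groups must be disjoint")


def build_cohorts(
    assignments: Sequence[MultiLabelAssignment], target: str
) -> Dict[str, CohortDefinition]:
    """The four constructions contrasting a target class against samples not
    assigned to it at all (not-classified samples belong to neither group)."""
    classified = [a for a in assignments if a.primary != NOT_CLASSIFIED]
    primary = [a.sample_id for a in classified if a.primary == target]
    secondary = [a.sample_id for a in classified if target in a.secondary]
    untouched = [a.sample_id for a in classified if target not in a.labels]
    non_primary = [a.sample_id for a in classified if a.primary != target]
    cohorts = {
        "single_label": CohortDefinition(target, "single_label", tuple(primary), tuple(non_primary)),
        "primary_only_excluding_secondary": CohortDefinition(
            target, "primary_only_excluding_secondary", tuple(primary), tuple(untouched)
        ),
        "secondary_only": CohortDefinition(
            target, "secondary_only", tuple(secondary), tuple(untouched)
        ),
        "primary_plus_secondary": CohortDefinition(
            target, "primary_plus_secondary", tuple(sorted(set(primary) | set(secondary))), tuple(untouched)
        ),
    }
    for mode, c in cohorts.items():
        if not c.in_group:
            logger.warning("target %s, mode %s: empty in-group; association will be skipped", target, mode)
    return cohorts


# ---------------------------------------------------------------------------
# Fisher association


@dataclass(frozen=True)
class FisherResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]  # rows: in/out, cols: flag+/flag-
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool
    rate_in: float
    rate_out: float
    rate_overall: float
    lift_vs_overall: float
    risk_ratio_vs_complement: float


def fisher_association(
    cohort: CohortDefinition, annotation: Mapping[str, bool]
) -> FisherResult:
    """Two-sided Fisher exact test of a boolean annotation against the
    cohort's in/out split.

    The p-value is the exact hypergeometric two-sided (point-probability)
    value. The sample odds ratio is (a*d)/(b*c) with the Haldane-Anscombe
    0.5 correction applied to every cell when any cell is zero; the 95% CI is
    the log-OR normal approximation on the (possibly corrected) cells.
    Effect sizes for both framings are reported: the in-group positive rate
    against the overall rate (lift) and against the complement's rate (risk
    ratio).
    """
    in_flags = [bool(annotation[s]) for s in cohort.in_group if s in annotation]
    out_flags = [bool(annotation[s]) for s in cohort.out_group if s in annotation]
    a = sum(in_flags)
    b = len(in_flags) - a
    c = sum(out_flags)
    d = len(out_flags) - c
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValidationError(f"degenerate 2x2 margin for table {(a, b, c, d)}")
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 if corrected else v for v in (a, b, c, d))
    odds_ratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    ci_low = math.exp(math.log(odds_ratio) - 1.959963984540054 * se)
    ci_high = math.exp(math.log(odds_ratio) + 1.959963984540054 * se)
    rate_in = a / (a + b)
    rate_out = c / (c + d)
    rate_overall = (a + c) / (a + b + c + d)
    lift = rate_in / rate_overall if rate_overall > 0 else math.inf
    rr = rate_in / rate_out if rate_out > 0 else math.inf
    return FisherResult(
        table=((a, b), (c, d)),
        p_value=float(p),
        odds_ratio=float(odds_ratio),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        haldane_corrected=corrected,
        rate_in=rate_in,
        rate_out=rate_out,
        rate_overall=rate_overall,
        lift_vs_overall=lift,
        risk_ratio_vs_complement=rr,
    )


def dichotomize_response(
    clinical: ClinicalTable, positive: Sequence[str] = ("sensitive",)
) -> Dict[str, bool]:
    """Binary drug-response flag, default sensitive vs {stable, resistant}."""
    if "response" not in clinical.data.columns:
        raise ValidationError("clinical table has no response column")
    resp = clinical.data["response"].dropna()
    return {s: (r in set(positive)) for s, r in resp.items()}


def survival_association(
    assignments: Sequence[MultiLabelAssignment],
    clinical: ClinicalTable,
    target: str,
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Log-rank p-values of in-group vs out-group survival for all four
    cohort constructions of one target class."""
    if "time" not in clinical.data.columns:
        raise ValidationError("clinical table has no survival columns")
    cohorts = build_cohorts(assignments, target)
    rows = []
    for mode, c in cohorts.items():
        in_ids = [s for s in c.in_group if s in clinical.data.index]
        out_ids = [s for s in c.out_group if s in clinical.data.index]
        if not in_ids or not out_ids:
            rows.append((mode, len(in_ids), len(out_ids), float("nan"), float("nan")))
            continue
        stat, p = logrank(
            clinical.data.loc[in_ids, "time"],
            clinical.data.loc[in_ids, "event"],
            clinical.data.loc[out_ids, "time"],
            clinical.data.loc[out_ids, "event"],
            horizon=horizon,
        )
        rows.append((mode, len(in_ids), len(out_ids), stat, p))
    return pd.DataFrame(rows, columns=["mode", "n_in", "n_out", "logrank_stat", "p_value"]).set_index("mode")
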