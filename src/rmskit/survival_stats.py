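"""Time-to-event statistics for embryo survival and tumor incidence.

Covers the statistics used when scoring transgenic zebrafish
experiments: Kaplan-Meier survival curves of injected embryo groups
observed daily, two-group log-rank comparisons, cumulative tumor
incidence among adults surviving past a minimum age, and Fisher's exact
test for phenotype proportions.

Conventions: event times are positive days; at tied times events are
processed before censorings (the standard product-limit convention);
the two-sided Fisher p-value follows the probability-mass rule (sum of
hypergeometric probabilities of margin-fixed tables at most as probable
as the observed one).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "read_survival_table",
    "km_estimate",
    "logrank_test",
    "tumor_incidence",
    "fisher_exact",
]

_REQUIRED = ("subject_id", "group", "time", "event")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (table["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return table


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV survival table (subject_id, group, time, event in {1,0})."""
    return _validate(pd.read_csv(path, sep="\t"))


def _group(table: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} empty or absent")
    return sub


def km_estimate(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve for one group.

    Returns a step function as a DataFrame with one row per observed
    time: columns time, survival (S(t)), n_at_risk, n_events.  S(0)=1
    implicitly; censored subjects leave the risk set after their time.
    """
    sub = _group(_validate(table), group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    ev = kmf.event_table.iloc[1:] if 0 in kmf.event_table.index else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    rows = []
    for t in ev.index:
        rows.append(
            {
                "time": float(t),
                "survival": float(surv.loc[t]),
                "n_at_risk": int(ev.loc[t, "at_risk"]),
                "n_events": int(ev.loc[t, "observed"]),
            }
        )
    return pd.DataFrame(rows)


def logrank_test(
    table: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p_value).

    Sums observed-minus-expected events over event times with the
    hypergeometric variance; the statistic is chi-square with 1 df.
    With no events anywhere the statistic is 0 and p is 1.
    """
    table = _validate(table)
    a = _group(table, group_a)
    b = _group(table, group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def tumor_incidence(
    table: pd.DataFrame, group: str, min_age: float = 30.0
) -> pd.DataFrame:
    """Cumulative tumor incidence, excluding early tumor-free deaths.

    ``event`` = 1 marks fluorescence-confirmed tumor detection; subjects
    censored (tumor-free) before ``min_age`` days are excluded from the
    denominator, implementing the rule that only animals surviving past
    that age enter the analysis.  Tumor-free animals are censored at
    their last observation.  Returns a step function with columns time,
    incidence (= 1 - KM(t)), n_at_risk, n_events.
    """
    sub = _group(_validate(table), group)
    keep = ~((sub["event"] == 0) & (sub["time"] < min_age))
    sub = sub[keep]
    if sub.empty:
        raise ValueError(f"all subjects in {group!r} excluded by min_age={min_age}")
    curve = km_estimate(sub, group)
    curve = curve.rename(columns={"survival": "incidence"})
    curve["incidence"] = 1.0 - curve["incidence"]
    return curve


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]] of non-negative integer counts with at
    least one positive margin.  The two-sided p is the total
    hypergeometric probability of all margin-fixed tables at most as
    probable as the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.all(arr == np.round(arr)):
        raise ValueError("counts must be integers")
    if arr.sum() == 0:
        raise ValueError("at least one margin must be positive")
    _, p = sps.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p)
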