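"""Kaplan-Meier estimation and log-rank comparison of overall survival
between carriers and non-carriers of HLA-matched clones.

Tie convention: at equal times, events precede censorings (censored subjects
remain at risk at their censoring time), so curves are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HLAGenotypes, ValidationError
from .dynamics import HLAMatchRule, _matched_flags

__all__ = ["KMCurve", "km_estimate", "logrank", "carrier_status"]


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate: event times (ascending), at-risk counts,
    event counts and survival probabilities after each time."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    if len(records) == 0:
        raise ValidationError("need >= 1 record")
    t = records["os_time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    if (t < 0).any():
        raise ValidationError("negative survival times")
    times = np.unique(t[e])
    at_risk = np.empty(len(times))
    events = np.empty(len(times))
    surv = np.empty(len(times))
    s = 1.0
    for i, ti in enumerate(times):
        at_risk[i] = np.sum(t >= ti)
        events[i] = np.sum((t == ti) & e)
        s *= 1.0 - events[i] / at_risk[i]
        surv[i] = s
    return KMCurve(times, at_risk, events, surv)


def logrank(groups: dict[str, pd.DataFrame] | pd.DataFrame
            ) -> tuple[float, int, float]:
    """Log-rank test across two or more groups.

    ``groups`` is either a mapping label -> survival frame or one frame with
    a ``group`` column.  Returns (chi2, df, p) with df = #groups - 1.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {str(k): v for k, v in groups.groupby("group")}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    t = np.concatenate([groups[g]["os_time"].to_numpy(float) for g in labels])
    e = np.concatenate([groups[g]["event"].to_numpy(bool) for g in labels])
    gidx = np.concatenate([
        np.full(len(groups[g]), i) for i, g in enumerate(labels)
    ])
    if not e.any():
        raise ValidationError("log-rank needs >= 1 event")
    k = len(labels)
    event_times = np.unique(t[e])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        n = at_risk.sum()
        d = ((t == ti) & e).sum()
        n_g = np.array([(at_risk & (gidx == i)).sum() for i in range(k)], float)
        d_g = np.array([((t == ti) & e & (gidx == i)).sum() for i in range(k)], float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if len(diff) == 1 and Vsub[0, 0] == 0:
        chi2 = 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def carrier_status(
    individuals: Sequence[str],
    clones: pd.DataFrame,
    rules: Sequence[HLAMatchRule],
    hla: HLAGenotypes,
    timepoints: Sequence[str] = ("C1", "C2"),
) -> pd.Series:
    """1 if the individual has >= 1 HLA-matched clone at any included
    timepoint, 0 otherwise; NaN for individuals absent from the clone table."""
    sub = clones[clones["timepoint"].isin(timepoints)]
    matched = sub.loc[_matched_flags(sub, rules, hla)]
    carrier_ids = set(matched["individual_id"])
    present = set(sub["individual_id"])
    vals = [
        (1.0 if i in carrier_ids else 0.0) if i in present else np.nan
        for i in individuals
    ]
    return pd.Series(vals, index=list(individuals), name="carrier")
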