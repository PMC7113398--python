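"""Cumulative risk score (RS) and threshold stratification.

Each patient scores +1 per survival-unfavorable (SU) superallele
carried and -1 per survival-favorable (SF) superallele carried; the sum
is the risk score.  A threshold t splits the cohort into high-risk
(RS >= t, inclusive by default) and low-risk groups, whose separation
is then measured by the Cox hazard ratio and log-rank test on observed
survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survstats import group_hazard_ratio

__all__ = [
    "compute_risk_scores",
    "StratifyResult",
    "stratify_by_threshold",
    "threshold_sweep",
]


def compute_risk_scores(
    cohort: Cohort, sf_set: Iterable[str], su_set: Iterable[str]
) -> pd.Series:
    """Per-patient RS = (# SU superalleles carried) - (# SF superalleles carried).

    SF and SU sets must be disjoint.  Superalleles named in either set
    but absent from the cohort's presence matrix count as universally
    non-carried (warned).
    """
    sf = list(dict.fromkeys(sf_set))
    su = list(dict.fromkeys(su_set))
    overlap = set(sf) & set(su)
    if overlap:
        raise ValueError(f"SF and SU sets overlap: {sorted(overlap)}")
    missing = (set(sf) | set(su)) - set(cohort.presence.columns)
    if missing:
        import warnings

        warnings.warn(
            f"superalleles not present in cohort, counted as non-carried: {sorted(missing)}",
            stacklevel=2,
        )
    sf_cols = [c for c in sf if c in cohort.presence.columns]
    su_cols = [c for c in su if c in cohort.presence.columns]
    rs = cohort.presence[su_cols].sum(axis=1) - cohort.presence[sf_cols].sum(axis=1)
    return rs.astype(int).rename("risk_score")


@dataclass
class StratifyResult:
    labels: pd.Series  # True = high-risk
    threshold: int
    n_high: int
    n_low: int
    degenerate: bool  # one group empty


def stratify_by_threshold(
    rs: pd.Series, threshold: int, inclusive: bool = True
) -> StratifyResult:
    """High-risk iff RS >= threshold (strict > with ``inclusive=False``).

    A split that leaves either group empty is returned flagged, not
    raised.
    """
    labels = rs >= threshold if inclusive else rs > threshold
    n_high = int(labels.sum())
    n_low = int((~labels).sum())
    return StratifyResult(
        labels=labels.rename("high_risk"),
        threshold=int(threshold),
        n_high=n_high,
        n_low=n_low,
        degenerate=(n_high == 0 or n_low == 0),
    )


def threshold_sweep(
    cohort: Cohort,
    sf_set: Iterable[str],
    su_set: Iterable[str],
    thresholds: Sequence[int],
    inclusive: bool = True,
    ties: str = "efron",
) -> pd.DataFrame:
    """HR / CI / log-rank p of the RS split at each threshold.

    Columns: threshold, n_low, n_high, hr, ci_low, ci_high, p,
    degenerate, separated.  Splits leaving a group empty (degenerate)
    or whose Cox likelihood is monotone (separated, e.g. a handful of
    high-risk patients who all die first) carry NaN statistics and the
    corresponding flag.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    rs = compute_risk_scores(cohort, sf_set, su_set)
    time = cohort.os_months.to_numpy(dtype=float)
    event = cohort.event.to_numpy(dtype=int)
    rows = []
    for thr in thresholds:
        strat = stratify_by_threshold(rs, thr, inclusive=inclusive)
        row = {
            "threshold": strat.threshold,
            "n_low": strat.n_low,
            "n_high": strat.n_high,
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "degenerate": strat.degenerate,
            "separated": False,
        }
        if not strat.degenerate:
            ghr = group_hazard_ratio(
                time, event, strat.labels.to_numpy(), ties=ties, on_separation="return"
            )
            if ghr.separated:
                row["separated"] = True
            else:
                row.update(hr=ghr.hr, ci_low=ghr.ci95[0], ci_high=ghr.ci95[1], p=ghr.p)
        rows.append(row)
    return pd.DataFrame(rows)
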