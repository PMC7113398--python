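"""Superallele screening: survival-favorable / survival-unfavorable classes.

For each superallele carried by at least ``min_support`` patients the
cohort splits into carriers and non-carriers; the mean overall survival
(MOS, months) of each group is compared with a two-sample t-test.  A
positive significant mean difference (carriers live longer) marks the
superallele survival-favorable (SF); a negative significant difference
marks it survival-unfavorable (SU); everything else is not significant
(NS).

Statistical caveat, on purpose: the group means use the raw follow-up
months of every patient, censored or not — the published screen is
defined (and only reproducible) this way.  A censoring-aware analysis
of the same contrast is available through
:func:`hlasurv.survstats.group_hazard_ratio` on the carrier indicator.

No multiplicity correction changes the SF/SU call; a Benjamini-Hochberg
column is emitted alongside for the reader.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .survstats import welch_t_test

__all__ = [
    "SF",
    "SU",
    "NS",
    "classify",
    "screen_superalleles",
    "sf_su_sets",
    "load_published_screen",
]

SF = "SF"
SU = "SU"
NS = "NS"

SCREEN_COLUMNS = [
    "superallele",
    "n_present",
    "n_absent",
    "mos_present",
    "mos_absent",
    "mean_diff",
    "p",
    "klass",
    "p_bh",
]


def classify(mean_diff: float, p: float, alpha: float = 0.05) -> str:
    """SF iff mean_diff > 0 and p < alpha; SU iff mean_diff < 0 and p < alpha; else NS."""
    if not (np.isfinite(mean_diff) and np.isfinite(p)):
        raise ValueError("mean_diff and p must be finite")
    if p < alpha:
        if mean_diff > 0:
            return SF
        if mean_diff < 0:
            return SU
    return NS


def screen_superalleles(
    cohort: Cohort,
    min_support: int | None = None,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Screen every sufficiently supported superallele for an OS-mean contrast.

    Returns one row per candidate, sorted by mean difference descending,
    with columns ``superallele, n_present, n_absent, mos_present,
    mos_absent, mean_diff, p, klass, p_bh``.  ``p_bh`` is the
    Benjamini-Hochberg adjusted p-value; it never changes ``klass``.
    """
    if min_support is None:
        min_support = cohort.min_support
    os_months = cohort.os_months.to_numpy(dtype=float)
    rows = []
    support = cohort.support
    for sa in cohort.superalleles:
        n_present = int(support[sa])
        if n_present < min_support:
            continue
        mask = cohort.presence[sa].to_numpy() == 1
        x = os_months[mask]
        y = os_months[~mask]
        if x.size < 2 or y.size < 2:
            continue
        res = welch_t_test(x, y, equal_var=equal_var)
        mos_p, mos_a = float(x.mean()), float(y.mean())
        diff = mos_p - mos_a
        rows.append(
            {
                "superallele": sa,
                "n_present": n_present,
                "n_absent": int((~mask).sum()),
                "mos_present": mos_p,
                "mos_absent": mos_a,
                "mean_diff": diff,
                "p": res.p,
                "klass": classify(diff, res.p, alpha),
            }
        )
    if not rows:
        import warnings

        warnings.warn("no superallele meets the support threshold; empty screen", stacklevel=2)
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    df = pd.DataFrame(rows)
    df["p_bh"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df = df.sort_values("mean_diff", ascending=False, kind="mergesort").reset_index(drop=True)
    return df[SCREEN_COLUMNS]


def sf_su_sets(screen_df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Extract the SF and SU superallele lists from a screen table."""
    sf = list(screen_df.loc[screen_df["klass"] == SF, "superallele"])
    su = list(screen_df.loc[screen_df["klass"] == SU, "superallele"])
    return sf, su


def load_published_screen() -> pd.DataFrame:
    """The published 24-row TCGA-SKCM screening summary shipped with the package.

    Columns mirror the screen output (counts, group MOS, mean difference,
    p) with the published printed precision preserved as strings in
    ``mean_diff_printed`` / ``p_printed`` next to their numeric forms.
    """
    ref = resources.files("hlasurv").joinpath("data/skcm_screen_reference.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df["mean_diff_printed"] = df["mean_diff"]
    df["p_printed"] = df["p"]
    for col in ("mos_present", "mos_absent", "mean_diff", "p"):
        df[col] = pd.to_numeric(df[col])
    for col in ("n_present", "n_absent"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return df
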