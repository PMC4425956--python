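"""FRC-based reproducibility rules and sample-gain accounting.

An individual's tests are screened for reproducibility on their FRC values:

1. a single test is never reproducible;
2. with exactly two tests, both are reproducible iff the smaller FRC is
   within 10% of the larger (inclusive), else neither is;
3. with three or more tests, the median FRC over all of the individual's
   tests is taken once; tests within 25% of that median (inclusive) are
   reproducible provided at least three tests fall inside the window —
   otherwise *all* tests are declared not reproducible.

The sample-gain report quantifies how many additional acceptable tests and
individuals are retained when tests with a wash-in sigh (by default the
``washin-pre`` scenario) are admitted to the reproducibility pool alongside
sigh-free tests. Because rule 3 is all-or-nothing, added tests can rescue
previously discarded ones, so the gain can exceed the number of tests added.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["assess", "assess_table", "sample_gain", "gain_percentages"]

TWO_TEST_RATIO = 0.90  # smaller FRC within 10% of the larger
MEDIAN_WINDOW = 0.25  # within 25% of the median
MIN_IN_WINDOW = 3
_REL_EPS = 1e-9  # boundary ties pass despite float rounding


def assess(frc_values: Sequence[float]) -> list[bool]:
    """Apply the reproducibility rules to one individual's FRC values.

    Returns a flag per test, in input order. Flags depend only on the
    multiset of values, never on their order. Boundary ties pass (the 10% and
    25% windows are inclusive).
    """
    frc = np.asarray(list(frc_values), dtype=float)
    if frc.size and (frc <= 0).any():
        raise ValueError("FRC values must be positive")
    n = frc.size
    if n == 0:
        return []
    if n == 1:
        return [False]
    if n == 2:
        ok = frc.min() >= TWO_TEST_RATIO * frc.max() * (1 - _REL_EPS)
        return [bool(ok)] * 2
    med = float(np.median(frc))
    inside = (frc >= (1 - MEDIAN_WINDOW) * med * (1 - _REL_EPS)) & (
        frc <= (1 + MEDIAN_WINDOW) * med * (1 + _REL_EPS)
    )
    if int(inside.sum()) < MIN_IN_WINDOW:
        return [False] * n
    return [bool(x) for x in inside]


def assess_table(
    df: pd.DataFrame,
    frc_col: str = "frc_l",
    id_col: str = "individual_id",
) -> pd.Series:
    """Per-test reproducibility flags for a whole cohort table."""
    flags = pd.Series(False, index=df.index)
    for _, idx in df.groupby(id_col).groups.items():
        flags.loc[idx] = assess(df.loc[idx, frc_col].tolist())
    return flags


def gain_percentages(before: int, after: int) -> int:
    """Percent increase from ``before`` to ``after``, rounded to the nearest
    integer (half away from zero); 0 when ``before`` is 0."""
    if before == 0:
        return 0
    return int(np.floor((after - before) / before * 100 + 0.5))


def sample_gain(
    outcomes: pd.DataFrame,
    include: Iterable[str] = ("washin-pre",),
    *,
    frc_col: str = "frc_l",
    id_col: str = "individual_id",
    scenario_col: str = "scenario",
) -> dict:
    """Count acceptable tests/individuals before and after admitting sighs.

    Runs the reproducibility rules twice — once on sigh-free (``none``) tests
    only, once on ``none`` plus the ``include`` scenarios pooled identically —
    and reports test and individual counts with rounded percent increases.
    Tests flagged unacceptable (an ``acceptable`` column, if present) are
    ignored throughout.
    """
    df = outcomes
    if "acceptable" in df.columns:
        df = df[df["acceptable"].fillna(True)]
    if df.empty:
        return {
            "tests_before": 0,
            "tests_after": 0,
            "individuals_before": 0,
            "individuals_after": 0,
            "extra_tests": 0,
            "pct_tests": 0,
            "pct_individuals": 0,
        }

    def _counts(scenarios: set[str]) -> tuple[int, int]:
        pool = df[df[scenario_col].isin(scenarios)]
        if pool.empty:
            return 0, 0
        flags = assess_table(pool, frc_col=frc_col, id_col=id_col)
        kept = pool[flags.to_numpy()]
        return len(kept), kept[id_col].nunique()

    t_before, i_before = _counts({"none"})
    t_after, i_after = _counts({"none"} | set(include))
    return {
        "tests_before": t_before,
        "tests_after": t_after,
        "individuals_before": i_before,
        "individuals_after": i_after,
        "extra_tests": t_after - t_before,
        "pct_tests": gain_percentages(t_before, t_after),
        "pct_individuals": gain_percentages(i_before, i_after),
    }
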