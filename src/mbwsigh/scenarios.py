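"""Sigh detection, scenario classification, and test acceptability.

A sigh is a breath whose expired volume is at least double the tidal volume of
the surrounding breathing (operationally: at least ``factor`` times the median
expired volume of the preceding ``window`` breaths). Each test is assigned one
of five scenarios by the presence and position of the sigh:

* ``none`` — no sigh;
* ``washin-pre`` — sigh during wash-in, before the last 5 wash-in breaths;
* ``washin-post`` — sigh within the last 5 wash-in breaths;
* ``washout-pre`` — sigh during washout, up to and including 10 breaths after
  the end-tidal tracer first reaches 1/40th of its starting value;
* ``washout-post`` — sigh during washout, after the washout-pre window.

Acceptability requires at most one sigh and an otherwise stable breathing
pattern (coefficient of variation of non-sigh tidal volumes below a
threshold). Other artifact types (sucking, snoring, mask leak, breath holds)
are not modelled.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .washout import BreathRecord, PHASE_WASHIN

__all__ = [
    "SCENARIOS",
    "detect_sighs",
    "classify_scenario",
    "acceptability",
]

SCENARIOS = ("none", "washin-pre", "washin-post", "washout-pre", "washout-post")

#: Wash-in breaths counted as "the last breaths" for the washin-pre/-post split.
WASHIN_TAIL_BREATHS = 5
#: Washout breaths after the 1/40th threshold still counted as washout-pre.
WASHOUT_PRE_EXTENSION = 10


def detect_sighs(
    breaths: Sequence[BreathRecord],
    window: int = 10,
    factor: float = 2.0,
) -> list[int]:
    """Return 1-based indices of breaths flagged as sighs.

    Breath *n* is flagged when its expired volume is at least ``factor`` times
    the median expired volume of the previous ``window`` breaths (the trailing
    median is robust both to drift and to an earlier sigh inside the window).
    The first ``window`` breaths are never flagged, as no reference is
    available; short series yield an empty result. The factor threshold is
    inclusive: exactly double counts as a sigh.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    v = np.array([b.v_exp for b in breaths])
    flagged = []
    for n in range(window, v.size):
        ref = float(np.median(v[n - window : n]))
        if ref > 0 and v[n] >= factor * ref:
            flagged.append(breaths[n].index)
    return flagged


def classify_scenario(
    sigh_indices: Sequence[int],
    washin_end: int,
    washout_threshold: int,
    washout_end_available: int,
) -> str:
    """Assign the five-way scenario label for one test.

    ``sigh_indices`` are 1-based on the combined breath axis; ``washin_end``
    is the last wash-in breath; ``washout_threshold`` is the washout-breath
    number where the end-tidal tracer first reached 1/40th of its starting
    value; ``washout_end_available`` is the total number of washout breaths
    recorded. When several sighs are present the first determines the label
    (such a test fails acceptability regardless).
    """
    if washin_end < 6:
        raise ValueError("washin_end must be >= 6 for the wash-in split to be defined")
    if not sigh_indices:
        return "none"
    j = min(sigh_indices)
    if j < 1:
        raise ValueError("breath indices are 1-based")
    if j <= washin_end:
        return "washin-pre" if j <= washin_end - WASHIN_TAIL_BREATHS else "washin-post"
    m = j - washin_end  # washout-breath number
    if m > washout_end_available:
        raise ValueError(
            f"sigh at combined breath {j} lies beyond the recorded washout "
            f"({washout_end_available} breaths)"
        )
    if m <= washout_threshold + WASHOUT_PRE_EXTENSION:
        return "washout-pre"
    return "washout-post"


def acceptability(
    breaths: Sequence[BreathRecord],
    sigh_indices: Sequence[int],
    cv_threshold: float = 0.25,
) -> bool:
    """Technical acceptability: up to one sigh, stable breathing otherwise.

    Stability is proxied by the coefficient of variation of expired volumes
    over non-sigh breaths, which must not exceed ``cv_threshold``.
    """
    if len(sigh_indices) > 1:
        return False
    sighs = set(sigh_indices)
    v = np.array([b.v_exp for b in breaths if b.index not in sighs])
    if v.size < 2:
        return True
    mean = float(np.mean(v))
    if mean <= 0:
        return False
    cv = float(np.std(v, ddof=1)) / mean
    return cv <= cv_threshold


def washin_end_index(breaths: Sequence[BreathRecord]) -> int:
    """1-based combined index of the last wash-in breath (0 if none)."""
    washin = [b.index for b in breaths if b.phase == PHASE_WASHIN]
    return max(washin) if washin else 0
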