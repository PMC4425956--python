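"""Breath segmentation and MBW outcome computation.

This module turns a raw flow + tracer-fraction trace into per-breath records
and then into the five standard multiple-breath washout outcomes:

* FRC — functional residual capacity, from net expired tracer divided by the
  end-tidal concentration drop over the washout;
* CEV — cumulative expired volume over the washout, up to the breath where
  the end-tidal tracer fraction first falls to 1/40th of its starting value;
* LCI — lung clearance index, CEV / FRC;
* MR1, MR2 — concentration-weighted moment ratios M1/M0 and M2/M0 of the
  washout curve over turnover number (cumulative expired volume / FRC).

Conventions fixed here (device software internals vary): end-tidal fraction is
the mean of the last 5% of each expiration; moments are summed over washout
breaths through the threshold breath; an optional apparatus dead-space volume
is subtracted from each breath's expired tracer volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import simpson

from .synthetic import MBWTrace

__all__ = [
    "BreathRecord",
    "TestOutcome",
    "EquilibrationNotReached",
    "WashoutIncomplete",
    "segment_breaths",
    "detect_washin_end",
    "detect_washout_end",
    "compute_outcomes",
]

PHASE_WASHIN = "wash-in"
PHASE_WASHOUT = "washout"

#: Fraction of the expiration whose mean tracer defines the end-tidal value.
END_TIDAL_FRACTION = 0.05


class EquilibrationNotReached(RuntimeError):
    """Wash-in never satisfied the equilibration criterion."""


class WashoutIncomplete(RuntimeError):
    """Washout never reached the 1/40th end-tidal threshold."""


@dataclass(frozen=True)
class BreathRecord:
    """Per-breath summary derived from the sampled signal.

    ``index`` is 1-based on the combined (wash-in + washout) breath axis.
    Volumes are litres; ``c_et`` is the end-tidal tracer fraction and
    ``c_insp`` the mean inspired tracer fraction (used for phase labelling).
    """

    index: int
    t_start: float
    t_end: float
    v_insp: float
    v_exp: float
    c_et: float
    phase: str
    c_insp: float = 0.0


@dataclass
class TestOutcome:
    """The five MBW outcomes for one test, plus bookkeeping flags."""

    frc: float
    cev: float
    lci: float
    mr1: float
    mr2: float
    n_washout_breaths: int
    scenario: str | None = None
    acceptable: bool | None = None
    reproducible: bool | None = None


def _halfcycle_volume(flow: np.ndarray, dt: float, t0_gap: float, t1_gap: float) -> float:
    """Integrate |flow| over one half-cycle of samples.

    Samples are midpoint-style (no exact zeros); ``t0_gap`` / ``t1_gap`` are
    the time offsets from the interpolated zero crossings to the first/last
    sample, contributing triangular end corrections. Negative gap disables the
    correction (trace boundary).
    """
    f = np.abs(flow)
    if f.size == 1:
        v = f[0] * dt
    else:
        v = float(simpson(f, dx=dt))
    if t0_gap > 0:
        v += 0.5 * t0_gap * f[0]
    if t1_gap > 0:
        v += 0.5 * t1_gap * f[-1]
    return v


def segment_breaths(
    trace: MBWTrace,
    min_volume: float = 0.002,
    *,
    phase_threshold: float | None = None,
) -> list[BreathRecord]:
    """Segment a trace into breaths at inspiration-onset flow zero crossings.

    Half-cycles with volume below ``min_volume`` (litres) are merged into
    their predecessor — an anti-chatter guard against noise-induced sign
    flips. Each breath is an inspiratory (negative-flow) half-cycle followed
    by an expiratory (positive-flow) one; a leading expiratory half-cycle is
    treated as pre-test and dropped.

    Breaths are labelled ``wash-in`` when their mean inspired tracer fraction
    exceeds ``phase_threshold`` (default: half the maximum inspired fraction
    seen in the trace), else ``washout``.

    An empty or constant-flow trace yields zero breaths. Non-uniform sampling
    raises ``ValueError``.
    """
    t, flow, tracer = trace.time, trace.flow, trace.tracer
    if t.size == 0:
        return []
    dts = np.diff(t)
    if dts.size and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace is not uniformly sampled")
    dt = float(dts[0]) if dts.size else 1.0 / trace.fs

    sign = np.sign(flow)
    # carry the previous sign through exact zeros
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    nonzero = np.flatnonzero(sign != 0)
    if nonzero.size == 0:
        return []
    sign[: nonzero[0]] = sign[nonzero[0]]

    # segments as (start, stop) half-open sample ranges of constant sign
    change = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [sign.size]])
    segs = [[int(a), int(b), int(sign[a])] for a, b in zip(starts, stops)]

    def seg_volume(a: int, b: int, first: bool, last: bool) -> float:
        # zero-crossing gap on each side: interpolated against the adjacent
        # opposite-sign sample, or extrapolated at the trace boundary
        if not (first or a == 0):
            f_prev, f_a = flow[a - 1], flow[a]
            g0 = dt * abs(f_a) / (abs(f_a) + abs(f_prev)) if f_a != f_prev else 0.0
        elif b - a >= 2 and abs(flow[a + 1]) > abs(flow[a]):
            g0 = min(dt, dt * abs(flow[a]) / (abs(flow[a + 1]) - abs(flow[a])))
        else:
            g0 = -1.0
        if not (last or b == sign.size):
            f_b1, f_b = flow[b], flow[b - 1]
            g1 = dt * abs(f_b) / (abs(f_b) + abs(f_b1)) if f_b != f_b1 else 0.0
        elif b - a >= 2 and abs(flow[b - 2]) > abs(flow[b - 1]):
            g1 = min(dt, dt * abs(flow[b - 1]) / (abs(flow[b - 2]) - abs(flow[b - 1])))
        else:
            g1 = -1.0
        return _halfcycle_volume(flow[a:b], dt, g0, g1)

    # merge low-volume half-cycles into their predecessor (anti-chatter)
    merged: list[list[int]] = []
    for seg in segs:
        a, b, s = seg
        vol = seg_volume(a, b, a == 0, b == sign.size)
        if merged and (vol < min_volume or merged[-1][2] == s):
            merged[-1][1] = b
        else:
            merged.append([a, b, s])
    # a leading runt segment merges forward
    if len(merged) >= 2:
        a, b, s = merged[0]
        if seg_volume(a, b, True, False) < min_volume:
            merged[1][0] = a
            merged.pop(0)

    records: list[BreathRecord] = []
    i = 0
    idx = 1
    while i + 1 < len(merged):
        a0, b0, s0 = merged[i]
        a1, b1, s1 = merged[i + 1]
        if s0 < 0 and s1 > 0:  # inspiration then expiration
            v_insp = seg_volume(a0, b0, i == 0, False)
            v_exp = seg_volume(a1, b1, False, i + 2 >= len(merged))
            exp_tracer = tracer[a1:b1]
            n_tail = max(1, int(round(END_TIDAL_FRACTION * exp_tracer.size)))
            c_et = float(np.mean(exp_tracer[-n_tail:]))
            c_insp = float(np.mean(tracer[a0:b0]))
            records.append(
                BreathRecord(
                    index=idx,
                    t_start=float(t[a0]),
                    t_end=float(t[b1 - 1]) + dt,
                    v_insp=v_insp,
                    v_exp=v_exp,
                    c_et=c_et,
                    phase=PHASE_WASHOUT,  # provisional; relabelled below
                    c_insp=c_insp,
                )
            )
            idx += 1
            i += 2
        else:
            i += 1

    if not records:
        return records

    if phase_threshold is None:
        cmax = max(r.c_insp for r in records)
        phase_threshold = 0.5 * cmax if cmax > 1e-6 else np.inf
    relabelled = [
        BreathRecord(
            index=r.index,
            t_start=r.t_start,
            t_end=r.t_end,
            v_insp=r.v_insp,
            v_exp=r.v_exp,
            c_et=r.c_et,
            phase=PHASE_WASHIN if r.c_insp > phase_threshold else PHASE_WASHOUT,
            c_insp=r.c_insp,
        )
        for r in records
    ]
    return relabelled


def detect_washin_end(
    breaths: Sequence[BreathRecord],
    c_insp: float,
    rel_tol: float = 0.02,
    run_length: int = 5,
) -> int:
    """Return the 1-based index of the breath completing equilibration.

    Equilibration is a run of ``run_length`` consecutive wash-in breaths whose
    end-tidal fractions are within ``rel_tol`` (relative) of the inspired
    fraction; the returned breath ends the first such run.
    """
    washin = [b for b in breaths if b.phase == PHASE_WASHIN]
    run = 0
    for b in washin:
        if abs(b.c_et - c_insp) / c_insp <= rel_tol:
            run += 1
            if run >= run_length:
                return b.index
        else:
            run = 0
    raise EquilibrationNotReached(
        f"no run of {run_length} wash-in breaths within {rel_tol:.3g} "
        f"(relative) of inspired fraction {c_insp}"
    )


def detect_washout_end(breaths: Sequence[BreathRecord], c_start: float) -> int:
    """Return the 1-based washout-breath number of the threshold breath.

    The threshold breath is the first washout breath whose end-tidal tracer
    fraction falls to 1/40th of ``c_start`` (the end-tidal fraction at the end
    of wash-in) or below.
    """
    if c_start <= 0:
        raise ValueError("c_start must be positive")
    washout = [b for b in breaths if b.phase == PHASE_WASHOUT]
    threshold = c_start / 40.0
    for m, b in enumerate(washout, start=1):
        if b.c_et <= threshold:
            return m
    raise WashoutIncomplete(
        f"end-tidal fraction never reached c_start/40 = {threshold:.4g} "
        f"over {len(washout)} washout breaths"
    )


def compute_outcomes(
    breaths: Sequence[BreathRecord],
    washout_end: int,
    *,
    dead_space: float = 0.0,
    c0: float | None = None,
) -> TestOutcome:
    """Compute FRC, CEV, LCI, MR1, MR2 from segmented breaths.

    ``washout_end`` is the threshold breath number within the washout
    (1-based). ``c0`` defaults to the end-tidal fraction of the last wash-in
    breath. ``dead_space`` litres of apparatus dead space are subtracted from
    each breath's expired tracer volume.

    Definitions: CEV is the sum of expired volumes over washout breaths 1..
    ``washout_end``; FRC is net expired tracer divided by (C0 − C_end); LCI =
    CEV / FRC; the j-th moment is ``M_j = sum_n (c_n/C0) * TO_n**j`` with
    turnover ``TO_n`` the cumulative expired volume through breath n divided
    by FRC; MR1 = M1/M0 and MR2 = M2/M0.
    """
    washout = [b for b in breaths if b.phase == PHASE_WASHOUT]
    if washout_end < 2:
        raise ValueError("need at least 2 washout breaths to compute outcomes")
    if washout_end > len(washout):
        raise ValueError(
            f"washout_end={washout_end} exceeds the {len(washout)} available "
            "washout breaths"
        )
    if c0 is None:
        washin = [b for b in breaths if b.phase == PHASE_WASHIN]
        if not washin:
            raise ValueError("no wash-in breaths and no explicit c0 given")
        c0 = washin[-1].c_et

    used = washout[:washout_end]
    v_exp = np.array([b.v_exp for b in used])
    c_et = np.array([b.c_et for b in used])

    c_end = c_et[-1]
    if c0 <= c_end:
        raise ZeroDivisionError(
            f"end-tidal drop is non-positive (C0={c0:.4g} <= C_end={c_end:.4g})"
        )

    cev = float(np.sum(v_exp))
    net_tracer = float(np.sum((v_exp - dead_space) * c_et))
    frc = net_tracer / (c0 - c_end)
    if frc <= 0:
        raise ValueError("computed FRC is non-positive")
    lci = cev / frc

    turnover = np.cumsum(v_exp) / frc
    weights = c_et / c0
    m0 = float(np.sum(weights))
    m1 = float(np.sum(weights * turnover))
    m2 = float(np.sum(weights * turnover**2))

    return TestOutcome(
        frc=frc,
        cev=cev,
        lci=lci,
        mr1=m1 / m0,
        mr2=m2 / m0,
        n_washout_breaths=washout_end,
    )
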