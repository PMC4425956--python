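"""Synthetic MBW data generation.

Two levels of simulation are provided, matching the two entry points of the
analysis pipeline:

* :func:`simulate_trace` produces a raw multiple-breath washout (MBW) signal —
  a uniformly sampled flow and tracer-fraction series for one test — from a
  small compartmental lung model.  SF6 is washed in to a target inspired
  fraction (4% by default) and then washed out until the end-tidal fraction
  falls below 1/40th of its starting value.  A single sigh (a breath with at
  least double the tidal volume) can be injected at a chosen position.

* :func:`simulate_outcomes` produces test-level outcome tables directly from
  the replicate mixed model used downstream: per-scenario mean shifts on top
  of a grand mean, an individual random effect, an individual-by-scenario
  interaction, and per-scenario residual noise.

Both are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LungSpec",
    "SighSpec",
    "StudyDesign",
    "MBWTrace",
    "EquilibrationError",
    "simulate_trace",
    "make_design",
    "simulate_outcomes",
    "simulate_outcome_table",
]

#: Scenario label for tests without a sigh.
SCENARIO_NONE = "none"


class EquilibrationError(RuntimeError):
    """Raised when the wash-in phase fails to reach the inspired tracer level."""


@dataclass(frozen=True)
class LungSpec:
    """Physical description of the simulated lung and measurement.

    Parameters
    ----------
    frc : float
        Functional residual capacity in litres. For a newborn this is on the
        order of 0.08–0.12 L.
    vt : float
        Tidal volume in litres (infant scale: ~0.03–0.06 L).
    dead_space : float
        Series (apparatus + mask) dead space in litres, re-breathed each
        inspiration and flushed first on expiration. An infant face mask
        contributes roughly 0.012 L.
    resp_rate : float
        Respiratory rate in breaths per minute.
    c_insp_washin : float
        Inspired tracer fraction during wash-in (dimensionless; 0.04 = 4% SF6).
    n_compartments : int
        1 for a homogeneous lung, 2 for two parallel compartments with
        independent dilution ratios (used to generate ventilation
        inhomogeneity, i.e. LCI above the homogeneous ideal).
    compartment_split : float
        Fraction of FRC held by compartment 1 (only used when
        ``n_compartments == 2``).
    vt_split : float or None
        Fraction of alveolar tidal volume ventilating compartment 1. Default
        ``None`` mirrors the volume split (``1 - compartment_split``) so that
        any asymmetric split yields unequal specific ventilation and hence a
        washout slower than the homogeneous ideal.
    noise_sd : float
        SD of additive Gaussian noise on the tracer-fraction signal.
    """

    frc: float
    vt: float
    dead_space: float = 0.0
    resp_rate: float = 40.0
    c_insp_washin: float = 0.04
    n_compartments: int = 1
    compartment_split: float = 0.5
    vt_split: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.frc > 0:
            raise ValueError("frc must be positive")
        if not self.vt > 0:
            raise ValueError("vt must be positive")
        if not 0 <= self.dead_space < self.vt:
            raise ValueError("dead_space must satisfy 0 <= dead_space < vt")
        if not 0 < self.c_insp_washin < 1:
            raise ValueError("c_insp_washin must be a fraction in (0, 1)")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.n_compartments == 2 and not 0 < self.compartment_split < 1:
            raise ValueError("compartment_split must be in (0, 1)")
        if self.vt_split is not None and not 0 < self.vt_split < 1:
            raise ValueError("vt_split must be in (0, 1)")
        if self.resp_rate <= 0:
            raise ValueError("resp_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SighSpec:
    """A single sigh: one breath with amplified tidal volume.

    ``phase`` is ``"wash-in"`` or ``"washout"``; ``breath_index`` is the
    1-based position of the sigh within that phase. The amplitude factor must
    be at least 2, matching the operational definition of a sigh as a breath
    with at least double the tidal volume.
    """

    phase: str
    breath_index: int
    amplitude_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.phase not in ("wash-in", "washout"):
            raise ValueError("phase must be 'wash-in' or 'washout'")
        if self.breath_index < 1:
            raise ValueError("breath_index is 1-based and must be >= 1")
        if self.amplitude_factor < 2:
            raise ValueError("a sigh has at least double tidal volume (factor >= 2)")


@dataclass(frozen=True)
class MBWTrace:
    """One simulated MBW test: uniformly sampled flow + tracer signal.

    Expiration is positive flow. ``meta`` carries the ground truth used to
    generate the trace (lung spec, sigh, phase boundaries, seed).
    """

    time: np.ndarray
    flow: np.ndarray
    tracer: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "flow_lps": self.flow, "tracer_frac": self.tracer}
        )

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the trace CSV and (optionally) a ground-truth JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {k: _jsonable(v) for k, v in self.meta.items()}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _jsonable(v):
    if isinstance(v, (LungSpec, SighSpec)):
        return asdict(v)
    if isinstance(v, np.generic):
        return v.item()
    return v


def simulate_trace(
    spec: LungSpec,
    sigh: SighSpec | None = None,
    washin_breaths: int = 30,
    seed: int = 0,
    *,
    fs: float = 200.0,
    equil_rel_tol: float = 0.02,
    washout_margin_breaths: int = 12,
    max_washout_breaths: int = 500,
) -> MBWTrace:
    """Simulate one MBW test as a sampled flow + tracer-fraction signal.

    The flow waveform is a sinusoid per breath (inspiration negative,
    expiration positive) whose half-cycle integral equals the breath's tidal
    volume. Tracer dynamics follow a discrete breath-by-breath compartment
    model: during wash-in the inspired gas carries ``c_insp_washin`` tracer;
    during washout it carries none. Washout continues until the end-tidal
    fraction drops below 1/40th of its starting value, plus
    ``washout_margin_breaths`` further breaths (and at least up to a washout
    sigh position, if one is requested).

    For a single compartment with zero dead space and no noise the end-tidal
    washout fractions follow the geometric law ``C_n = C_0 * r**n`` with
    ``r = frc / (frc + vt)``.

    Raises
    ------
    EquilibrationError
        If the wash-in does not approach ``c_insp_washin`` within
        ``equil_rel_tol`` (relative) by the end of the wash-in phase, or if
        the washout never reaches the 1/40th threshold.
    ValueError
        If the sigh position lies outside the generated phase.
    """
    rng = np.random.default_rng(seed)
    period = 60.0 / spec.resp_rate
    n_per_breath = int(round(period * fs))
    dt = period / n_per_breath  # exact grid per breath

    if sigh is not None and sigh.phase == "wash-in" and sigh.breath_index > washin_breaths:
        raise ValueError(
            f"sigh at wash-in breath {sigh.breath_index} lies outside the "
            f"{washin_breaths}-breath wash-in phase"
        )

    # Compartment bookkeeping: FRC and ventilation may be split differently
    # (unequal specific ventilation -> inhomogeneous washout). Re-breathed
    # dead-space gas carries the previous breath's mixed end-tidal fraction.
    if spec.n_compartments == 1:
        frc_shares = np.array([1.0])
        vt_shares = np.array([1.0])
    else:
        frc_shares = np.array([spec.compartment_split, 1.0 - spec.compartment_split])
        v1 = spec.vt_split if spec.vt_split is not None else 1.0 - spec.compartment_split
        vt_shares = np.array([v1, 1.0 - v1])
    frc_j = spec.frc * frc_shares
    conc = np.zeros_like(frc_shares)  # tracer-free lung before wash-in
    c_et_prev = 0.0

    flow_chunks: list[np.ndarray] = []
    tracer_chunks: list[np.ndarray] = []

    t_local = (np.arange(n_per_breath) + 0.5) / n_per_breath  # cycle phase in (0,1)
    base_wave = -np.sin(2 * np.pi * t_local)  # inspiration first (negative)

    def run_breath(c_in: float, vt_b: float) -> float:
        """Advance the lung one breath; append signal; return end-tidal fraction."""
        nonlocal conc, c_et_prev
        vt_alv = vt_b - spec.dead_space
        new = (
            frc_j * conc
            + vt_shares * spec.dead_space * c_et_prev
            + vt_shares * vt_alv * c_in
        ) / (frc_j + vt_shares * vt_b)
        conc = new
        c_et = float(np.dot(vt_shares, conc))

        amp = np.pi * vt_b / period
        flow = amp * base_wave
        tracer = np.empty(n_per_breath)
        half = n_per_breath // 2
        tracer[:half] = c_in  # inspired gas at the mouth
        # Expired gas: dead-space (fresh) gas first, then alveolar gas.
        exp_flow = flow[half:]
        v_exp_cum = np.cumsum(exp_flow) * dt
        tracer[half:] = np.where(v_exp_cum < spec.dead_space, c_in, c_et)
        flow_chunks.append(flow)
        tracer_chunks.append(tracer)
        c_et_prev = c_et
        return c_et

    def vt_of(phase: str, idx: int) -> float:
        if sigh is not None and sigh.phase == phase and sigh.breath_index == idx:
            return spec.vt * sigh.amplitude_factor
        return spec.vt

    # Wash-in
    c_et = 0.0
    for b in range(1, washin_breaths + 1):
        c_et = run_breath(spec.c_insp_washin, vt_of("wash-in", b))
    if abs(c_et - spec.c_insp_washin) / spec.c_insp_washin > equil_rel_tol:
        raise EquilibrationError(
            f"wash-in end-tidal fraction {c_et:.4g} not within relative "
            f"tolerance {equil_rel_tol} of inspired fraction {spec.c_insp_washin}"
        )

    c_start = c_et
    threshold = c_start / 40.0

    # Washout: continue until the 1/40th threshold plus a safety margin, and
    # at least far enough to include a requested washout sigh.
    threshold_breath = None
    b = 0
    while True:
        b += 1
        if b > max_washout_breaths:
            raise EquilibrationError(
                f"washout did not reach the 1/40th threshold ({threshold:.4g}) "
                f"within {max_washout_breaths} breaths"
            )
        c_et = run_breath(0.0, vt_of("washout", b))
        if threshold_breath is None and c_et <= threshold:
            threshold_breath = b
        if threshold_breath is not None and b >= threshold_breath + washout_margin_breaths:
            if sigh is None or sigh.phase != "washout" or b >= sigh.breath_index:
                break
    n_washout = b
    if sigh is not None and sigh.phase == "washout" and sigh.breath_index > n_washout:
        raise ValueError(
            f"sigh at washout breath {sigh.breath_index} lies outside the "
            f"{n_washout}-breath washout phase"
        )

    flow = np.concatenate(flow_chunks)
    tracer = np.concatenate(tracer_chunks)
    if spec.noise_sd > 0:
        tracer = tracer + rng.normal(0.0, spec.noise_sd, size=tracer.shape)
    time = np.arange(flow.size) * dt

    meta = {
        "spec": spec,
        "sigh": sigh,
        "seed": seed,
        "fs": fs,
        "washin_breaths": washin_breaths,
        "n_washout_breaths": n_washout,
        "c_start": c_start,
        "threshold_breath": threshold_breath,
    }
    return MBWTrace(time=time, flow=flow, tracer=tracer, fs=1.0 / dt, meta=meta)


# ---------------------------------------------------------------------------
# Outcome-level simulation


@dataclass(frozen=True)
class StudyDesign:
    """Allocation of tests to individuals and scenarios.

    ``assignments`` has one row per test with columns ``individual_id``,
    ``test_id`` and ``scenario``. Use :func:`make_design` for the default
    near-even allocation, or construct the frame directly for bespoke designs.
    """

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual_id", "test_id", "scenario"}
        missing = required - set(self.assignments.columns)
        if missing:
            raise ValueError(f"assignments missing columns: {sorted(missing)}")
        counts = self.assignments.groupby("individual_id").size()
        if (counts < 1).any():
            raise ValueError("every individual must have at least one test")

    @property
    def n_individuals(self) -> int:
        return self.assignments["individual_id"].nunique()

    @property
    def n_tests(self) -> int:
        return len(self.assignments)

    @property
    def scenario_counts(self) -> dict[str, int]:
        return self.assignments["scenario"].value_counts().to_dict()


def make_design(
    scenario_counts: Mapping[str, int],
    n_individuals: int,
    seed: int = 0,
) -> StudyDesign:
    """Allocate tests to individuals near-evenly and scenarios at random.

    Total tests are split as evenly as possible across individuals (the
    remainder individuals, chosen by the seeded RNG, get one extra test);
    scenario labels are then shuffled over tests so that the per-scenario
    totals match ``scenario_counts`` exactly.
    """
    total = int(sum(scenario_counts.values()))
    if any(v < 0 for v in scenario_counts.values()):
        raise ValueError("scenario counts must be non-negative")
    if total < n_individuals:
        raise ValueError(
            f"cannot allocate {total} tests to {n_individuals} individuals "
            "with at least one test each"
        )
    rng = np.random.default_rng(seed)
    base, rem = divmod(total, n_individuals)
    per_indiv = np.full(n_individuals, base, dtype=int)
    extra = rng.choice(n_individuals, size=rem, replace=False)
    per_indiv[extra] += 1

    labels = np.concatenate(
        [np.repeat(s, c) for s, c in sorted(scenario_counts.items())]
    )
    rng.shuffle(labels)

    individual = np.repeat(np.arange(n_individuals), per_indiv)
    df = pd.DataFrame(
        {
            "individual_id": [f"I{i:04d}" for i in individual],
            "test_id": [f"T{k:05d}" for k in range(total)],
            "scenario": labels,
        }
    )
    return StudyDesign(assignments=df)


def simulate_outcomes(
    params,
    design: StudyDesign,
    seed: int = 0,
    *,
    outcome_col: str = "lci",
) -> pd.DataFrame:
    """Simulate one outcome variable for every test of a design.

    The generative model for individual *i*, scenario *s*, replicate *k* is

        y = mu + alpha_s + b_i + c_{i,s} + eps,

    with ``b_i ~ N(0, omega^2)`` drawn once per individual, ``c_{i,s} ~
    N(0, tau^2)`` once per (individual, scenario) pair, and residual
    ``eps ~ N(0, sigma_s^2)`` per test; ``alpha_none = 0``. The same seed
    yields an identical table.

    ``params`` is a :class:`mbwsigh.model.ModelParams` (or anything with
    ``mu``, ``alpha``, ``omega``, ``tau``, ``sigma`` attributes).
    """
    df = design.assignments.copy()
    scen = df["scenario"].to_numpy()
    missing = set(scen) - set(params.sigma)
    if missing:
        raise KeyError(
            f"design scenarios absent from model parameters: {sorted(missing)}"
        )
    rng = np.random.default_rng(seed)

    indiv_codes, _ = pd.factorize(df["individual_id"], sort=True)
    pair_codes, _ = pd.factorize(
        df["individual_id"].astype(str) + "\x00" + df["scenario"].astype(str),
        sort=True,
    )
    b = rng.normal(0.0, params.omega, size=indiv_codes.max() + 1)
    c = rng.normal(0.0, params.tau, size=pair_codes.max() + 1)
    sigma = np.array([params.sigma[s] for s in scen])
    alpha = np.array([params.alpha.get(s, 0.0) for s in scen])
    eps = rng.normal(0.0, 1.0, size=len(df)) * sigma

    df[outcome_col] = params.mu + alpha + b[indiv_codes] + c[pair_codes] + eps
    return df


def simulate_outcome_table(
    params_by_outcome: Mapping[str, object],
    design: StudyDesign,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate several outcome variables on a shared design.

    Each outcome uses its own parameter set and an independent seed stream
    (random effects are independent across outcomes — a simplification; real
    MBW outcomes are correlated since they derive from the same washout).
    Keys of ``params_by_outcome`` become column names.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(params_by_outcome))
    out = design.assignments.copy()
    for (name, params), child in zip(params_by_outcome.items(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        col = simulate_outcomes(params, design, sub_seed, outcome_col=name)[name]
        out[name] = col
    return out
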