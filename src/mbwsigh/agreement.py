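"""95% limits of agreement between hypothetical replicate measurements.

Two comparisons are supported, both between hypothetical measurements on the
*same* individual (so the individual effect ``b_i`` cancels):

* ``single`` — one test from scenario *s* versus one sigh-free test:
  ``D = alpha_s + (c_{i,s} - c_{i,none}) + (eps_s - eps_none)``, so
  ``Var(D) = 2 tau^2 + sigma_s^2 + sigma_none^2``. For scenario ``none`` the
  two tests share the interaction term, leaving ``2 sigma_none^2`` — the
  classical Bland–Altman width for equal-variance repeats.

* ``mean3`` — the mean of three replicates of which one comes from scenario
  *s* versus the mean of three sigh-free replicates:
  ``center = alpha_s / 3`` and
  ``Var(D) = (2 tau^2 + 5 sigma_none^2 + sigma_s^2) / 9``
  (the ``none`` interaction is shared by all sigh-free replicates and cancels
  except against ``c_{i,s}``). For scenario ``none``: ``2 sigma_none^2 / 3``.

Limits are ``center ± 1.96 sqrt(Var(D))``, with 1.96 used exactly. Parameter
estimates are treated as fixed; no estimation uncertainty is propagated into
the limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .model import ModelParams

__all__ = ["LoAResult", "loa_single", "loa_mean3", "loa_table"]

_Z = 1.96


@dataclass(frozen=True)
class LoAResult:
    """Limits of agreement for one comparison and scenario."""

    comparison: str  # "single" | "mean3"
    scenario: str
    center: float
    lower: float
    upper: float

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0


def _check(params: ModelParams, scenario: str) -> None:
    if scenario not in params.sigma:
        raise KeyError(f"scenario {scenario!r} has no residual SD in params")


def loa_single(params: ModelParams, scenario: str) -> LoAResult:
    """Limits of agreement comparing single replicates."""
    _check(params, scenario)
    s_none = params.sigma["none"]
    if scenario == "none":
        center = 0.0
        var = 2.0 * s_none**2
    else:
        center = params.alpha.get(scenario, 0.0)
        var = 2.0 * params.tau**2 + params.sigma[scenario] ** 2 + s_none**2
    hw = _Z * math.sqrt(var)
    return LoAResult("single", scenario, center, center - hw, center + hw)


def loa_mean3(params: ModelParams, scenario: str) -> LoAResult:
    """Limits of agreement comparing means of three replicates.

    The mixed mean replaces one of the three sigh-free replicates by a test
    from ``scenario``.
    """
    _check(params, scenario)
    s_none = params.sigma["none"]
    if scenario == "none":
        center = 0.0
        var = 2.0 * s_none**2 / 3.0
    else:
        center = params.alpha.get(scenario, 0.0) / 3.0
        var = (
            2.0 * params.tau**2 + 5.0 * s_none**2 + params.sigma[scenario] ** 2
        ) / 9.0
    hw = _Z * math.sqrt(var)
    return LoAResult("mean3", scenario, center, center - hw, center + hw)


def loa_table(
    params: ModelParams, scenarios: Iterable[str] | None = None
) -> pd.DataFrame:
    """LoA for every scenario and both comparisons, as a tidy table."""
    if scenarios is None:
        scenarios = params.scenarios()
    rows = []
    for s in scenarios:
        for res in (loa_single(params, s), loa_mean3(params, s)):
            rows.append(
                {
                    "comparison": res.comparison,
                    "scenario": res.scenario,
                    "center": res.center,
                    "lower": res.lower,
                    "upper": res.upper,
                }
            )
    return pd.DataFrame(rows)
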