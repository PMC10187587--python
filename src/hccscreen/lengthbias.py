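"""Length-time bias adjustment via a slow/fast tumor mixture.

Slow-growing tumors are both less fatal (relative risk of death ``theta``
vs aggressive tumors) and longer in their preclinical phase, hence
over-represented among screen-detected cancers. With slow-class prevalence
``w_s`` among screen-detected and ``w_c`` among symptomatic patients, the
expected ratio of observed death probabilities under *no* true screening
benefit is

    R0 = (1 - w_s (1 - theta)) / (1 - w_c (1 - theta))

so the length-bias-corrected relative risk of death for screen-detected vs
symptomatic tumors is ``phi = (delta1 / delta2) / R0`` where ``delta1`` and
``delta2`` are the observed death probabilities. ``w_s`` and ``w_c`` are not
identified from data; they are derived from an assumed overall slow
proportion ``1 - q`` and an enrichment mode:

* ``maximal`` — slow tumors preferentially fill the screen-detected stratum
  up to feasibility: ``w_s = min(1, (1-q)/p)`` (a conservative bound);
* ``proportional`` — the odds of the slow class among screen-detected equal
  ``enrichment_factor`` times the odds among symptomatic patients.

Both modes respect the accounting identity
``p * w_s + (1 - p) * w_c = 1 - q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LengthBiasScenario",
    "PhiEstimate",
    "slow_prevalences",
    "null_ratio",
    "estimate_phi",
    "adjust_survival_for_length_bias",
]


class EnrichmentError(ValueError):
    """Raised when a scenario's slow-class prevalences are infeasible."""


@dataclass(frozen=True)
class LengthBiasScenario:
    """One cell of the length-bias sensitivity analysis.

    ``slow_proportion`` is the assumed overall proportion of slow-growing
    tumors (1 - q); ``theta`` the relative risk of death for slow vs
    aggressive tumors. Base case: 20% slow, theta = 0.9.
    """

    slow_proportion: float = 0.2
    theta: float = 0.9
    enrichment_mode: str = "maximal"
    enrichment_factor: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.slow_proportion < 1.0:
            raise ValueError("slow_proportion must lie in [0, 1)")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")
        if self.enrichment_mode not in ("maximal", "proportional"):
            raise ValueError("enrichment_mode must be 'maximal' or 'proportional'")
        if self.enrichment_mode == "proportional":
            if self.enrichment_factor is None or not self.enrichment_factor > 0:
                raise ValueError(
                    "proportional enrichment requires enrichment_factor > 0"
                )


@dataclass(frozen=True)
class PhiEstimate:
    """Length-bias-corrected relative risk of death, screen vs symptomatic."""

    delta1: float
    delta2: float
    p_screen: float
    w_screen: float
    w_clinical: float
    null_ratio: float
    phi: float


def slow_prevalences(
    scenario: LengthBiasScenario, p_screen: float
) -> tuple[float, float]:
    """Slow-class prevalence among screen-detected (w_s) and symptomatic
    (w_c) patients implied by the scenario at observed screen proportion
    ``p_screen``."""
    if not 0.0 < p_screen < 1.0:
        raise ValueError("p_screen must lie in (0, 1)")
    sp = scenario.slow_proportion
    if sp == 0.0:
        return 0.0, 0.0
    if scenario.enrichment_mode == "maximal":
        w_s = min(1.0, sp / p_screen)
        w_c = (sp - p_screen * w_s) / (1.0 - p_screen)
    else:
        f = float(scenario.enrichment_factor)

        def w_s_of(w_c: float) -> float:
            # odds(w_s) = f * odds(w_c)
            return f * w_c / (1.0 - w_c + f * w_c)

        def balance(w_c: float) -> float:
            return p_screen * w_s_of(w_c) + (1.0 - p_screen) * w_c - sp

        hi = min(1.0 - 1e-12, sp / (1.0 - p_screen))
        if balance(0.0) > 0 or balance(hi) < 0:
            raise EnrichmentError(
                f"no feasible (w_s, w_c) for slow_proportion={sp}, "
                f"p_screen={p_screen}, enrichment_factor={f}"
            )
        w_c = brentq(balance, 0.0, hi, xtol=1e-12)
        w_s = w_s_of(w_c)
    for name, w in (("w_screen", w_s), ("w_clinical", w_c)):
        if not -1e-12 <= w <= 1.0 + 1e-12:
            raise EnrichmentError(f"{name}={w} outside [0, 1]")
    return float(np.clip(w_s, 0.0, 1.0)), float(np.clip(w_c, 0.0, 1.0))


def null_ratio(scenario: LengthBiasScenario, p_screen: float) -> float:
    """Expected delta1/delta2 under no true screening benefit (R0)."""
    w_s, w_c = slow_prevalences(scenario, p_screen)
    th = scenario.theta
    return (1.0 - w_s * (1.0 - th)) / (1.0 - w_c * (1.0 - th))


def estimate_phi(
    delta1: float,
    delta2: float,
    p_screen: float,
    scenario: LengthBiasScenario,
) -> PhiEstimate:
    """Length-bias-corrected relative risk phi = (delta1/delta2) / R0.

    ``delta1`` / ``delta2`` are observed death probabilities for
    screen-detected / symptomatic patients; ``p_screen`` the observed
    proportion screen-detected.
    """
    for name, v in (("delta1", delta1), ("delta2", delta2)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    w_s, w_c = slow_prevalences(scenario, p_screen)
    th = scenario.theta
    r0 = (1.0 - w_s * (1.0 - th)) / (1.0 - w_c * (1.0 - th))
    return PhiEstimate(
        delta1=float(delta1),
        delta2=float(delta2),
        p_screen=float(p_screen),
        w_screen=w_s,
        w_clinical=w_c,
        null_ratio=r0,
        phi=(delta1 / delta2) / r0,
    )


def adjust_survival_for_length_bias(
    km_table: pd.DataFrame,
    scenario: LengthBiasScenario,
    p_screen: float,
    time_col: str = "time",
    deaths_col: str = "events",
    at_risk_col: str = "at_risk",
) -> pd.DataFrame:
    """Length-bias-adjust a Kaplan-Meier curve for the screen-containing
    stratum.

    Each interval's conditional death probability ``q_i = d_i / n_i`` is
    divided by R0 (capped at 1) and the survival curve recomposed as the
    product of adjusted conditional survivals. ``km_table`` must carry event
    times, deaths and numbers at risk (as produced by
    :func:`hccscreen.survival.km_estimate`). Returns a copy with an
    ``adjusted_survival`` column.
    """
    r0 = null_ratio(scenario, p_screen)
    d = km_table[deaths_col].to_numpy(float)
    n = km_table[at_risk_col].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n > 0, d / n, 0.0)
    q_adj = np.minimum(1.0, q / r0)
    out = km_table.copy()
    out["adjusted_survival"] = np.cumprod(1.0 - q_adj)
    out["null_ratio"] = r0
    return out
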