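"""Fit gating, aggregation across models/timepoints/assays, classification.

Interaction calls follow the standard thresholds: a combination is
synergistic when the mean δ ≥ 5 percentage points, antagonistic when
δ ≤ −5, additive in between (±5 being the typical noise level of large-scale
combination screens).  MuSyC metrics classify against their additivity
anchors (α = 1, β = 0, γ = 1) with a small tolerance band, since exact
equality never occurs in floating point.  Fits with R² below 0.8 are dropped
before aggregation.  All SDs are sample SDs (n − 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .musyc import MuSyCSurface

ANTAGONISM = "antagonism"
ADDITIVITY = "additivity"
SYNERGISM = "synergism"

WEAK = "weak"
STRONG = "strong"
NOT_APPLICABLE = "not_applicable"
DISCORDANT = "discordant"

DEFAULT_R2_THRESHOLD = 0.8
DEFAULT_TIME_WINDOW = (28.0, 80.0)


@dataclass
class InteractionCall:
    """One classification of a drug interaction metric."""

    label: str              # antagonism | additivity | synergism
    basis: str              # delta | alpha12 | alpha21 | beta | gamma12 | gamma21
    value: float
    strength: str = NOT_APPLICABLE


def gate_by_r2(fits: Sequence, threshold: float = DEFAULT_R2_THRESHOLD):
    """Split fits into (retained, exclusion log) by the R² quality gate.

    Each fit must expose ``r_squared``; entries may be bare fit objects or
    (metadata, fit) pairs.  The exclusion log records each dropped fit with
    whatever identity it carries.
    """
    retained, excluded = [], []
    for entry in fits:
        fit = entry[1] if isinstance(entry, tuple) else entry
        r2 = getattr(fit, "r_squared")
        if r2 is not None and r2 >= threshold:
            retained.append(entry)
        else:
            excluded.append({"entry": entry, "r_squared": r2, "threshold": threshold})
    return retained, excluded


def mean_sd(values: Iterable[float]) -> tuple[float, float]:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty list")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def aggregate_models(deltas: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean ± sample SD of per-model mean δ values."""
    return mean_sd(deltas)


def aggregate_timepoints(
    per_timepoint: Sequence[tuple[float, float]],
    window: tuple[float, float] = DEFAULT_TIME_WINDOW,
) -> tuple[float, float]:
    """Mean ± SD of (timepoint_h, value) pairs inside the inclusive window."""
    lo, hi = window
    vals = [v for t, v in per_timepoint if lo <= t <= hi]
    if not vals:
        raise ValueError(f"no timepoints inside window [{lo}, {hi}] h")
    return mean_sd(vals)


def classify_delta(delta: float) -> InteractionCall:
    """Classify a mean δ score: ≤ −5 antagonism, ≥ 5 synergism, else additive."""
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    if delta <= -5.0:
        label = ANTAGONISM
    elif delta >= 5.0:
        label = SYNERGISM
    else:
        label = ADDITIVITY
    return InteractionCall(label=label, basis="delta", value=float(delta))


_MUSYC_BASES = {
    # basis -> (additivity anchor, default tolerance kind)
    "alpha12": (1.0, "fold"),
    "alpha21": (1.0, "fold"),
    "beta": (0.0, "abs"),
    "gamma12": (1.0, "fold"),
    "gamma21": (1.0, "fold"),
}


def classify_musyc(
    surface: MuSyCSurface,
    tolerance: dict | None = None,
) -> list[InteractionCall]:
    """Classify each MuSyC synergy axis against its additivity anchor.

    Default tolerance band: ±0.05 on β (absolute), ±5 % on the fold
    parameters α and γ.  Parameters flagged unstable by the fit are still
    reported but marked ``not_applicable`` so aggregation can skip them.
    """
    tolerance = tolerance or {}
    beta_tol = float(tolerance.get("beta", 0.05))
    fold_tol = float(tolerance.get("fold", 0.05))
    unstable = surface.unstable or {}
    calls = []
    for basis, (anchor, kind) in _MUSYC_BASES.items():
        value = surface.beta if basis == "beta" else getattr(surface, basis)
        if kind == "abs":
            lo, hi = anchor - beta_tol, anchor + beta_tol
        else:
            lo, hi = anchor * (1 - fold_tol), anchor * (1 + fold_tol)
        if value > hi:
            label = SYNERGISM
        elif value < lo:
            label = ANTAGONISM
        else:
            label = ADDITIVITY
        strength = NOT_APPLICABLE if unstable.get(basis, False) else ""
        calls.append(InteractionCall(label=label, basis=basis, value=float(value),
                                     strength=strength or NOT_APPLICABLE))
    return calls


def consensus_strength(calls: Sequence[InteractionCall]) -> str:
    """Degree of agreement across per-model calls.

    All models synergistic → strong; a proper subset synergistic (rest
    additive) → weak; any mix of synergism and antagonism → discordant; no
    synergistic call → not_applicable.
    """
    if len(calls) < 2:
        raise ValueError("need >= 2 model calls for a consensus")
    labels = [c.label for c in calls]
    n_syn = labels.count(SYNERGISM)
    n_ant = labels.count(ANTAGONISM)
    if n_syn and n_ant:
        return DISCORDANT
    if n_syn == len(labels):
        return STRONG
    if n_syn >= 1:
        return WEAK
    return NOT_APPLICABLE
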