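"""Condition-comparison analytics on solved flux distributions.

Subsystem-level tables average the absolute net flux of each reaction within
a pathway label, per condition, and row-normalize across conditions for
heatmap-style comparison. Reaction-level change between a control and a
treatment condition is scored as log2 of the flux ratio with a small floor,
and the top-k most up-/down-regulated reactions are listed deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubsystemFluxTable",
    "FluxChangeResult",
    "subsystem_table",
    "log_ratio",
    "top_k",
    "DEFAULT_FLUX_FLOOR",
]

DEFAULT_FLUX_FLOOR = 1e-6


@dataclass
class SubsystemFluxTable:
    mean_flux: pd.DataFrame  # subsystems x conditions, mean |net flux|
    normalized: pd.DataFrame  # row min-max normalized twin in [0, 1]


@dataclass
class FluxChangeResult:
    scores: pd.Series  # log2(treat/control) per scored reaction id
    flagged: list[str]  # reactions excluded because both fluxes < floor
    up: list[tuple[str, float]]
    down: list[tuple[str, float]]


def subsystem_table(
    net_fluxes: dict[str, np.ndarray],
    reaction_ids: list[str],
    subsystems: list[str],
) -> SubsystemFluxTable:
    """Mean |net flux| per subsystem per condition, plus its row-normalized twin.

    Constant rows normalize to 0.5 (no cross-condition signal).
    """
    frame = pd.DataFrame(
        {cid: np.abs(np.asarray(v, dtype=float)) for cid, v in net_fluxes.items()},
        index=reaction_ids,
    )
    frame["subsystem"] = subsystems
    mean_flux = frame.groupby("subsystem").mean()
    lo = mean_flux.min(axis=1)
    hi = mean_flux.max(axis=1)
    rng = hi - lo
    normalized = mean_flux.sub(lo, axis=0).div(rng.where(rng > 0, 1.0), axis=0)
    normalized[rng == 0] = 0.5
    return SubsystemFluxTable(mean_flux=mean_flux, normalized=normalized)


def log_ratio(
    v_control: np.ndarray,
    v_treat: np.ndarray,
    reaction_ids: list[str],
    floor: float = DEFAULT_FLUX_FLOOR,
) -> FluxChangeResult:
    """log2(|v_treat| / |v_control|) with a flux floor.

    Each flux is floored at ``floor`` before the ratio; reactions where both
    conditions are below the floor carry no signal and are excluded (flagged)
    rather than reported as an artificial log-ratio of 0.
    """
    v_control = np.abs(np.asarray(v_control, dtype=float))
    v_treat = np.abs(np.asarray(v_treat, dtype=float))
    if v_control.shape != v_treat.shape or len(v_control) != len(reaction_ids):
        raise ValueError("flux vectors and reaction ids must have equal length")
    scores = {}
    flagged = []
    for rid, vc, vt in zip(reaction_ids, v_control, v_treat):
        if vc < floor and vt < floor:
            flagged.append(rid)
            continue
        scores[rid] = float(np.log2(max(vt, floor) / max(vc, floor)))
    series = pd.Series(scores, dtype=float)
    result = FluxChangeResult(scores=series, flagged=flagged, up=[], down=[])
    result.up, result.down = top_k(series)
    return result


def top_k(scores: pd.Series, k: int = 10) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """k largest and k smallest scores; ties broken by reaction id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    up = [(rid, float(s)) for rid, s in items[:k]]
    items_asc = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    down = [(rid, float(s)) for rid, s in items_asc[:k]]
    return up, down
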