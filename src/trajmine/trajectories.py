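"""Second mining step: concatenate directional pairs into linear trajectories.

Significant directional pairs D1 -> D2 and D2 -> D3 fuse into the
trajectory D1 -> D2 -> D3, and so on up to length six.  A patient
*follows* a trajectory when the first occurrences of all its codes appear
in the trajectory's order -- strictly increasing dates, with any other
diagnoses freely interleaved.  A trajectory is reported only when at
least ``min_followers`` patients follow it (20 by default), at every
reported length: a qualifying length-3 chain never suppresses its
length-2 prefixes.  Chaining never synthesises a direct pair: A -> C is
reported only if (A, C) itself was a significant directional pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .icd10 import DEATH_CODE
from .pairs import PairStatistics
from .registry import Registry, days_since_epoch, whole_year_age

_DAYS_PER_YEAR = 365.25


@dataclass(eq=False)
class LinearTrajectory:
    """An ordered chain of 2-6 codes with follower-based statistics.

    ``edge_stats`` holds the underlying :class:`PairStatistics` per
    adjacent pair.  Summary fields are filled by
    :func:`trajectory_summary` over the follower set only: mean age at
    the first code's first occurrence, mean years between consecutive
    first occurrences per edge, and the count of followers dead within
    five years of the final code's first occurrence.
    """

    codes: tuple[str, ...]
    n_followers: int
    edge_stats: tuple[PairStatistics, ...] = ()
    mean_age_at_inception: float | None = None
    inter_diagnosis_times: tuple[float, ...] | None = None
    mortality_5y: int | None = None
    sex: str = "all"

    @property
    def length(self) -> int:
        return len(self.codes)

    def __post_init__(self) -> None:
        if not 2 <= len(self.codes) <= 6:
            raise ValueError("trajectory length must be between 2 and 6")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError(f"repeated code in trajectory {self.codes}")
        if DEATH_CODE in self.codes[:-1]:
            raise ValueError("the death code may only terminate a trajectory")


def _follower_mask(
    pivot: pd.DataFrame, codes: Sequence[str]
) -> np.ndarray:
    """Boolean per patient: first occurrences strictly increasing in order."""
    for code in codes:
        if code not in pivot.columns:
            return np.zeros(len(pivot), dtype=bool)
    sub = days_since_epoch(pivot[list(codes)].to_numpy())
    ok = ~np.isnan(sub).any(axis=1)
    with np.errstate(invalid="ignore"):
        increasing = (np.diff(sub, axis=1) > 0).all(axis=1)
    return ok & increasing


def count_followers(
    registry: Registry, codes: Sequence[str], _pivot: pd.DataFrame | None = None
) -> int:
    """Number of patients whose first occurrences follow *codes* in order.

    Intervening other diagnoses are irrelevant; equal first-occurrence
    dates break the chain (no direction is observable on a same-day
    pair).
    """
    codes = list(codes)
    if len(codes) < 2:
        raise ValueError("a trajectory has at least two codes")
    if len(set(codes)) != len(codes):
        raise ValueError("trajectory codes must be distinct")
    pivot = registry.first_occurrences() if _pivot is None else _pivot
    return int(_follower_mask(pivot, codes).sum())


def build_trajectories(
    pairs: Sequence[PairStatistics],
    registry: Registry,
    min_followers: int = 20,
    max_length: int = 6,
) -> list[LinearTrajectory]:
    """Chain directional pairs into all qualifying linear trajectories.

    Depth-first extension over the pair graph, pruned by the
    anti-monotonicity of follower counts (an extension can never have
    more followers than its prefix).  Codes never repeat within one
    trajectory and the death code only appears terminally.  Returns every
    qualifying trajectory of every length from 2 to *max_length*,
    lexicographically ordered.
    """
    if not 2 <= max_length <= 6:
        raise ValueError("max_length must be between 2 and 6")
    by_key: dict[tuple[str, str], PairStatistics] = {}
    for pair in pairs:
        if (pair.d2, pair.d1) in by_key:
            raise ValueError(
                f"pair list contains both orientations of ({pair.d1}, {pair.d2})"
            )
        by_key[(pair.d1, pair.d2)] = pair
    adjacency: dict[str, list[str]] = {}
    for d1, d2 in sorted(by_key):
        adjacency.setdefault(d1, []).append(d2)

    pivot = registry.first_occurrences()
    results: list[LinearTrajectory] = []

    def extend(path: list[str], followers: int) -> None:
        if len(path) >= 2:
            results.append(
                LinearTrajectory(
                    codes=tuple(path),
                    n_followers=followers,
                    edge_stats=tuple(
                        by_key[(a, b)] for a, b in zip(path, path[1:])
                    ),
                )
            )
        if len(path) >= max_length:
            return
        for nxt in adjacency.get(path[-1], ()):
            if nxt in path:
                continue
            n = count_followers(registry, path + [nxt], _pivot=pivot)
            if n >= min_followers:
                extend(path + [nxt], n)

    for d1, d2 in sorted(by_key):
        if d1 == DEATH_CODE:
            continue
        n = count_followers(registry, [d1, d2], _pivot=pivot)
        if n >= min_followers:
            extend([d1, d2], n)

    results.sort(key=lambda t: t.codes)
    return results


def trajectory_summary(
    registry: Registry,
    trajectory: LinearTrajectory,
    mortality_horizon_years: float = 5.0,
) -> LinearTrajectory:
    """Fill follower-set summary statistics on a trajectory.

    Over followers only: mean age (whole years) at the first code's first
    occurrence, mean elapsed years per edge between consecutive first
    occurrences, and the count of followers whose death falls within
    *mortality_horizon_years* of the last code's first occurrence.
    """
    pivot = registry.first_occurrences()
    mask = _follower_mask(pivot, trajectory.codes)
    n = int(mask.sum())
    if n == 0:
        return replace(
            trajectory,
            n_followers=0,
            mean_age_at_inception=None,
            inter_diagnosis_times=None,
            mortality_5y=0,
        )
    sub = pivot.loc[mask, list(trajectory.codes)]
    patients = registry.patients.set_index("patient_id")
    birth = patients.loc[sub.index, "birth_date"].reset_index(drop=True)
    ages = whole_year_age(birth, sub[trajectory.codes[0]].reset_index(drop=True))
    days = days_since_epoch(sub.to_numpy())
    gaps = tuple(float(g) for g in np.diff(days, axis=1).mean(axis=0) / _DAYS_PER_YEAR)
    death = patients.loc[sub.index, "death_date"]
    death_days = days_since_epoch(death.to_numpy())
    last = days[:, -1]
    with np.errstate(invalid="ignore"):
        dead_soon = death_days <= last + mortality_horizon_years * _DAYS_PER_YEAR
    return replace(
        trajectory,
        n_followers=n,
        mean_age_at_inception=float(ages.mean()),
        inter_diagnosis_times=gaps,
        mortality_5y=int(np.nansum(dead_soon)),
    )


def trajectories_to_table(
    trajectories: Sequence[LinearTrajectory],
) -> pd.DataFrame:
    """Flat delimited-friendly table, one trajectory per row."""
    rows = []
    for t in trajectories:
        rows.append(
            {
                "trajectory": "->".join(t.codes),
                "length": t.length,
                "n_followers": t.n_followers,
                "mean_age_at_inception": t.mean_age_at_inception,
                "mean_gap_years": "|".join(
                    f"{g:.4f}" for g in (t.inter_diagnosis_times or ())
                ),
                "mortality_5y": t.mortality_5y,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trajectory",
            "length",
            "n_followers",
            "mean_age_at_inception",
            "mean_gap_years",
            "mortality_5y",
        ],
    )
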