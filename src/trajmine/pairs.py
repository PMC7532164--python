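"""First mining step: statistically significant directional diagnosis pairs.

The step runs in four stages, each of which is also exposed on its own:

1. *Pre-filter* -- an exact one-sided binomial test of how many D1
   patients receive D2 within the analysis window after D1's first
   occurrence, against the marginal frequency of D2 in the whole cohort.
   Deliberately cheap and conservative: it only has to produce a superset
   of the truly associated pairs.
2. *Matched controls* -- every exposed patient is matched, at their first
   D1 event, to randomly drawn unexposed patients sharing sex, whole-year
   age, discharge type and ISO discharge week (with documented
   relaxations when a pool is empty).  Replicate i yields the count C_i
   of matched controls that receive D2 within the window.
3. *Relative risk and pair significance* -- RR = C_exposed / mean(C_i);
   each matched control individual is a Bernoulli trial for acquiring D2
   in-window, the replicates pool into an estimate of that probability,
   and the exact binomial tail of C_exposed against it gives the pair
   P-value.
4. *Directionality* -- among patients holding both codes with first
   occurrences within the window of each other, an exact binomial test of
   D1-first orderings against D2-first orderings at probability 1/2.

All pair counting anchors on **first occurrences**, consistent with the
directionality and trajectory-follower semantics.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .icd10 import DEATH_CODE, DEFAULT_EXCLUDED_CHAPTERS
from .registry import (
    Registry,
    days_since_epoch,
    filter_chapters,
    inject_death_events,
    whole_year_age,
)

logger = logging.getLogger("trajmine")

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance thresholds and sampling sizes for pair mining.

    The two Bonferroni-corrected alphas are configuration defaults taken
    from the published pipeline, not recomputed here: the pre-filter runs
    at 1.21e-9 and the matched-control pair test at 1.21e-8, the
    directionality test at 0.05 with relative risk above ``min_rr``.
    """

    prefilter_alpha: float = 1.21e-9
    pair_alpha: float = 1.21e-8
    direction_alpha: float = 0.05
    n_controls: int = 10_000
    window_years: float = 5.0
    min_rr: float = 1.0
    excluded_chapters: frozenset[str] = DEFAULT_EXCLUDED_CHAPTERS

    def __post_init__(self) -> None:
        for name in ("prefilter_alpha", "pair_alpha", "direction_alpha"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.n_controls < 1:
            raise ValueError("n_controls must be at least 1")
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")


@dataclass(frozen=True)
class MatchKey:
    """Matching covariates derived from one event and its patient."""

    sex: str
    age: int
    discharge_type: str
    week: int


@dataclass(eq=False)
class PairStatistics:
    """Full statistics for one ordered candidate pair D1 -> D2."""

    d1: str
    d2: str
    n_exposed: int
    c_exposed: int
    control_counts: np.ndarray
    rr: float
    p_cooccurrence: float
    n_d1_first: int
    n_d2_first: int
    p_direction: float

    @property
    def mean_control_count(self) -> float:
        return float(np.mean(self.control_counts))

    @property
    def key(self) -> tuple[str, str]:
        return (self.d1, self.d2)


# ---------------------------------------------------------------------------
# Candidate enumeration and pre-filter
# ---------------------------------------------------------------------------

def enumerate_candidate_pairs(codes: Iterable[str]) -> list[tuple[str, str]]:
    """All K*(K-1) ordered pairs of distinct codes, lexicographic order."""
    ordered = sorted(set(codes))
    if not ordered:
        raise ValueError("code set is empty")
    return list(itertools.permutations(ordered, 2))


def _pivot_days(registry: Registry) -> tuple[np.ndarray, list[str], np.ndarray]:
    """First-occurrence matrix in float days (NaN = never), plus codes/ids."""
    table = registry.first_occurrences()
    codes = sorted(table.columns)
    table = table[codes]
    days = days_since_epoch(table.to_numpy())
    return days, codes, table.index.to_numpy()


def prefilter_pairs(
    registry: Registry,
    thresholds: ThresholdConfig | None = None,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Exact-binomial co-occurrence screen over all ordered pairs.

    For each ordered pair (D1, D2): of the ``n_exposed`` patients holding
    D1, count those whose first D2 occurrence falls within
    ``window_years`` after the first D1 occurrence, and compute the
    one-sided binomial tail P-value of that count against the null
    success probability ``P(patient holds D2)``.  Rows with
    ``p_cooccurrence < prefilter_alpha`` are retained (all rows when
    *keep_all*); a pair with zero co-occurrences has P = 1 and can never
    be retained.
    """
    thresholds = thresholds or ThresholdConfig()
    days, codes, _ = _pivot_days(registry)
    n_patients = registry.n_patients
    if n_patients == 0 or not codes:
        return pd.DataFrame(
            columns=["d1", "d2", "n_exposed", "c_within", "p_cooccurrence"]
        )
    window = thresholds.window_years * _DAYS_PER_YEAR
    present = ~np.isnan(days)
    marginal = present.sum(axis=0) / n_patients

    rows = []
    for i, d1 in enumerate(codes):
        n_exposed = int(present[:, i].sum())
        if n_exposed == 0:
            continue
        delta = days - days[:, [i]]
        with np.errstate(invalid="ignore"):
            within = (delta > 0) & (delta <= window)
        counts = within.sum(axis=0)
        pvals = binom.sf(counts - 1, n_exposed, marginal)
        for j, d2 in enumerate(codes):
            if j == i:
                continue
            rows.append((d1, d2, n_exposed, int(counts[j]), float(pvals[j])))
    table = pd.DataFrame(
        rows, columns=["d1", "d2", "n_exposed", "c_within", "p_cooccurrence"]
    )
    table = table.sort_values(["d1", "d2"]).reset_index(drop=True)
    if keep_all:
        return table
    retained = table[table["p_cooccurrence"] < thresholds.prefilter_alpha]
    return retained.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Matched-control sampling
# ---------------------------------------------------------------------------

_RELAXATION_LEVELS = (
    "full",        # sex + age + discharge type + ISO week
    "quarter",     # week relaxed to the same quarter of the ISO year
    "no_week",     # week dropped
    "no_discharge",  # discharge type dropped as well
    "sex_age",     # sex + age only
    "any",         # any unexposed patient
)


@dataclass
class ControlSample:
    """Matched-control assignment for one exposure code D1.

    ``control_ids[i, j]`` is the patient-table row index of the control
    matched to exposed patient j in replicate i, and ``matched_dates`` the
    control's own matching event date (float days).  The sample depends
    only on D1, so one sample serves every pair that shares the exposure.
    """

    d1: str
    exposed_ids: np.ndarray          # patient ids of exposed patients
    exposed_dates: np.ndarray        # first D1 event date per exposed (days)
    control_rows: np.ndarray         # (n_controls, n_exposed) int rows
    matched_dates: np.ndarray        # (n_controls, n_exposed) float days
    pool_patient_ids: np.ndarray     # row -> patient id
    relaxations: dict[str, int] = field(default_factory=dict)

    @property
    def n_controls(self) -> int:
        return self.control_rows.shape[0]

    def outcome_counts(
        self, registry: Registry, d2: str, window_years: float
    ) -> tuple[int, np.ndarray]:
        """(C_exposed, C_1..C_N) for outcome code *d2*.

        A patient counts when their first *d2* occurrence falls strictly
        after, and within *window_years* of, the anchoring event date.
        """
        first = registry.first_occurrences()
        window = window_years * _DAYS_PER_YEAR
        if d2 in first.columns:
            by_id = pd.Series(days_since_epoch(first[d2].to_numpy()), index=first.index)
        else:
            by_id = pd.Series(np.nan, index=first.index)
        exp_d2 = by_id.reindex(self.exposed_ids).to_numpy()
        with np.errstate(invalid="ignore"):
            c_exposed = int(
                ((exp_d2 > self.exposed_dates) & (exp_d2 <= self.exposed_dates + window)).sum()
            )
        ctl_d2 = by_id.reindex(self.pool_patient_ids).to_numpy()[self.control_rows]
        with np.errstate(invalid="ignore"):
            hits = (ctl_d2 > self.matched_dates) & (ctl_d2 <= self.matched_dates + window)
        return c_exposed, hits.sum(axis=1).astype(int)


def _first_exposure_events(registry: Registry, d1: str) -> pd.DataFrame:
    events = registry.events
    mine = events[events["code"] == d1]
    if mine.empty:
        raise ValueError(f"no patient carries code {d1!r}")
    mine = mine.sort_values(["patient_id", "date", "discharge_type"], kind="mergesort")
    return mine.groupby("patient_id", sort=True).first().reset_index()


def sample_matched_controls(
    registry: Registry,
    d1: str,
    n_controls: int,
    seed,
    exclude_code: str | None = None,
) -> ControlSample:
    """Draw matched-control replicates for exposure code *d1*.

    Each exposed patient is anchored at their first *d1* event; the
    matching pool holds unexposed patients with at least one (non-Y99)
    event sharing the full :class:`MatchKey`.  When the outcome code of
    interest is known, pass it as *exclude_code* so that the outcome
    itself cannot serve as the comparison event that admits a control
    into the pool (otherwise controls anchored at their own first
    outcome event systematically under-count).  Empty pools fall back
    through documented relaxations (week -> quarter -> no week -> no
    discharge type -> sex+age -> anyone), each occurrence logged.  Within
    one replicate controls are drawn without replacement where pool sizes
    permit.  Reproducible from *seed*.
    """
    exposures = _first_exposure_events(registry, d1)
    patients = registry.patients.set_index("patient_id")
    exposed_ids = exposures["patient_id"].to_numpy()
    exposed_set = set(exposed_ids)

    exp_birth = patients.loc[exposed_ids, "birth_date"].reset_index(drop=True)
    exp_sex = patients.loc[exposed_ids, "sex"].to_numpy()
    exp_age = whole_year_age(exp_birth, exposures["date"]).to_numpy()
    exp_week = exposures["week"].to_numpy()
    exp_dtype = exposures["discharge_type"].to_numpy()
    exposed_days = days_since_epoch(exposures["date"].to_numpy())

    # candidate events: unexposed patients, death code excluded
    pool_events = registry.events
    keep = (pool_events["code"] != DEATH_CODE) & ~pool_events["patient_id"].isin(
        exposed_set
    )
    if exclude_code is not None:
        keep &= pool_events["code"] != exclude_code
    pool_events = pool_events[keep].reset_index(drop=True)
    if pool_events.empty:
        raise ValueError(f"no unexposed patients available to match {d1!r}")
    pe_birth = patients.loc[pool_events["patient_id"], "birth_date"].reset_index(
        drop=True
    )
    pe = pd.DataFrame(
        {
            "patient_id": pool_events["patient_id"],
            "day": days_since_epoch(pool_events["date"].to_numpy()),
            "sex": patients.loc[pool_events["patient_id"], "sex"].to_numpy(),
            "age": whole_year_age(pe_birth, pool_events["date"]).to_numpy(),
            "dtype": pool_events["discharge_type"].to_numpy(),
            "week": pool_events["week"].to_numpy(),
        }
    )
    pe["quarter"] = (pe["week"] - 1).clip(lower=0) // 13
    # one row per (patient, key variant): keep the earliest matching event
    pe = pe.sort_values(["patient_id", "day"], kind="mergesort").reset_index(drop=True)
    pool_patient_ids = pe["patient_id"].to_numpy()

    def build_index(columns: list[str]) -> dict[tuple, np.ndarray]:
        # values are row labels into ``pe`` (a RangeIndex, so usable as
        # positions); drop_duplicates keeps each patient's earliest event
        # per key so draws are uniform over patients, not events
        if not columns:
            dedup = pe.drop_duplicates(["patient_id"])
            return {(): dedup.index.to_numpy()}
        dedup = pe.drop_duplicates(["patient_id"] + columns)
        groups = dedup.groupby(columns, sort=False).groups
        return {
            (k if isinstance(k, tuple) else (k,)): idx.to_numpy()
            for k, idx in groups.items()
        }

    indexes = {
        "full": build_index(["sex", "age", "dtype", "week"]),
        "quarter": build_index(["sex", "age", "dtype", "quarter"]),
        "no_week": build_index(["sex", "age", "dtype"]),
        "no_discharge": build_index(["sex", "age"]),
        "sex_age": build_index(["sex", "age"]),
        "any": build_index([]),
    }

    relaxations = dict.fromkeys(_RELAXATION_LEVELS, 0)
    pools: list[np.ndarray] = []
    for j in range(len(exposed_ids)):
        quarter = (int(exp_week[j]) - 1) // 13
        keys = {
            "full": (exp_sex[j], exp_age[j], exp_dtype[j], exp_week[j]),
            "quarter": (exp_sex[j], exp_age[j], exp_dtype[j], quarter),
            "no_week": (exp_sex[j], exp_age[j], exp_dtype[j]),
            "no_discharge": (exp_sex[j], exp_age[j]),
            "sex_age": (exp_sex[j], exp_age[j]),
            "any": (),
        }
        for level in _RELAXATION_LEVELS:
            pool = indexes[level].get(keys[level])
            if pool is not None and len(pool):
                relaxations[level] += 1
                pools.append(pool)
                break
    relaxed = {k: v for k, v in relaxations.items() if k != "full" and v}
    if relaxed:
        logger.info("matching pools for %s relaxed: %s", d1, relaxed)

    rng = np.random.default_rng(seed)
    n_exposed = len(pools)
    control_rows = np.empty((n_controls, n_exposed), dtype=np.int64)
    # vectorised first draw, then per-replicate collision resolution so
    # that one replicate reuses a control patient only when pools overlap
    # too tightly to avoid it
    for j, pool in enumerate(pools):
        control_rows[:, j] = pool[rng.integers(0, len(pool), size=n_controls)]
    for i in range(n_controls):
        used: set[str] = set()
        for j, pool in enumerate(pools):
            pid = pool_patient_ids[control_rows[i, j]]
            attempts = 0
            while pid in used and attempts < 8 and len(pool) > 1:
                control_rows[i, j] = pool[rng.integers(0, len(pool))]
                pid = pool_patient_ids[control_rows[i, j]]
                attempts += 1
            used.add(pid)
    matched_dates = pe["day"].to_numpy()[control_rows]
    return ControlSample(
        d1=d1,
        exposed_ids=exposed_ids,
        exposed_dates=exposed_days,
        control_rows=control_rows,
        matched_dates=matched_dates,
        pool_patient_ids=pool_patient_ids,
        relaxations=relaxations,
    )


# ---------------------------------------------------------------------------
# Relative risk, pair significance, directionality
# ---------------------------------------------------------------------------

def relative_risk(c_exposed: int, control_counts: Sequence[int]) -> float:
    """RR = C_exposed / mean(C_1..C_N); infinite when controls are all zero."""
    counts = np.asarray(control_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("control_counts must be non-empty")
    mean = float(counts.mean())
    if mean > 0:
        return float(c_exposed) / mean
    if c_exposed > 0:
        return math.inf
    raise ValueError(
        "relative risk undefined: no exposed and no control occurrences"
    )


def pair_significance(
    c_exposed: int, control_counts: Sequence[int], n_exposed: int
) -> float:
    """Exact binomial tail of the exposed count against the control rate.

    Each matched control individual is one Bernoulli trial for acquiring
    D2 within the window, so a control replicate's count is binomial;
    the N replicates pool into the estimate
    ``p = sum(C_i) / (N * n_exposed)`` and the P-value is
    P(X >= C_exposed) for X ~ Binomial(n_exposed, p), one-sided for
    excess risk.  Larger N sharpens the estimate of p but does not bound
    the attainable P-value.

    When no control ever acquires D2 the model degenerates: returns 0.0
    for a positive exposed count (the matched evidence is maximal, as is
    the relative risk) and 1.0 otherwise.
    """
    counts = np.asarray(control_counts)
    if counts.size < 1:
        raise ValueError("control_counts must be non-empty")
    if not 0 <= c_exposed <= n_exposed:
        raise ValueError("c_exposed must lie between 0 and n_exposed")
    rate = float(counts.sum()) / (counts.size * n_exposed)
    if rate <= 0.0:
        return 0.0 if c_exposed > 0 else 1.0
    return float(binom.sf(c_exposed - 1, n_exposed, min(rate, 1.0)))


def directionality_test(
    registry: Registry, d1: str, d2: str, window_years: float = 5.0
) -> tuple[int, int, float]:
    """Exact binomial test of D1-before-D2 orderings.

    Considers patients whose first occurrences of both codes lie within
    *window_years* of each other; same-day first occurrences carry no
    direction and are excluded.  Returns (n_d1_first, n_d2_first,
    one-sided P-value for the D1-first excess).
    """
    first = registry.first_occurrences()
    for code in (d1, d2):
        if code not in first.columns:
            raise ValueError(f"code {code!r} does not occur in the registry")
    t1 = days_since_epoch(first[d1].to_numpy())
    t2 = days_since_epoch(first[d2].to_numpy())
    window = window_years * _DAYS_PER_YEAR
    with np.errstate(invalid="ignore"):
        delta = t2 - t1
        usable = np.abs(delta) <= window
        n1 = int(((delta > 0) & usable).sum())
        n2 = int(((delta < 0) & usable).sum())
    if n1 + n2 == 0:
        raise ValueError(
            f"no patient orders the pair ({d1}, {d2}); direction undefined"
        )
    return n1, n2, float(binom.sf(n1 - 1, n1 + n2, 0.5))


# ---------------------------------------------------------------------------
# Full first step
# ---------------------------------------------------------------------------

@dataclass
class MiningResult:
    """Outcome of the full first step on one registry."""

    directional: list[PairStatistics]
    low_rr: list[PairStatistics]
    stage_counts: dict[str, int]
    thresholds: ThresholdConfig
    sex_filter: str
    seed: int

    @property
    def pairs_table(self) -> pd.DataFrame:
        return pairs_to_table(self.directional)


def pairs_to_table(pairs: Sequence[PairStatistics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "d1": p.d1,
                "d2": p.d2,
                "n_exposed": p.n_exposed,
                "c_exposed": p.c_exposed,
                "mean_control_count": p.mean_control_count,
                "rr": p.rr,
                "p_cooccurrence": p.p_cooccurrence,
                "n_d1_first": p.n_d1_first,
                "n_d2_first": p.n_d2_first,
                "p_direction": p.p_direction,
            }
            for p in pairs
        ],
        columns=[
            "d1",
            "d2",
            "n_exposed",
            "c_exposed",
            "mean_control_count",
            "rr",
            "p_cooccurrence",
            "n_d1_first",
            "n_d2_first",
            "p_direction",
        ],
    )


def _control_seed(seed: int, d1: str) -> np.random.SeedSequence:
    # keyed by (seed, code bytes) so a pair's draws do not depend on which
    # other pairs survived the pre-filter
    return np.random.SeedSequence([int(seed), int.from_bytes(d1.encode(), "big")])


def mine_directional_pairs(
    registry: Registry,
    thresholds: ThresholdConfig | None = None,
    sex_filter: str = "all",
    seed: int = 0,
) -> MiningResult:
    """Run the complete first step and return the directional pairs.

    Pipeline: optional sex restriction -> chapter filtering -> death-code
    injection -> pre-filter -> matched-control RR and pair significance ->
    directionality.  A pair is directional when it passes all four tests
    (prefilter_alpha, pair_alpha, rr > min_rr, direction_alpha); pairs
    that are significant but have RR below ``min_rr`` are returned
    separately in ``low_rr``.
    """
    thresholds = thresholds or ThresholdConfig()
    registry = registry.restrict_sex(sex_filter)
    events = filter_chapters(registry.events, thresholds.excluded_chapters)
    registry = Registry(registry.patients, events, registry.observation_window)
    registry = inject_death_events(registry, thresholds.window_years)

    codes = registry.codes
    n_candidates = len(codes) * (len(codes) - 1)
    retained = prefilter_pairs(registry, thresholds)
    logger.info(
        "pre-filter: %d of %d candidate pairs retained", len(retained), n_candidates
    )

    directional: list[PairStatistics] = []
    low_rr: list[PairStatistics] = []
    n_significant = 0
    for row in retained.itertuples(index=False):
        d1, d2 = row.d1, row.d2
        if d1 == DEATH_CODE:
            continue  # death has no successors
        sample = sample_matched_controls(
            registry,
            d1,
            thresholds.n_controls,
            _control_seed(seed, d1),
            exclude_code=d2,
        )
        c_exposed, control_counts = sample.outcome_counts(
            registry, d2, thresholds.window_years
        )
        try:
            rr = relative_risk(c_exposed, control_counts)
        except ValueError:
            continue
        p_pair = pair_significance(
            c_exposed, control_counts, len(sample.exposed_ids)
        )
        if p_pair >= thresholds.pair_alpha:
            continue
        n_significant += 1
        try:
            n1, n2, p_dir = directionality_test(
                registry, d1, d2, thresholds.window_years
            )
        except ValueError:
            continue
        stats = PairStatistics(
            d1=d1,
            d2=d2,
            n_exposed=len(sample.exposed_ids),
            c_exposed=c_exposed,
            control_counts=control_counts,
            rr=rr,
            p_cooccurrence=float(row.p_cooccurrence),
            n_d1_first=n1,
            n_d2_first=n2,
            p_direction=p_dir,
        )
        if rr <= thresholds.min_rr:
            if rr < 1.0:
                low_rr.append(stats)
            continue
        if p_dir < thresholds.direction_alpha:
            directional.append(stats)

    directional.sort(key=lambda p: p.key)
    low_rr.sort(key=lambda p: p.key)
    seen = {p.key for p in directional}
    assert not any((b, a) in seen for a, b in seen), "reversed duplicate pair"
    stage_counts = {
        "candidates": n_candidates,
        "prefiltered": len(retained),
        "significant": n_significant,
        "directional": len(directional),
    }
    logger.info("mining stages: %s", stage_counts)
    return MiningResult(
        directional=directional,
        low_rr=low_rr,
        stage_counts=stage_counts,
        thresholds=thresholds,
        sex_filter=sex_filter,
        seed=seed,
    )
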