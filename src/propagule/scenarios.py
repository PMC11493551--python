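"""Incursion-scenario design and batch execution.

A scenario is one incursion configuration: propagule size (PS, toads per
introduction event), propagule number (PN, 1–3 events), entry-point site and
the day of first introduction within a two-year span.  Scenario combinations
are drawn with a Latin hypercube over those four dimensions (optionally
maximin-optimised over candidate designs), each combination is replicated
with independent seeds, and every replicate is scored with the strict
establishment criterion: final adult count / total introduced > 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import ibm
from .environment import Landscape, RainfallSeries

PS_RANGE = (2, 20)
PN_RANGE = (1, 3)
SITES = ("site1", "site2")
INTRO_DAY_RANGE = (1, 730)
DEFAULT_MAX_YEARS = 3


@dataclass
class ScenarioParams:
    """One incursion configuration."""

    propagule_size: int
    propagule_number: int
    entry_point: str
    intro_days: list[int]
    replicate_seed: int = 0
    #: "per_event" introduces PS toads at every event (the default reading);
    #: "split_total" divides PS across the events as evenly as possible.
    propagule_interpretation: str = "per_event"

    def __post_init__(self):
        if self.propagule_size < 1:
            raise ValueError("propagule_size must be >= 1")
        if len(self.intro_days) != self.propagule_number:
            raise ValueError("intro_days must have one entry per event")
        days = sorted(int(d) for d in self.intro_days)
        lo, hi = INTRO_DAY_RANGE
        if days[0] < lo or days[-1] > hi:
            raise ValueError(f"intro days must lie in [{lo}, {hi}]")
        self.intro_days = days

    def event_sizes(self) -> list[int]:
        if self.propagule_interpretation == "per_event":
            return [self.propagule_size] * self.propagule_number
        if self.propagule_interpretation == "split_total":
            base, extra = divmod(self.propagule_size, self.propagule_number)
            return [base + (1 if i < extra else 0)
                    for i in range(self.propagule_number)]
        raise ValueError(
            f"unknown propagule interpretation {self.propagule_interpretation!r}")

    @property
    def total_introduced(self) -> int:
        return sum(self.event_sizes())


@dataclass
class ScenarioResult:
    established: int
    final_adult_count: int
    total_introduced: int
    extinction_day: int | None = None
    trajectory: pd.DataFrame | None = None


@dataclass
class LhsDesign:
    """A scenario design table plus the pre-discretisation unit draws."""

    table: pd.DataFrame
    unit_sample: np.ndarray
    seed: int | None = None
    optimize: str = "none"

    def __len__(self):
        return len(self.table)


def _min_pairwise_distance(sample: np.ndarray) -> float:
    from scipy.spatial.distance import pdist
    return float(pdist(sample).min())


def lhs_design(n_combos: int, seed, optimize: str = "none",
               n_candidates: int = 10, rng_extra=None) -> LhsDesign:
    """Latin hypercube design over (PS, PN, site, first introduction day).

    Continuous unit-cube draws (one per stratum per dimension — the Latin
    property) are discretised onto PS ∈ [2, 20], PN ∈ {1, 2, 3}, site ∈
    {site1, site2} and first day ∈ [1, 730]; additional event days are drawn
    uniformly after the first.  ``optimize="maximin"`` keeps the best of
    ``n_candidates`` same-seeded candidate designs by minimum pairwise
    distance (candidate 1 is the unoptimised design, so the optimum can only
    improve on it).
    """
    if n_combos < 1:
        raise ValueError("n_combos must be >= 1")
    if optimize not in ("none", "maximin"):
        raise ValueError(f"unknown optimize option {optimize!r}")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=max(1, n_candidates))
    samples = [qmc.LatinHypercube(d=4, seed=int(s)).random(n_combos)
               for s in (sub_seeds if optimize == "maximin" else sub_seeds[:1])]
    if optimize == "maximin" and n_combos > 1:
        sample = max(samples, key=_min_pairwise_distance)
    else:
        sample = samples[0]

    ps = (PS_RANGE[0] + np.floor(sample[:, 0] * (PS_RANGE[1] - PS_RANGE[0] + 1))
          ).clip(*PS_RANGE).astype(int)
    pn = (PN_RANGE[0] + np.floor(sample[:, 1] * 3)).clip(*PN_RANGE).astype(int)
    site = np.where(sample[:, 2] < 0.5, SITES[0], SITES[1])
    day1 = (1 + np.floor(sample[:, 3] * INTRO_DAY_RANGE[1])
            ).clip(*INTRO_DAY_RANGE).astype(int)

    rows = []
    for i in range(n_combos):
        days = [int(day1[i])]
        for _ in range(int(pn[i]) - 1):
            lo = min(days[0] + 1, INTRO_DAY_RANGE[1])
            days.append(int(rng.integers(lo, INTRO_DAY_RANGE[1] + 1)))
        days = sorted(days)
        rows.append({
            "combo_id": i, "propagule_size": int(ps[i]),
            "propagule_number": int(pn[i]), "entry_point": site[i],
            "intro_day_1": days[0],
            "intro_day_2": days[1] if len(days) > 1 else np.nan,
            "intro_day_3": days[2] if len(days) > 2 else np.nan,
        })
    table = pd.DataFrame(rows)
    return LhsDesign(table=table, unit_sample=sample, seed=None if seed is None
                     else int(np.asarray(seed).ravel()[0]) if np.ndim(seed) else int(seed),
                     optimize=optimize)


def params_from_row(row, seed=0, propagule_interpretation="per_event") -> ScenarioParams:
    days = [int(row["intro_day_1"])]
    for k in ("intro_day_2", "intro_day_3"):
        v = row.get(k) if isinstance(row, dict) else row[k]
        if v is not None and not pd.isna(v):
            days.append(int(v))
    return ScenarioParams(
        propagule_size=int(row["propagule_size"]),
        propagule_number=int(row["propagule_number"]),
        entry_point=str(row["entry_point"]),
        intro_days=days, replicate_seed=int(seed),
        propagule_interpretation=propagule_interpretation)


def run_scenario(params: ScenarioParams, landscape: Landscape,
                 rainfall: RainfallSeries, ibm_params: ibm.IbmParams | None = None,
                 max_years: int = DEFAULT_MAX_YEARS, rng=None,
                 validate_ledger: bool = False,
                 record_trajectory: bool = False) -> ScenarioResult:
    """Run one replicate: introductions fire on their days, the simulator is
    stepped daily until 3 years after first introduction or extinction.

    Cohorts from separate events share the arena and interact freely.
    Establishment is scored by the strict ratio rule
    ``final adults / total introduced > 1.0``.
    """
    ibm_params = ibm_params or ibm.IbmParams()
    if params.entry_point not in landscape.entry_points:
        raise ValueError(f"landscape has no entry point {params.entry_point!r}; "
                         f"available: {sorted(landscape.entry_points)}")
    entry_cell = landscape.entry_points[params.entry_point]
    rng = rng if rng is not None else np.random.default_rng(params.replicate_seed)

    first = params.intro_days[0]
    end_day = first + 365 * max_years
    if rainfall.n_days < end_day - 1:
        raise ValueError(f"rainfall series too short: needs {end_day - 1} days, "
                         f"has {rainfall.n_days}")
    intro_schedule: dict[int, int] = {}
    for day, size in zip(params.intro_days, params.event_sizes()):
        intro_schedule[day] = intro_schedule.get(day, 0) + size

    state = ibm.SimState(day=first, validate_ledger=validate_ledger)
    extinction_day = None
    trajectory = [] if record_trajectory else None
    last_intro = max(intro_schedule)
    while state.day < end_day:
        if state.day in intro_schedule:
            ibm.introduce(state, intro_schedule[state.day], entry_cell,
                          landscape, ibm_params, rng)
        ibm.step(state, landscape, rainfall, ibm_params, rng)
        if record_trajectory:
            trajectory.append((state.day - 1, state.n_adults(),
                               len(state.toads)))
        if state.is_extinct() and state.day > last_intro:
            extinction_day = state.day - 1
            break

    final_adults = state.n_adults()
    total = params.total_introduced
    established = int(final_adults / total > 1.0)
    traj = (pd.DataFrame(trajectory, columns=["day", "adults", "terrestrial"])
            if record_trajectory else None)
    return ScenarioResult(established=established, final_adult_count=final_adults,
                          total_introduced=total, extinction_day=extinction_day,
                          trajectory=traj)


def enumerate_jobs(table: pd.DataFrame, replicates: int) -> list:
    """The (combination, replicate) execution list of a batch:
    one entry per scenario run, n_combos × replicates in total."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    return [(row, rep) for _, row in table.iterrows()
            for rep in range(replicates)]


def replicate_rng(base_seed: int, combo_id: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from the batch seed."""
    ss = np.random.SeedSequence([int(base_seed), int(combo_id), int(replicate)])
    return np.random.default_rng(ss)


def run_batch(design: LhsDesign | pd.DataFrame, landscapes: dict[str, Landscape],
              rainfall: RainfallSeries, ibm_params: ibm.IbmParams | None = None,
              replicates: int = 30, base_seed: int = 0,
              max_years: int = DEFAULT_MAX_YEARS, workers: int = 1,
              propagule_interpretation: str = "per_event") -> pd.DataFrame:
    """Execute every (combination, replicate) pair; one outcome row each.

    ``landscapes`` maps entry-point names (site1/site2) to the landscape
    holding that entry point.  A failed replicate is recorded with
    ``error = 1`` rather than dropped.  Row count = n_combos × replicates.
    """
    table = design.table if isinstance(design, LhsDesign) else design
    if len(table) == 0:
        raise ValueError("design is empty")
    ibm_params = ibm_params or ibm.IbmParams()
    jobs = enumerate_jobs(table, replicates)

    def _one(row, rep):
        combo = int(row["combo_id"])
        rng = replicate_rng(base_seed, combo, rep)
        seed_label = hash((base_seed, combo, rep)) & 0x7FFFFFFF
        sp = params_from_row(row, seed=seed_label,
                             propagule_interpretation=propagule_interpretation)
        out = {"combo_id": combo, "replicate": rep, "seed": seed_label,
               "PS": sp.propagule_size, "PN": sp.propagule_number,
               "SE": sp.entry_point, "intro_day": sp.intro_days[0],
               "established": 0, "final_adults": 0,
               "total_introduced": sp.total_introduced,
               "extinction_day": np.nan, "error": 0}
        try:
            land = landscapes[sp.entry_point]
            res = run_scenario(sp, land, rainfall, ibm_params,
                               max_years=max_years, rng=rng)
            out.update(established=res.established,
                       final_adults=res.final_adult_count,
                       total_introduced=res.total_introduced,
                       extinction_day=(np.nan if res.extinction_day is None
                                       else res.extinction_day))
        except Exception:
            out["error"] = 1
        return out

    if workers and workers > 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=workers)(delayed(_one)(row, rep)
                                        for row, rep in jobs)
    else:
        rows = [_one(row, rep) for row, rep in jobs]
    return pd.DataFrame(rows)
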