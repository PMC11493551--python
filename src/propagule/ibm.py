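"""Daily-time-step individual-based simulator of toad life history.

Terrestrial toads (metamorphs, juveniles, adults) are individuals held in a
struct-of-arrays :class:`Population`; aquatic eggs and tadpoles are pooled
into per-clutch cohorts (:class:`Cohorts`), which keeps clutches of ~10⁴ eggs
cheap to simulate.  Each simulated day executes a fixed phase order:

1. environment update (season label, wet-season reset of spawning flags)
2. aquatic development (hatching at 3 days, metamorphosis at 34–55 days)
3. behaviour choice (inactive / breeding / rehydrating / foraging)
4. movement (season-specific kernels, road preference, ≤ 1000 m per day)
5. breeding and spawning (wet-season adults; females spawn once per season)
6. hydration update (ambient rehydration on wet/rainy days, at water margins
   and in human habitation; otherwise a fixed daily loss fraction)
7. mortality (stage-specific daily probabilities, egg cannibalism by
   tadpoles, larval carrying capacity, deterministic desiccation at 40% loss)
8. ageing and growth (von Bertalanffy growth in SVL; stage transitions at
   SVL thresholds calibrated to a mean maturation age of 243 days)

Reproduction must see post-movement positions, and mortality runs late so a
same-day spawner can die without losing her clutch — hence the phase order.
A per-compartment conservation ledger is reconciled after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .environment import Landscape, RainfallSeries, day_of_year, WET_ONSET_DOY

# stage / sex / activity / hydric-state codes
STAGE_METAMORPH, STAGE_JUVENILE, STAGE_ADULT = 0, 1, 2
SEX_MALE, SEX_FEMALE = 0, 1
ACT_INACTIVE, ACT_BREEDING, ACT_REHYDRATING, ACT_FORAGING = 0, 1, 2, 3
HYD_HYDRATED, HYD_DEHYDRATED, HYD_EXTREME, HYD_DESICCATED = 0, 1, 2, 3

STAGE_NAMES = {STAGE_METAMORPH: "metamorph", STAGE_JUVENILE: "juvenile",
               STAGE_ADULT: "adult"}
ACTIVITY_NAMES = {ACT_INACTIVE: "inactive", ACT_BREEDING: "breeding",
                  ACT_REHYDRATING: "rehydrating", ACT_FORAGING: "foraging"}


@dataclass
class IbmParams:
    """Life-history, physiology and movement parameters (daily rates).

    Values the source system prints are used directly (hatching, metamorphosis
    and maturation times, fecundity range, hydric thresholds, introduction SVL,
    movement ceiling); the rest are documented modelling assumptions and are
    all overridable.
    """

    # development
    hatch_days: int = 3
    metamorph_min: int = 34
    metamorph_max: int = 55
    maturity_mean_days: float = 243.0
    # fecundity (eggs per clutch, linear in female SVL)
    fecundity_min: int = 7675
    fecundity_max: int = 14288
    # hydric physiology (fractions of standard body weight lost)
    dehydration_threshold: float = 0.10
    extreme_dehydration_threshold: float = 0.25
    desiccation_threshold: float = 0.40
    daily_water_loss_frac: float = 0.10
    # movement
    max_daily_move_m: float = 1000.0
    wet_move_scale_m: float = 120.0
    dry_move_scale_m: float = 25.0
    directed_move_scale_m: float = 300.0
    heading_persistence_sd: float = 0.6   # radians, wet-season persistent walk
    road_preference_weight: float = 3.0
    perception_range_m: float = 200.0
    # behaviour propensities
    p_breed_wet: float = 0.8
    p_inactive_wet: float = 0.2
    p_inactive_dry: float = 0.5
    # mortality (daily probabilities, ordered: eggs highest)
    mort_egg: float = 0.05
    mort_tadpole: float = 0.02
    mort_metamorph: float = 0.01
    mort_juvenile: float = 0.005
    mort_adult: float = 0.001
    egg_cannibalism_frac: float = 0.5     # extra egg removal when tadpoles share the cell
    tadpole_capacity_per_cell: int = 500  # larval carrying capacity per water cell
    # introduction cohort
    sex_ratio: float = 0.5
    intro_svl_mean: float = 90.0
    intro_svl_sd: float = 10.0
    intro_svl_min: float = 70.0
    intro_svl_max: float = 110.0
    # growth (von Bertalanffy in SVL, mm)
    metamorph_svl_mm: float = 25.0
    juvenile_svl_mm: float = 40.0
    adult_svl_mm: float = 70.0
    svl_asymptote_mm: float = 120.0
    growth_k_cv: float = 0.2              # lognormal sd of individual growth rates

    def __post_init__(self):
        probs = [self.mort_egg, self.mort_tadpole, self.mort_metamorph,
                 self.mort_juvenile, self.mort_adult, self.sex_ratio,
                 self.p_breed_wet, self.p_inactive_wet, self.p_inactive_dry,
                 self.egg_cannibalism_frac]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not (self.dehydration_threshold < self.extreme_dehydration_threshold
                < self.desiccation_threshold):
            raise ValueError("hydric thresholds must be ordered "
                             "dehydrated < extreme < desiccated")
        if self.fecundity_min >= self.fecundity_max:
            raise ValueError("fecundity_min must be below fecundity_max")

    @property
    def growth_k(self) -> float:
        """Base growth rate solving for the mean maturation age.

        Maturation (metamorph SVL -> adult SVL threshold) takes
        ``ln((L∞−L0)/(L∞−L_adult)) / k`` days under exponential approach to
        the asymptote, so ``k`` is chosen to make that equal the mean
        maturation age.
        """
        num = self.svl_asymptote_mm - self.metamorph_svl_mm
        den = self.svl_asymptote_mm - self.adult_svl_mm
        return math.log(num / den) / self.maturity_mean_days

    def stage_mortality(self) -> np.ndarray:
        return np.array([self.mort_metamorph, self.mort_juvenile, self.mort_adult])

    def to_dict(self) -> dict:
        return asdict(self)


def hydric_state(loss_frac, params: IbmParams):
    """Map hydration loss fractions onto the four hydric states (monotone)."""
    loss = np.asarray(loss_frac, dtype=float)
    state = np.zeros(loss.shape, dtype=np.int8)
    state[loss >= params.dehydration_threshold] = HYD_DEHYDRATED
    state[loss >= params.extreme_dehydration_threshold] = HYD_EXTREME
    state[loss >= params.desiccation_threshold] = HYD_DESICCATED
    return state


def clutch_size(svl_mm, params: IbmParams):
    """Eggs per clutch: linear map of female SVL onto the fecundity range."""
    svl = np.asarray(svl_mm, dtype=float)
    frac = (svl - params.adult_svl_mm) / (params.intro_svl_max - params.adult_svl_mm)
    size = params.fecundity_min + frac * (params.fecundity_max - params.fecundity_min)
    return np.clip(np.rint(size), params.fecundity_min, params.fecundity_max).astype(np.int64)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

_TOAD_FIELDS = {
    "id": np.int64, "sex": np.int8, "stage": np.int8, "age_days": np.int32,
    "svl_mm": np.float64, "growth_k": np.float64, "hydration_loss": np.float64,
    "activity": np.int8, "cell": np.int64, "heading": np.float64,
    "has_spawned": np.bool_,
}

_CLUTCH_FIELDS = {
    "cell": np.int64, "n_eggs": np.int64, "n_tadpoles": np.int64,
    "age_days": np.int32, "meta_age": np.int32, "mother_id": np.int64,
}


class _SoA:
    """Minimal growable struct-of-arrays container."""

    _fields: dict

    def __init__(self, **arrays):
        n = None
        for name, dtype in self._fields.items():
            arr = np.asarray(arrays.get(name, np.empty(0, dtype)), dtype=dtype)
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError(f"field {name} length mismatch")
            setattr(self, name, arr)

    def __len__(self):
        return len(getattr(self, next(iter(self._fields))))

    def add(self, **arrays):
        n_new = len(np.atleast_1d(arrays[next(iter(self._fields))]))
        for name, dtype in self._fields.items():
            if name not in arrays:
                raise ValueError(f"missing field {name}")
            new = np.broadcast_to(np.asarray(arrays[name], dtype=dtype), (n_new,))
            setattr(self, name, np.concatenate([getattr(self, name), new]))

    def remove(self, mask):
        keep = ~np.asarray(mask, dtype=bool)
        for name in self._fields:
            setattr(self, name, getattr(self, name)[keep])


class Population(_SoA):
    """Terrestrial toads as parallel arrays (one slot per individual)."""

    _fields = _TOAD_FIELDS

    def stage_counts(self) -> np.ndarray:
        return np.bincount(self.stage, minlength=3)


class Cohorts(_SoA):
    """Aquatic egg/tadpole cohorts, one slot per clutch."""

    _fields = _CLUTCH_FIELDS

    def tadpoles_per_cell(self, n_cells: int) -> np.ndarray:
        if len(self) == 0:
            return np.zeros(n_cells, dtype=np.int64)
        return np.bincount(self.cell, weights=self.n_tadpoles,
                           minlength=n_cells).astype(np.int64)


_FLOW_KEYS = ("introduced", "eggs_laid", "hatched", "metamorphosed",
              "matured_mj", "matured_ja", "deaths_egg", "deaths_tadpole",
              "deaths_metamorph", "deaths_juvenile", "deaths_adult")


@dataclass
class SimState:
    """Mutable simulation state: day counter, populations and the ledger."""

    day: int = 1
    toads: Population = field(default_factory=Population)
    clutches: Cohorts = field(default_factory=Cohorts)
    flows: dict = field(default_factory=lambda: {k: 0 for k in _FLOW_KEYS})
    tallies: dict = field(default_factory=lambda: {k: 0 for k in _FLOW_KEYS})
    next_id: int = 0
    validate_ledger: bool = False
    _last_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(5, dtype=np.int64))

    def compartment_counts(self) -> np.ndarray:
        """(eggs, tadpoles, metamorphs, juveniles, adults)."""
        sc = self.toads.stage_counts()
        return np.array([int(self.clutches.n_eggs.sum()),
                         int(self.clutches.n_tadpoles.sum()),
                         sc[STAGE_METAMORPH], sc[STAGE_JUVENILE],
                         sc[STAGE_ADULT]], dtype=np.int64)

    def n_adults(self) -> int:
        return int(self.toads.stage_counts()[STAGE_ADULT])

    def is_extinct(self) -> bool:
        return len(self.toads) == 0 and len(self.clutches) == 0

    def check_ledger(self):
        """Reconcile compartment counts against the accumulated flows."""
        f = self.flows
        e0, t0, m0, j0, a0 = self._last_counts
        expected = np.array([
            e0 + f["eggs_laid"] - f["hatched"] - f["deaths_egg"],
            t0 + f["hatched"] - f["metamorphosed"] - f["deaths_tadpole"],
            m0 + f["metamorphosed"] - f["deaths_metamorph"] - f["matured_mj"],
            j0 + f["matured_mj"] - f["deaths_juvenile"] - f["matured_ja"],
            a0 + f["introduced"] + f["matured_ja"] - f["deaths_adult"],
        ])
        actual = self.compartment_counts()
        if not np.array_equal(expected, actual):
            raise AssertionError(
                f"conservation ledger violated on day {self.day}: "
                f"expected {expected.tolist()}, got {actual.tolist()}")

    def _close_day(self):
        for k, v in self.flows.items():
            self.tallies[k] += v
        self._last_counts = self.compartment_counts()
        self.flows = {k: 0 for k in _FLOW_KEYS}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def introduce(state: SimState, n: int, entry_cell: int, landscape: Landscape,
              params: IbmParams, rng: np.random.Generator) -> SimState:
    """Add ``n`` adult founders at the entry cell.

    Sexes are i.i.d. Bernoulli(sex ratio); SVL is normal with mean 90 mm
    truncated to [70, 110] mm, matching intercepted colonists.
    """
    if n < 1:
        raise ValueError("must introduce at least one toad")
    if not landscape.is_terrestrial[entry_cell]:
        raise ValueError(f"entry cell {entry_cell} is not terrestrial "
                         "(ocean or water)")
    a = (params.intro_svl_min - params.intro_svl_mean) / params.intro_svl_sd
    b = (params.intro_svl_max - params.intro_svl_mean) / params.intro_svl_sd
    svl = truncnorm.rvs(a, b, loc=params.intro_svl_mean,
                        scale=params.intro_svl_sd, size=n, random_state=rng)
    ids = np.arange(state.next_id, state.next_id + n)
    state.next_id += n
    state.toads.add(
        id=ids,
        sex=np.where(rng.random(n) < params.sex_ratio,
                     SEX_FEMALE, SEX_MALE).astype(np.int8),
        stage=np.full(n, STAGE_ADULT, dtype=np.int8),
        age_days=np.full(n, int(params.maturity_mean_days), dtype=np.int32),
        svl_mm=svl,
        growth_k=params.growth_k * rng.lognormal(0.0, params.growth_k_cv, n),
        hydration_loss=np.zeros(n),
        activity=np.full(n, ACT_INACTIVE, dtype=np.int8),
        cell=np.full(n, entry_cell, dtype=np.int64),
        heading=rng.uniform(0, 2 * math.pi, n),
        has_spawned=np.zeros(n, dtype=bool),
    )
    state.flows["introduced"] += n
    return state


def decide_behaviour(pop: Population, landscape: Landscape, wet: bool,
                     raining: bool, params: IbmParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Daily activity for every terrestrial toad.

    Dehydrated (and worse) toads prioritise rehydrating; only adults may
    breed, only in the wet season, and females never after spawning that
    season; remaining active toads forage; the rest shelter.
    """
    n = len(pop)
    act = np.full(n, ACT_INACTIVE, dtype=np.int8)
    if n == 0:
        return act
    hyd = hydric_state(pop.hydration_loss, params)
    needs_water = hyd >= HYD_DEHYDRATED
    act[needs_water] = ACT_REHYDRATING
    if wet:
        eligible = ((pop.stage == STAGE_ADULT) & ~needs_water
                    & ((pop.sex == SEX_MALE) | ~pop.has_spawned))
        act[eligible & (rng.random(n) < params.p_breed_wet)] = ACT_BREEDING
    rest = ~needs_water & (act != ACT_BREEDING)
    p_inactive = params.p_inactive_wet if wet or raining else params.p_inactive_dry
    act[rest & (rng.random(n) >= p_inactive)] = ACT_FORAGING
    return act


def disperse(pop: Population, move_mask: np.ndarray, landscape: Landscape,
             wet: bool, params: IbmParams, rng: np.random.Generator) -> None:
    """Move juveniles/adults one daily step; updates cells and headings.

    Rehydrating toads head straight for the nearest rehydration site and
    breeding toads for the nearest water margin (never overshooting the
    target); foragers take a kernel step — persistent-heading long steps in
    the wet season, short random-heading steps in the dry — choosing among
    candidate headings with extra weight on road cells.  Realised
    centre-to-centre displacement never exceeds the daily movement ceiling.
    """
    idx = np.flatnonzero(move_mask & (pop.stage >= STAGE_JUVENILE)
                         & (pop.activity != ACT_INACTIVE))
    if idx.size == 0:
        return
    grid = landscape.grid
    cap = max(params.max_daily_move_m - grid.spacing_m, 0.0)
    act = pop.activity[idx]
    cell = pop.cell[idx]
    x, y = grid.centres(cell)
    new_cell = cell.copy()

    directed = (act == ACT_REHYDRATING) | (act == ACT_BREEDING)
    if directed.any():
        near_reh, dist_reh = landscape.nearest_map("rehydration")
        near_br, dist_br = landscape.nearest_map("breeding_margin")
        di = np.flatnonzero(directed)
        c = cell[di]
        rehydrating = act[di] == ACT_REHYDRATING
        target = np.where(rehydrating, near_reh[c], near_br[c])
        tdist = np.where(rehydrating, dist_reh[c], dist_br[c])
        ok = target >= 0
        step_len = np.minimum(rng.exponential(params.directed_move_scale_m,
                                              di.size), cap)
        arrive = ok & (step_len >= tdist)
        new_cell[di[arrive]] = target[arrive]
        enroute = ok & ~arrive & (tdist > 0)
        if enroute.any():
            e = di[enroute]
            tx, ty = grid.centres(target[enroute])
            ux = (tx - x[e]) / tdist[enroute]
            uy = (ty - y[e]) / tdist[enroute]
            dest = grid.xy_to_cell(x[e] + ux * step_len[enroute],
                                   y[e] + uy * step_len[enroute])
            valid = landscape.is_terrestrial[dest]
            new_cell[e[valid]] = dest[valid]

    foraging = act == ACT_FORAGING
    if foraging.any():
        fi = np.flatnonzero(foraging)
        scale = params.wet_move_scale_m if wet else params.dry_move_scale_m
        step_len = np.minimum(rng.exponential(scale, fi.size), cap)
        if wet:
            primary = pop.heading[idx[fi]] + rng.normal(
                0.0, params.heading_persistence_sd, fi.size)
        else:
            primary = rng.uniform(0, 2 * math.pi, fi.size)
        headings = np.column_stack([
            primary,
            rng.uniform(0, 2 * math.pi, fi.size),
            rng.uniform(0, 2 * math.pi, fi.size),
        ])
        dest = grid.xy_to_cell(
            x[fi, None] + np.cos(headings) * step_len[:, None],
            y[fi, None] + np.sin(headings) * step_len[:, None])
        weights = landscape.is_terrestrial[dest].astype(float)
        weights *= np.where(landscape.is_road[dest],
                            params.road_preference_weight, 1.0)
        total = weights.sum(axis=1)
        movable = total > 0
        pick = np.zeros(fi.size, dtype=np.int64)
        u = rng.random(fi.size) * np.where(total > 0, total, 1.0)
        cum = np.cumsum(weights, axis=1)
        pick = (u[:, None] > cum).sum(axis=1).clip(0, 2)
        chosen = dest[np.arange(fi.size), pick]
        new_cell[fi[movable]] = chosen[movable]
        pop.heading[idx[fi[movable]]] = headings[np.arange(fi.size), pick][movable]

    pop.cell[idx] = new_cell


def spawn_clutch(state: SimState, female_pos: int, landscape: Landscape,
                 params: IbmParams, rng: np.random.Generator,
                 tadpoles_per_cell: np.ndarray | None = None) -> int | None:
    """Attempt to spawn for the female at array position ``female_pos``.

    The clutch cell is the perceptible water cell with the fewest resident
    tadpoles (ties: nearest, then lowest index).  Returns the chosen cell, or
    None when no waterbody lies within perception (the attempt fails).
    """
    pop = state.toads
    if tadpoles_per_cell is None:
        tadpoles_per_cell = state.clutches.tadpoles_per_cell(landscape.grid.n_cells)
    fx, fy = landscape.grid.centres(int(pop.cell[female_pos]))
    candidates = landscape.water_cells_within(float(fx), float(fy),
                                              params.perception_range_m)
    if candidates.size == 0:
        return None
    counts = tadpoles_per_cell[candidates]
    cx, cy = landscape.grid.centres(candidates)
    dist = np.hypot(cx - fx, cy - fy)
    best = np.lexsort((candidates, dist, counts))[0]
    target = int(candidates[best])
    n_eggs = int(clutch_size(pop.svl_mm[female_pos], params))
    state.clutches.add(
        cell=target, n_eggs=n_eggs, n_tadpoles=0, age_days=0,
        meta_age=int(rng.integers(params.metamorph_min, params.metamorph_max + 1)),
        mother_id=int(pop.id[female_pos]))
    pop.has_spawned[female_pos] = True
    state.flows["eggs_laid"] += n_eggs
    return target


def _spawning_phase(state: SimState, landscape: Landscape, params: IbmParams,
                    rng: np.random.Generator) -> None:
    pop = state.toads
    breeding = pop.activity == ACT_BREEDING
    females = np.flatnonzero(breeding & (pop.sex == SEX_FEMALE)
                             & ~pop.has_spawned & (pop.stage == STAGE_ADULT))
    males = np.flatnonzero(breeding & (pop.sex == SEX_MALE)
                           & (pop.stage == STAGE_ADULT))
    if females.size == 0 or males.size == 0:
        return
    mx, my = landscape.grid.centres(pop.cell[males])
    tree = cKDTree(np.column_stack([mx, my]))
    fx, fy = landscape.grid.centres(pop.cell[females])
    d, _ = tree.query(np.column_stack([fx, fy]))
    paired = females[d <= params.perception_range_m]
    if paired.size == 0:
        return
    tpc = state.clutches.tadpoles_per_cell(landscape.grid.n_cells)
    for pos in paired:
        cell = spawn_clutch(state, int(pos), landscape, params, rng,
                            tadpoles_per_cell=tpc)
        if cell is not None:
            tpc = state.clutches.tadpoles_per_cell(landscape.grid.n_cells)


def apply_mortality(state: SimState, landscape: Landscape, params: IbmParams,
                    rng: np.random.Generator) -> SimState:
    """Daily survival draws for every compartment.

    Eggs sharing a cell with tadpoles suffer an additional removal fraction
    (cannibalism/chemical suppression); per-cell tadpole counts above the
    larval carrying capacity are culled proportionally; toads at or beyond
    the desiccation threshold die deterministically.
    """
    pop = state.toads
    n = len(pop)
    if n:
        p = params.stage_mortality()[pop.stage]
        die = rng.random(n) < p
        die |= pop.hydration_loss >= params.desiccation_threshold
        if die.any():
            dead_stages = np.bincount(pop.stage[die], minlength=3)
            state.flows["deaths_metamorph"] += int(dead_stages[STAGE_METAMORPH])
            state.flows["deaths_juvenile"] += int(dead_stages[STAGE_JUVENILE])
            state.flows["deaths_adult"] += int(dead_stages[STAGE_ADULT])
            pop.remove(die)

    cl = state.clutches
    if len(cl):
        n_cells = landscape.grid.n_cells
        tpc = cl.tadpoles_per_cell(n_cells)
        # eggs
        has_eggs = cl.n_eggs > 0
        if has_eggs.any():
            survive = rng.binomial(cl.n_eggs, 1.0 - params.mort_egg)
            shared = tpc[cl.cell] > 0
            cannibal = shared & has_eggs
            if cannibal.any():
                survive[cannibal] = rng.binomial(
                    survive[cannibal], 1.0 - params.egg_cannibalism_frac)
            state.flows["deaths_egg"] += int((cl.n_eggs - survive).sum())
            cl.n_eggs = survive.astype(np.int64)
        # tadpoles: background survival then carrying capacity
        has_tad = cl.n_tadpoles > 0
        if has_tad.any():
            survive = rng.binomial(cl.n_tadpoles, 1.0 - params.mort_tadpole)
            state.flows["deaths_tadpole"] += int((cl.n_tadpoles - survive).sum())
            cl.n_tadpoles = survive.astype(np.int64)
            totals = cl.tadpoles_per_cell(n_cells)
            over = totals > params.tadpole_capacity_per_cell
            if over.any():
                factor = np.ones(n_cells)
                factor[over] = params.tadpole_capacity_per_cell / totals[over]
                capped = np.floor(cl.n_tadpoles * factor[cl.cell]).astype(np.int64)
                state.flows["deaths_tadpole"] += int((cl.n_tadpoles - capped).sum())
                cl.n_tadpoles = capped
        cl.remove((cl.n_eggs == 0) & (cl.n_tadpoles == 0))
    return state


def _aquatic_development(state: SimState, landscape: Landscape,
                         params: IbmParams, rng: np.random.Generator) -> None:
    cl = state.clutches
    if len(cl) == 0:
        return
    # hatching: eggs become tadpoles at the hatching age
    hatch = (cl.age_days >= params.hatch_days) & (cl.n_eggs > 0)
    if hatch.any():
        state.flows["hatched"] += int(cl.n_eggs[hatch].sum())
        cl.n_tadpoles[hatch] += cl.n_eggs[hatch]
        cl.n_eggs[hatch] = 0
    # metamorphosis: tadpoles leave the water as individual metamorphs
    meta = (cl.age_days >= cl.meta_age) & (cl.n_tadpoles > 0)
    if meta.any():
        near_land, _ = landscape.nearest_map("terrestrial")
        total = int(cl.n_tadpoles[meta].sum())
        cells = np.repeat(near_land[cl.cell[meta]], cl.n_tadpoles[meta])
        ids = np.arange(state.next_id, state.next_id + total)
        state.next_id += total
        state.toads.add(
            id=ids,
            sex=(rng.random(total) < 0.5).astype(np.int8),
            stage=np.full(total, STAGE_METAMORPH, dtype=np.int8),
            age_days=np.zeros(total, dtype=np.int32),
            svl_mm=np.full(total, params.metamorph_svl_mm),
            growth_k=params.growth_k * rng.lognormal(0.0, params.growth_k_cv, total),
            hydration_loss=np.zeros(total),
            activity=np.full(total, ACT_INACTIVE, dtype=np.int8),
            cell=cells,
            heading=rng.uniform(0, 2 * math.pi, total),
            has_spawned=np.zeros(total, dtype=bool),
        )
        state.flows["metamorphosed"] += total
        cl.n_tadpoles[meta] = 0
    cl.remove((cl.n_eggs == 0) & (cl.n_tadpoles == 0))


def _hydration_phase(state: SimState, landscape: Landscape, wet: bool,
                     raining: bool, params: IbmParams) -> None:
    pop = state.toads
    if len(pop) == 0:
        return
    if wet or raining:
        pop.hydration_loss[:] = 0.0  # ambient rehydration
        return
    at_water = landscape.is_rehydration_site[pop.cell]
    pop.hydration_loss = np.where(
        at_water, 0.0, pop.hydration_loss + params.daily_water_loss_frac)


def _growth_phase(state: SimState, params: IbmParams) -> None:
    pop = state.toads
    state.clutches.age_days += 1
    if len(pop) == 0:
        return
    pop.age_days += 1
    pop.svl_mm = pop.svl_mm + pop.growth_k * (params.svl_asymptote_mm - pop.svl_mm)
    to_juv = (pop.stage == STAGE_METAMORPH) & (pop.svl_mm >= params.juvenile_svl_mm)
    pop.stage[to_juv] = STAGE_JUVENILE
    state.flows["matured_mj"] += int(to_juv.sum())
    to_adult = (pop.stage == STAGE_JUVENILE) & (pop.svl_mm >= params.adult_svl_mm)
    # metamorphs promoted this step cannot also reach adulthood the same day
    to_adult &= ~to_juv
    pop.stage[to_adult] = STAGE_ADULT
    state.flows["matured_ja"] += int(to_adult.sum())


def step(state: SimState, landscape: Landscape, rainfall: RainfallSeries,
         params: IbmParams, rng: np.random.Generator) -> SimState:
    """Advance the simulation by one day (the fixed phase order above)."""
    day = state.day
    if day > rainfall.n_days:
        raise ValueError(f"rainfall series ends before day {day}")
    wet = rainfall.wet_on(day)
    raining = rainfall.rain_on(day) > 0

    # 1. environment: reset spawning flags at wet-season onset
    if int(day_of_year(day)) == WET_ONSET_DOY and len(state.toads):
        state.toads.has_spawned[:] = False

    _aquatic_development(state, landscape, params, rng)

    state.toads.activity = decide_behaviour(state.toads, landscape, wet,
                                            raining, params, rng)
    disperse(state.toads, np.ones(len(state.toads), dtype=bool), landscape,
             wet, params, rng)
    if wet:
        _spawning_phase(state, landscape, params, rng)
    _hydration_phase(state, landscape, wet, raining, params)
    apply_mortality(state, landscape, params, rng)
    _growth_phase(state, params)

    if state.validate_ledger:
        state.check_ledger()
    state._close_day()
    state.day += 1
    return state


def population_snapshot(state: SimState) -> "pd.DataFrame":
    """Daily snapshot rows ``day, stage, sex, count`` for the export format."""
    import pandas as pd
    pop = state.toads
    rows = []
    for stage, sname in STAGE_NAMES.items():
        for sex, xname in ((SEX_MALE, "male"), (SEX_FEMALE, "female")):
            count = int(((pop.stage == stage) & (pop.sex == sex)).sum())
            rows.append({"day": state.day, "stage": sname, "sex": xname,
                         "count": count})
    return pd.DataFrame(rows)
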