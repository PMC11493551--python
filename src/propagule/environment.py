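"""Hexagonal-grid landscapes and wet–dry rainfall series.

The spatial arena is a pointy-top hexagonal tessellation in odd-row offset
layout: columns are ``spacing_m`` apart, rows ``spacing_m * sqrt(3)/2`` apart,
and odd rows are shifted right by half a column.  Every cell carries one
habitat code; derived layers (water, rehydration sites, breeding margins,
foraging habitat, roads) are pure functions of the habitat vector.

Two synthetic landscape styles are provided:

* ``packed``    — a single contiguous cluster of human-disturbed habitat
  (housing, a permanent waterbody, one road) in a woodland matrix,
  caricaturing a compact township around a port;
* ``fragmented`` — scattered disturbed patches plus several small pit lakes
  in woodland, caricaturing a dispersed mining settlement.

Rainfall follows a tropical savannah regime: a wet season from November to
April, a dry season otherwise, with daily occurrence/amount drawn from a
season-specific Bernoulli × Gamma mixture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SQRT3_2 = math.sqrt(3.0) / 2.0

# habitat codes (integer-coded, stable across file formats)
OCEAN = 0
ROAD = 1
HUMAN_HABITATION = 2
GRASSLAND = 3           # bushland/grassland
WOODLAND = 4
EPHEMERAL_WATER = 5     # ephemeral free-flowing waterbody
NONFLOWING_WATER = 6    # permanent non-flowing waterbody
OTHER = 7

HABITAT_NAMES = {
    OCEAN: "ocean",
    ROAD: "road",
    HUMAN_HABITATION: "human_habitation",
    GRASSLAND: "bushland_grassland",
    WOODLAND: "woodland",
    EPHEMERAL_WATER: "ephemeral_flowing_water",
    NONFLOWING_WATER: "non_flowing_water",
    OTHER: "other",
}
_VALID_CODES = frozenset(HABITAT_NAMES)

# 365-day calendar, day 1 = 1 January (no leap days)
_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_END = np.cumsum(_MONTH_LENGTHS)
WET_MONTHS = frozenset({11, 12, 1, 2, 3, 4})
#: first day-of-year of the wet season (1 November)
WET_ONSET_DOY = int(_MONTH_END[9]) + 1


def day_of_year(day: int | np.ndarray) -> np.ndarray:
    """Map a 1-based simulation day index onto a 1-based day of year."""
    return (np.asarray(day) - 1) % 365 + 1


def month_of_day(day: int | np.ndarray) -> np.ndarray:
    doy = day_of_year(day)
    return np.searchsorted(_MONTH_END, doy, side="left") + 1


def is_wet_season(day: int | np.ndarray):
    """True on calendar wet-season (November–April) days."""
    doy = day_of_year(day)
    return (doy >= WET_ONSET_DOY) | (doy <= int(_MONTH_END[3]))


# ---------------------------------------------------------------------------
# hex grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HexGrid:
    """A rectangular window of a pointy-top hexagonal lattice.

    Cells are addressed ``(col, row)`` 0-based; the flat index is
    ``row * n_cols + col``.  Centre coordinates in metres:
    ``x = (col + 0.5 * (row % 2)) * spacing``, ``y = row * spacing * sqrt(3)/2``.
    """

    width_m: float
    height_m: float
    spacing_m: float = 10.0

    def __post_init__(self):
        if self.spacing_m <= 0:
            raise ValueError(f"spacing_m must be > 0, got {self.spacing_m}")
        if self.width_m < self.spacing_m:
            raise ValueError(
                f"width_m ({self.width_m}) must be at least one spacing ({self.spacing_m})")
        if self.height_m < self.spacing_m * SQRT3_2:
            raise ValueError(
                f"height_m ({self.height_m}) must be at least one row pitch "
                f"({self.spacing_m * SQRT3_2:.3f})")

    @property
    def row_pitch_m(self) -> float:
        return self.spacing_m * SQRT3_2

    @property
    def n_cols(self) -> int:
        return int(math.floor(self.width_m / self.spacing_m))

    @property
    def n_rows(self) -> int:
        return int(math.floor(self.height_m / self.row_pitch_m))

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def cell_area_m2(self) -> float:
        return SQRT3_2 * self.spacing_m ** 2

    # -- indexing -----------------------------------------------------------
    def cell_index(self, col, row):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def col_row(self, idx):
        idx = np.asarray(idx)
        return idx % self.n_cols, idx // self.n_cols

    def centres(self, idx=None):
        """Centre coordinates (x, y) in metres of the given (or all) cells."""
        if idx is None:
            idx = np.arange(self.n_cells)
        col, row = self.col_row(idx)
        x = (col + 0.5 * (row % 2)) * self.spacing_m
        y = row * self.row_pitch_m
        return x, y

    def xy_to_cell(self, x, y):
        """Nearest cell for continuous coordinates (clamped to the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r0 = np.rint(y / self.row_pitch_m).astype(np.int64)
        best_d2 = None
        best = None
        for dr in (-1, 0, 1):
            r = np.clip(r0 + dr, 0, self.n_rows - 1)
            c = np.clip(np.rint(x / self.spacing_m - 0.5 * (r % 2)).astype(np.int64),
                        0, self.n_cols - 1)
            cx = (c + 0.5 * (r % 2)) * self.spacing_m
            cy = r * self.row_pitch_m
            d2 = (cx - x) ** 2 + (cy - y) ** 2
            if best_d2 is None:
                best_d2, best = d2, self.cell_index(c, r)
            else:
                take = d2 < best_d2
                best_d2 = np.where(take, d2, best_d2)
                best = np.where(take, self.cell_index(c, r), best)
        return best

    def neighbours(self, idx) -> np.ndarray:
        """Indices of the up-to-six adjacent cells of one cell."""
        col, row = self.col_row(int(idx))
        if row % 2 == 0:
            offs = [(1, 0), (-1, 0), (0, -1), (-1, -1), (0, 1), (-1, 1)]
        else:
            offs = [(1, 0), (-1, 0), (1, -1), (0, -1), (1, 1), (0, 1)]
        out = []
        for dc, dr in offs:
            c, r = col + dc, row + dr
            if 0 <= c < self.n_cols and 0 <= r < self.n_rows:
                out.append(r * self.n_cols + c)
        return np.array(out, dtype=np.int64)

    def neighbour_matrix(self) -> np.ndarray:
        """(n_cells, 6) neighbour indices, -1 where off-grid. Vectorised."""
        idx = np.arange(self.n_cells)
        col, row = self.col_row(idx)
        odd = (row % 2).astype(bool)
        out = np.full((self.n_cells, 6), -1, dtype=np.int64)
        offs_even = [(1, 0), (-1, 0), (0, -1), (-1, -1), (0, 1), (-1, 1)]
        offs_odd = [(1, 0), (-1, 0), (1, -1), (0, -1), (1, 1), (0, 1)]
        for k in range(6):
            dc = np.where(odd, offs_odd[k][0], offs_even[k][0])
            dr = np.where(odd, offs_odd[k][1], offs_even[k][1])
            c, r = col + dc, row + dr
            ok = (c >= 0) & (c < self.n_cols) & (r >= 0) & (r < self.n_rows)
            out[ok, k] = r[ok] * self.n_cols + c[ok]
        return out


def build_grid(width_m: float, height_m: float, spacing_m: float = 10.0) -> HexGrid:
    """Construct a hex grid covering ``width_m`` × ``height_m`` metres."""
    if width_m <= 0 or height_m <= 0 or spacing_m <= 0:
        raise ValueError("grid dimensions and spacing must all be positive")
    return HexGrid(width_m, height_m, spacing_m)


def label_components(grid: HexGrid, mask: np.ndarray) -> np.ndarray:
    """Connected-component labels (hex adjacency) of a boolean cell mask.

    Returns an int array with -1 outside the mask and labels 0..k-1 inside.
    Frontier-sweep implementation; intended for desk-scale grids.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.n_cells,):
        raise ValueError("mask must have one entry per cell")
    nb = grid.neighbour_matrix()
    labels = np.full(grid.n_cells, -1, dtype=np.int64)
    current = 0
    for seed in np.flatnonzero(mask):
        if labels[seed] != -1:
            continue
        frontier = np.array([seed])
        labels[seed] = current
        while frontier.size:
            cand = nb[frontier].ravel()
            cand = cand[cand >= 0]
            cand = cand[mask[cand] & (labels[cand] == -1)]
            cand = np.unique(cand)
            labels[cand] = current
            frontier = cand
        current += 1
    return labels


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

class Landscape:
    """A habitat map on a hex grid plus derived habitat layers.

    Derived layers are deterministic functions of the habitat vector:

    * water            — ephemeral + non-flowing waterbodies
    * rehydration site — terrestrial water margins and human habitation
    * breeding margin  — terrestrial cells adjacent to water (where breeding
      adults congregate; clutches are laid into the adjacent water cells)
    * foraging         — grassland and human habitation
    """

    def __init__(self, grid: HexGrid, habitat: np.ndarray,
                 entry_points: dict[str, int] | None = None):
        habitat = np.asarray(habitat, dtype=np.int8)
        if habitat.shape != (grid.n_cells,):
            raise ValueError(
                f"habitat vector length {habitat.shape} != cell count {grid.n_cells}")
        bad = set(np.unique(habitat)) - _VALID_CODES
        if bad:
            raise ValueError(f"unknown habitat codes: {sorted(bad)}")
        self.grid = grid
        self.habitat = habitat
        self._nearest_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._layer_cache: dict[str, np.ndarray] = {}
        self._water_tree = None
        self.entry_points = dict(entry_points or {})
        for name, cell in self.entry_points.items():
            if not self.is_terrestrial[cell]:
                raise ValueError(f"entry point {name!r} is not on a terrestrial cell")

    # -- derived layers (habitat-only functions; habitat is immutable, so
    #    each layer is computed once and cached) ---------------------------
    def _layer(self, name: str, fn) -> np.ndarray:
        if name not in self._layer_cache:
            self._layer_cache[name] = fn()
        return self._layer_cache[name]

    @property
    def is_water(self) -> np.ndarray:
        return self._layer("water", lambda: (self.habitat == EPHEMERAL_WATER)
                           | (self.habitat == NONFLOWING_WATER))

    @property
    def is_terrestrial(self) -> np.ndarray:
        return self._layer("terrestrial",
                           lambda: ~(self.is_water | (self.habitat == OCEAN)))

    @property
    def is_road(self) -> np.ndarray:
        return self._layer("road", lambda: self.habitat == ROAD)

    @property
    def is_foraging(self) -> np.ndarray:
        return self._layer("foraging", lambda: (self.habitat == GRASSLAND)
                           | (self.habitat == HUMAN_HABITATION))

    def _adjacent_to_water(self) -> np.ndarray:
        def compute():
            nb = self.grid.neighbour_matrix()
            water = np.concatenate([self.is_water, [False]])  # -1 -> pad slot
            return water[nb].any(axis=1)
        return self._layer("adjacent_to_water", compute)

    @property
    def is_rehydration_site(self) -> np.ndarray:
        return self._layer("rehydration", lambda: (
            (self.is_terrestrial & self._adjacent_to_water())
            | (self.habitat == HUMAN_HABITATION)))

    @property
    def is_breeding_margin(self) -> np.ndarray:
        return self._layer("breeding_margin",
                           lambda: self.is_terrestrial & self._adjacent_to_water())

    @property
    def is_breeding_site(self) -> np.ndarray:
        """Water cells that can receive clutches."""
        return self.is_water

    # -- spatial queries ----------------------------------------------------
    def nearest_map(self, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (nearest target cell, centre distance in m) for a layer.

        ``layer`` is one of ``rehydration``, ``breeding_margin``, ``water``,
        ``terrestrial``.  Computed once per landscape and cached.
        """
        if layer not in self._nearest_cache:
            mask = {
                "rehydration": self.is_rehydration_site,
                "breeding_margin": self.is_breeding_margin,
                "water": self.is_water,
                "terrestrial": self.is_terrestrial,
            }[layer]
            targets = np.flatnonzero(mask)
            if targets.size == 0:
                nearest = np.full(self.grid.n_cells, -1, dtype=np.int64)
                dist = np.full(self.grid.n_cells, np.inf)
            else:
                tx, ty = self.grid.centres(targets)
                tree = cKDTree(np.column_stack([tx, ty]))
                x, y = self.grid.centres()
                dist, j = tree.query(np.column_stack([x, y]), workers=-1)
                nearest = targets[j]
            self._nearest_cache[layer] = (nearest, dist)
        return self._nearest_cache[layer]

    def water_cells_within(self, x: float, y: float, radius_m: float) -> np.ndarray:
        """Water cell indices whose centres lie within ``radius_m`` of (x, y)."""
        if self._water_tree is None:
            self._water_idx = np.flatnonzero(self.is_water)
            wx, wy = self.grid.centres(self._water_idx)
            self._water_tree = cKDTree(np.column_stack([wx, wy])) if self._water_idx.size else None
            if self._water_tree is None:
                return np.array([], dtype=np.int64)
        if self._water_tree is None:
            return np.array([], dtype=np.int64)
        hits = self._water_tree.query_ball_point([x, y], r=radius_m)
        return self._water_idx[np.asarray(hits, dtype=np.int64)]

    def disturbed_mask(self) -> np.ndarray:
        """Human-disturbed footprint: habitation, roads and non-flowing water."""
        return ((self.habitat == HUMAN_HABITATION) | (self.habitat == ROAD)
                | (self.habitat == NONFLOWING_WATER))


def _disk_mask(grid: HexGrid, cx: float, cy: float, radius_m: float) -> np.ndarray:
    x, y = grid.centres()
    return (x - cx) ** 2 + (y - cy) ** 2 <= radius_m ** 2


def generate_landscape(style: str, grid: HexGrid, seed,
                       disturbed_area_km2: float | None = None) -> Landscape:
    """Generate a synthetic landscape of the requested style.

    ``packed`` produces one contiguous disturbed cluster (human habitation
    around a permanent waterbody, crossed by a single road) with a default
    footprint of 4 km²; ``fragmented`` scatters habitation patches and pit
    lakes totalling 9.7 km² by default.  Footprints are capped at 25% of the
    grid so that the generators scale down to smoke-test arenas.  The entry
    point (``site1`` / ``site2``) is placed inside the disturbed area.
    """
    rng = np.random.default_rng(seed)
    if style not in ("packed", "fragmented"):
        raise ValueError(f"unknown landscape style {style!r}")
    default_area = 4.0 if style == "packed" else 9.7
    area_km2 = disturbed_area_km2 if disturbed_area_km2 is not None else default_area
    area_m2 = min(area_km2 * 1e6, 0.25 * grid.n_cells * grid.cell_area_m2)
    if area_m2 < 20 * grid.cell_area_m2:
        raise ValueError("grid too small to host the disturbed cluster")

    habitat = np.full(grid.n_cells, WOODLAND, dtype=np.int8)
    W, H = grid.n_cols * grid.spacing_m, grid.n_rows * grid.row_pitch_m

    if style == "packed":
        radius = math.sqrt(area_m2 / math.pi)
        cx = W / 2 + rng.uniform(-0.02, 0.02) * W
        cy = H / 2 + rng.uniform(-0.02, 0.02) * H
        cluster = _disk_mask(grid, cx, cy, radius)
        habitat[cluster] = HUMAN_HABITATION
        # grassland verge around the township
        verge = _disk_mask(grid, cx, cy, radius * 1.15) & ~cluster
        habitat[verge] = GRASSLAND
        # permanent waterbody inside the cluster
        wx = cx + 0.35 * radius * math.cos(rng.uniform(0, 2 * math.pi))
        wy = cy + 0.35 * radius * math.sin(rng.uniform(0, 2 * math.pi))
        habitat[_disk_mask(grid, wx, wy, 0.22 * radius)] = NONFLOWING_WATER
        # one road crossing the cluster east-west
        x, y = grid.centres()
        road = (np.abs(y - cy) <= grid.row_pitch_m / 2) & (np.abs(x - cx) <= radius * 1.4)
        habitat[road & (habitat != NONFLOWING_WATER)] = ROAD
        entry_name = "site1"
        ex, ey = cx - 0.5 * radius, cy + 0.3 * radius
    else:
        # lakes take ~20% of the footprint, habitation patches the rest;
        # fewer, larger patches are tried when the grid cannot host the
        # default layout, down to the 3 disturbed components that still
        # distinguish the style from "packed"
        centres = None
        for n_patches, n_lakes in ((6, 4), (4, 3), (3, 2)):
            lake_r = math.sqrt(0.20 * area_m2 / n_lakes / math.pi)
            patch_r = math.sqrt(0.80 * area_m2 / n_patches / math.pi)
            min_sep = 2.3 * max(lake_r, patch_r)
            margin = max(lake_r, patch_r) * 1.2
            if W - 2 * margin <= 0 or H - 2 * margin <= 0:
                continue
            for _restart in range(60):  # greedy placement can dead-end
                got: list[tuple[float, float]] = []
                for _ in range(2_000):
                    if len(got) >= n_patches + n_lakes:
                        break
                    px = rng.uniform(margin, W - margin)
                    py = rng.uniform(margin, H - margin)
                    if all((px - qx) ** 2 + (py - qy) ** 2 >= min_sep ** 2
                           for qx, qy in got):
                        got.append((px, py))
                if len(got) >= n_patches + n_lakes:
                    centres = got
                    break
            if centres is not None:
                break
        if centres is None:
            raise ValueError("grid too small to scatter the fragmented patches")
        for i, (px, py) in enumerate(centres[:n_patches]):
            m = _disk_mask(grid, px, py, patch_r)
            habitat[m] = HUMAN_HABITATION
            verge = _disk_mask(grid, px, py, patch_r * 1.2) & ~m
            habitat[verge] = GRASSLAND
        for (px, py) in centres[n_patches:]:
            habitat[_disk_mask(grid, px, py, lake_r)] = NONFLOWING_WATER
        # a short access road inside the entry patch
        ex0, ey0 = centres[0]
        x, y = grid.centres()
        road = (np.abs(y - ey0) <= grid.row_pitch_m / 2) & (np.abs(x - ex0) <= patch_r)
        habitat[road] = ROAD
        entry_name = "site2"
        ex, ey = ex0, ey0 + 0.2 * patch_r

    entry_cell = int(grid.xy_to_cell(ex, ey))
    land = Landscape(grid, habitat)
    if not land.is_terrestrial[entry_cell]:
        terr_near, _ = land.nearest_map("terrestrial")
        entry_cell = int(terr_near[entry_cell])
    land.entry_points[entry_name] = entry_cell
    return land


# ---------------------------------------------------------------------------
# rainfall
# ---------------------------------------------------------------------------

@dataclass
class RainfallSeries:
    """Daily rainfall: 1-based day index, mm/day, running total, season label."""

    rain_mm: np.ndarray
    season: np.ndarray = field(default=None)  # "wet"/"dry" per day

    def __post_init__(self):
        self.rain_mm = np.asarray(self.rain_mm, dtype=float)
        if self.season is None:
            self.season = np.where(is_wet_season(self.day), "wet", "dry")
        self.season = np.asarray(self.season)
        if np.any(self.rain_mm < 0):
            raise ValueError("rain_mm must be non-negative")
        if self.season.shape != self.rain_mm.shape:
            raise ValueError("season and rain_mm must be the same length")

    @property
    def n_days(self) -> int:
        return len(self.rain_mm)

    @property
    def day(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)

    @property
    def cum_mm(self) -> np.ndarray:
        return np.cumsum(self.rain_mm)

    def rain_on(self, day: int) -> float:
        return float(self.rain_mm[day - 1])

    def wet_on(self, day: int) -> bool:
        return self.season[day - 1] == "wet"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.day, "rain_mm": self.rain_mm,
                             "cum_mm": self.cum_mm, "season": self.season})


def generate_rainfall(n_days: int, seed, p_rain_wet: float = 0.55,
                      p_rain_dry: float = 0.05, mean_mm_wet: float = 12.0,
                      mean_mm_dry: float = 2.0) -> RainfallSeries:
    """Bernoulli wet-day × Gamma amount rainfall with Nov–Apr wet season.

    On each day rain falls with the season's probability; amounts are drawn
    from a Gamma(shape 2) with the season's mean, giving the positive skew of
    tropical daily totals.  Expected daily rain is ``p_rain * mean_mm``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    for name, p in (("p_rain_wet", p_rain_wet), ("p_rain_dry", p_rain_dry)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    days = np.arange(1, n_days + 1)
    wet = is_wet_season(days)
    p = np.where(wet, p_rain_wet, p_rain_dry)
    mean = np.where(wet, mean_mm_wet, mean_mm_dry)
    rains = rng.random(n_days) < p
    amounts = rng.gamma(shape=2.0, scale=np.maximum(mean, 1e-12) / 2.0)
    rain_mm = np.where(rains, amounts, 0.0)
    return RainfallSeries(rain_mm=rain_mm, season=np.where(wet, "wet", "dry"))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_landscape(land: Landscape, path) -> None:
    """Write a landscape as ESRI ASCII grid (``.asc``) or long CSV."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        g = land.grid
        rows = land.habitat.reshape(g.n_rows, g.n_cols)
        with open(path, "w") as fh:
            fh.write(f"ncols {g.n_cols}\n")
            fh.write(f"nrows {g.n_rows}\n")
            fh.write("xllcorner 0\n")
            fh.write("yllcorner 0\n")
            fh.write(f"cellsize {g.spacing_m:g}\n")
            fh.write("NODATA_value -9999\n")
            # ESRI convention: first data row is the northernmost (last) row
            for r in range(g.n_rows - 1, -1, -1):
                fh.write(" ".join(map(str, rows[r])) + "\n")
    else:
        g = land.grid
        col, row = g.col_row(np.arange(g.n_cells))
        with open(path, "w") as fh:
            fh.write("# habitat codes: " + ", ".join(
                f"{k}={v}" for k, v in HABITAT_NAMES.items()) + "\n")
            fh.write(f"# spacing_m={g.spacing_m:g} n_cols={g.n_cols} n_rows={g.n_rows}\n")
            for name, cell in land.entry_points.items():
                fh.write(f"# entry {name} {cell}\n")
            fh.write("col,row,habitat\n")
            for c, r, h in zip(col, row, land.habitat):
                fh.write(f"{c},{r},{h}\n")


def read_landscape(path, spacing_m: float | None = None) -> Landscape:
    """Read a landscape written by :func:`write_landscape` (either format)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.strip().lower().startswith("ncols"):
        return _read_ascii_grid(path)
    return _read_long_csv(path, spacing_m)


def _read_ascii_grid(path) -> Landscape:
    header = {}
    data_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if toks[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                   "cellsize", "nodata_value"):
                header[toks[0].lower()] = float(toks[1])
                continue
            try:
                vals = [int(t) for t in toks]
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer habitat code")
            data_rows.append((lineno, vals))
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    spacing = header["cellsize"]
    if len(data_rows) != nrows:
        raise ValueError(f"{path}: expected {nrows} data rows, found {len(data_rows)}")
    habitat = np.empty((nrows, ncols), dtype=np.int8)
    for i, (lineno, vals) in enumerate(data_rows):
        if len(vals) != ncols:
            raise ValueError(f"{path} line {lineno}: ragged row "
                             f"({len(vals)} values, expected {ncols})")
        bad = [v for v in vals if v not in _VALID_CODES]
        if bad:
            raise ValueError(f"{path} line {lineno}: unknown habitat code {bad[0]}")
        habitat[nrows - 1 - i] = vals  # undo north-first ordering
    grid = HexGrid(ncols * spacing, (nrows + 0.5) * spacing * SQRT3_2, spacing)
    assert grid.n_cols == ncols and grid.n_rows == nrows
    return Landscape(grid, habitat.ravel())


def _read_long_csv(path, spacing_m: float | None) -> Landscape:
    meta_spacing = None
    entries: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                for t in toks:
                    if t.startswith("spacing_m="):
                        meta_spacing = float(t.split("=")[1])
                if toks and toks[0] == "entry":
                    entries[toks[1]] = int(toks[2])
                continue
            if line.lower().startswith("col,"):
                continue
            toks = line.split(",")
            if len(toks) != 3:
                raise ValueError(f"{path} line {lineno}: expected col,row,habitat")
            try:
                c, r, h = int(toks[0]), int(toks[1]), int(toks[2])
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer field")
            if h not in _VALID_CODES:
                raise ValueError(f"{path} line {lineno}: unknown habitat code {h}")
            rows.append((c, r, h))
    if not rows:
        raise ValueError(f"{path}: no habitat rows")
    spacing = spacing_m or meta_spacing or 10.0
    arr = np.asarray(rows, dtype=np.int64)
    ncols, nrows = int(arr[:, 0].max()) + 1, int(arr[:, 1].max()) + 1
    if len(rows) != ncols * nrows:
        raise ValueError(f"{path}: expected {ncols * nrows} rows for a "
                         f"{ncols}x{nrows} grid, found {len(rows)}")
    habitat = np.empty(ncols * nrows, dtype=np.int8)
    habitat[arr[:, 1] * ncols + arr[:, 0]] = arr[:, 2]
    grid = HexGrid(ncols * spacing, (nrows + 0.5) * spacing * SQRT3_2, spacing)
    assert grid.n_cols == ncols and grid.n_rows == nrows
    return Landscape(grid, habitat, entries)


def write_rainfall(series: RainfallSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_rainfall(path) -> RainfallSeries:
    df = pd.read_csv(path)
    for colname in ("day", "rain_mm", "cum_mm", "season"):
        if colname not in df.columns:
            raise ValueError(f"{path}: missing column {colname!r}")
    cum = df["cum_mm"].to_numpy(float)
    dec = np.flatnonzero(np.diff(cum) < -1e-9)
    if dec.size:
        day = int(df["day"].iloc[dec[0] + 1])
        raise ValueError(f"{path}: cumulative rainfall decreases at day {day}")
    return RainfallSeries(rain_mm=df["rain_mm"].to_numpy(float),
                          season=df["season"].to_numpy())


def landscape_entry_sidecar(land: Landscape, path) -> None:
    Path(path).write_text(json.dumps(land.entry_points))
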