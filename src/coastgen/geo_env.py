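"""Geographic distances and sea-surface-temperature climatology.

Three between-site distances are used as isolation-by-distance predictors:

* great-circle distance ``D_gcc`` (haversine on a sphere of radius
  6371.393 km),
* coastline distance ``D_csl`` (shortest 8-connected path through the
  water cells of a rasterized coastal strip — fish cannot cross
  peninsulas, so this can greatly exceed ``D_gcc``),
* meridional distance ``D_lat`` (north-south arc length).

The isolation-by-environment predictors are absolute differences in
per-site SST climatology: the mean annual maximum, mean annual minimum
and overall median of a multi-year daily SST series.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.393

__all__ = [
    "SiteGeo",
    "CoastGrid",
    "SiteEnv",
    "great_circle",
    "latitude_distance",
    "coastline_distance",
    "sst_climatology",
    "pair_predictors",
    "read_sites_tsv",
    "read_sst_csv",
]


@dataclass(frozen=True)
class SiteGeo:
    """A sampling site with decimal-degree coordinates."""

    site_id: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (abs(self.lat) <= 90 and abs(self.lon) <= 180):
            raise ValueError(f"invalid coordinates for site {self.site_id}")


class CoastGrid:
    """Raster of water (True) / land (False) cells in a projected plane.

    Parameters
    ----------
    water
        2-D boolean array; ``water[i, j]`` is True where a path may pass.
    cell_km
        Edge length of a (square) cell in km. Default 0.1 km.
    origin
        Planar (x, y) coordinate of cell (0, 0)'s centre, in km.
    site_cells
        Mapping site_id -> (row, col) of the water cell the site snaps to.
    """

    def __init__(
        self,
        water: np.ndarray,
        cell_km: float = 0.1,
        origin: tuple[float, float] = (0.0, 0.0),
        site_cells: dict[str, tuple[int, int]] | None = None,
    ) -> None:
        self.water = np.asarray(water, dtype=bool)
        if self.water.ndim != 2:
            raise ValueError("water raster must be 2-D")
        self.cell_km = float(cell_km)
        self.origin = origin
        self.site_cells = dict(site_cells or {})
        for sid, (r, c) in self.site_cells.items():
            if not self.water[r, c]:
                raise ValueError(f"site {sid} snaps to a land cell ({r}, {c})")

    def to_ascii(self, path: str) -> None:
        """Write the raster as an ASCII grid ('.' water, 'X' land) with a header."""
        with open(path, "w") as fh:
            fh.write(f"# cell_km={self.cell_km}\n")
            for sid, (r, c) in sorted(self.site_cells.items()):
                fh.write(f"# site {sid} {r} {c}\n")
            for row in self.water:
                fh.write("".join("." if w else "X" for w in row) + "\n")

    @classmethod
    def from_ascii(cls, path: str) -> "CoastGrid":
        cell_km = 0.1
        site_cells: dict[str, tuple[int, int]] = {}
        rows: list[list[bool]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# cell_km="):
                    cell_km = float(line.split("=", 1)[1])
                elif line.startswith("# site "):
                    _, _, sid, r, c = line.split()
                    site_cells[sid] = (int(r), int(c))
                elif line and not line.startswith("#"):
                    rows.append([ch == "." for ch in line])
        return cls(np.array(rows, dtype=bool), cell_km=cell_km, site_cells=site_cells)


@dataclass(frozen=True)
class SiteEnv:
    """Per-site SST climatology summaries (degrees C)."""

    site_id: str
    sst_max: float
    sst_min: float
    sst_med: float

    def __post_init__(self) -> None:
        if not (self.sst_min <= self.sst_med <= self.sst_max):
            raise ValueError(
                f"site {self.site_id}: require sst_min <= sst_med <= sst_max"
            )


def great_circle(a: SiteGeo, b: SiteGeo, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Haversine great-circle distance in km.

    D = 2R * arcsin sqrt(sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlambda/2))
    """
    phi1, phi2 = np.radians(a.lat), np.radians(b.lat)
    dphi = phi2 - phi1
    dlam = np.radians(b.lon - a.lon)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def latitude_distance(a: SiteGeo, b: SiteGeo, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Meridional (north-south) arc length in km: 2*pi*R*|dlat|/360."""
    return float(2.0 * np.pi * radius_km * abs(a.lat - b.lat) / 360.0)


def coastline_distance(a: SiteGeo | str, b: SiteGeo | str, grid: CoastGrid) -> float:
    """Shortest 8-connected water path between two sites, in km.

    Axial steps cost one cell edge, diagonal steps sqrt(2) edges.  Raises
    ``ValueError`` if the water region does not connect the sites.
    """
    sid_a = a if isinstance(a, str) else a.site_id
    sid_b = b if isinstance(b, str) else b.site_id
    try:
        start = grid.site_cells[sid_a]
        goal = grid.site_cells[sid_b]
    except KeyError as exc:
        raise ValueError(f"site {exc.args[0]} not registered on the coast grid")
    if start == goal:
        return 0.0
    dist = _dijkstra(grid.water, start, goal)
    if not np.isfinite(dist):
        raise ValueError(f"sites not connected: {sid_a} and {sid_b}")
    return dist * grid.cell_km


_SQRT2 = float(np.sqrt(2.0))
_MOVES = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
          (-1, -1, _SQRT2), (-1, 1, _SQRT2), (1, -1, _SQRT2), (1, 1, _SQRT2)]


def _dijkstra(water: np.ndarray, start: tuple[int, int], goal: tuple[int, int]) -> float:
    nr, nc = water.shape
    dist = np.full((nr, nc), np.inf)
    dist[start] = 0.0
    heap = [(0.0, start)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if (r, c) == goal:
            return d
        if d > dist[r, c]:
            continue
        for dr, dc, w in _MOVES:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and water[r2, c2]:
                nd = d + w
                if nd < dist[r2, c2]:
                    dist[r2, c2] = nd
                    heapq.heappush(heap, (nd, (r2, c2)))
    return np.inf


def sst_climatology(
    site_id: str,
    dates: pd.DatetimeIndex | np.ndarray,
    values: np.ndarray,
    annual_extremes: str = "mean",
) -> SiteEnv:
    """Summarise a daily SST series into (SST_max, SST_min, SST_med).

    SST_max / SST_min are the mean over calendar years of each year's
    maximum / minimum daily value (``annual_extremes="mean"``, the
    default) or the overall extremes (``"overall"``).  SST_med is the
    median of all daily values.  The series must span at least one full
    year with no gap longer than 30 days.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) != len(values):
        raise ValueError("dates and values length mismatch")
    order = np.argsort(dates.values)
    dates, values = dates[order], values[order]
    if (dates[-1] - dates[0]).days < 364:
        raise ValueError(f"site {site_id}: SST series shorter than one year")
    gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if len(gaps) and gaps.max() > 30:
        raise ValueError(f"site {site_id}: gap of {gaps.max()} days in SST series")
    ser = pd.Series(values, index=dates)
    if annual_extremes == "mean":
        by_year = ser.groupby(ser.index.year)
        # partial edge years would bias annual extremes; keep years with >300 days
        full = by_year.count() > 300
        years = full[full].index
        if len(years) == 0:
            years = by_year.count().index
        sst_max = float(by_year.max()[years].mean())
        sst_min = float(by_year.min()[years].mean())
    elif annual_extremes == "overall":
        sst_max = float(ser.max())
        sst_min = float(ser.min())
    else:
        raise ValueError("annual_extremes must be 'mean' or 'overall'")
    return SiteEnv(site_id, sst_max=sst_max, sst_min=sst_min, sst_med=float(ser.median()))


def pair_predictors(
    sites: list[SiteGeo],
    envs: list[SiteEnv],
    grid: CoastGrid | None = None,
) -> pd.DataFrame:
    """Build the site-pair predictor table.

    One row per unordered site pair with columns ``site_a, site_b, D_gcc,
    D_csl, D_lat, dSST_max, dSST_min, dSST_med``.  ``D_csl`` is omitted
    when no coast grid is supplied.
    """
    env_by_id = {e.site_id: e for e in envs}
    for s in sites:
        if s.site_id not in env_by_id:
            raise ValueError(f"missing SST climatology for site {s.site_id}")
    rows = []
    for a, b in combinations(sites, 2):
        ea, eb = env_by_id[a.site_id], env_by_id[b.site_id]
        row = {
            "site_a": a.site_id,
            "site_b": b.site_id,
            "D_gcc": great_circle(a, b),
            "D_lat": latitude_distance(a, b),
            "dSST_max": abs(ea.sst_max - eb.sst_max),
            "dSST_min": abs(ea.sst_min - eb.sst_min),
            "dSST_med": abs(ea.sst_med - eb.sst_med),
        }
        if grid is not None:
            row["D_csl"] = coastline_distance(a, b, grid)
        rows.append(row)
    cols = ["site_a", "site_b", "D_gcc", "D_csl", "D_lat",
            "dSST_max", "dSST_min", "dSST_med"]
    if grid is None:
        cols.remove("D_csl")
    return pd.DataFrame(rows, columns=cols)


def read_sites_tsv(path: str) -> list[SiteGeo]:
    """Read a site table (columns: site, lat, lon)."""
    df = pd.read_csv(path, sep="\t")
    return [SiteGeo(str(r.site), float(r.lat), float(r.lon)) for r in df.itertuples()]


def read_sst_csv(path: str) -> dict[str, pd.Series]:
    """Read per-site daily SST series from a CSV with columns date, <site>..."""
    df = pd.read_csv(path, parse_dates=["date"])
    df = df.set_index("date")
    return {c: df[c] for c in df.columns}
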