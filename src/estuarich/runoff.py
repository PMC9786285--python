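"""Curve-number runoff covariates.

Converts watershed land-cover/soil composition plus a daily precipitation
series into per-estuary mean annual runoff volume for each aggregated
land-cover group, normalized by watershed area (m^3/km^2/yr).  These are
the six estuary-level covariates consumed downstream.

The runoff primitive is the standard SCS/NRCS (TR-55) event method:

    S  = 1000/CN - 10        (potential retention, inches)
    Ia = 0.2 * S             (initial abstraction)
    Q  = (P - Ia)^2 / (P - Ia + S)   for P > Ia, else 0

computed at a daily time step with no antecedent-moisture adjustment,
routing, evapotranspiration, or groundwater terms.  Internal arithmetic is
in US customary units (inches), with mm <-> inch conversion at the
boundary and output volumes in m^3.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LULC_GROUPS",
    "SOIL_GROUPS",
    "CCAP_TO_GROUP",
    "CurveNumberTable",
    "WatershedComposition",
    "PrecipSeries",
    "RunoffByClass",
    "aggregate_ccap",
    "potential_retention",
    "event_runoff",
    "annual_runoff_by_class",
    "load_composition_csv",
    "load_precip_csv",
    "composition_from_grids",
]

MM_PER_INCH = 25.4

#: Aggregated land-cover groups, in covariate order (X3..X8).
LULC_GROUPS = (
    "developed",
    "cropland",
    "forest",
    "palustrine_wetland",
    "estuarine_wetland",
    "barren",
)

SOIL_GROUPS = ("A", "B", "C", "D")

#: C-CAP integer class -> aggregated group.  Codes absent here are
#: deliberately excluded and drop out of the covariates.
CCAP_TO_GROUP = {
    2: "developed",
    3: "developed",
    4: "developed",
    5: "developed",
    6: "cropland",
    9: "forest",
    10: "forest",
    11: "forest",
    13: "palustrine_wetland",
    14: "palustrine_wetland",
    15: "palustrine_wetland",
    16: "estuarine_wetland",
    17: "estuarine_wetland",
    18: "estuarine_wetland",
    20: "barren",
}

WETLAND_GROUPS = frozenset({"palustrine_wetland", "estuarine_wetland"})


def aggregate_ccap(ccap_code: int) -> str | None:
    """Map a C-CAP integer class code to its aggregated land-cover group.

    Returns ``None`` for codes that are not part of any covariate group
    (water, grassland, pasture, etc.); such cells contribute no runoff
    covariate by design.
    """
    return CCAP_TO_GROUP.get(int(ccap_code))


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete curve-number configuration."""


@dataclass(frozen=True)
class CurveNumberTable:
    """Curve numbers keyed by (land-cover group, hydrologic soil group)."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for group in LULC_GROUPS:
            for soil in SOIL_GROUPS:
                key = (group, soil)
                if key not in self.entries:
                    raise ConfigurationError(f"missing curve number for {key}")
                cn = self.entries[key]
                if not (30.0 <= cn <= 100.0):
                    raise ConfigurationError(
                        f"curve number {cn} for {key} outside [30, 100]"
                    )
                if group in WETLAND_GROUPS and cn != 100.0:
                    raise ConfigurationError(
                        f"wetland group {key} must carry CN=100, got {cn}"
                    )

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.entries[key]

    @classmethod
    def default(cls) -> "CurveNumberTable":
        """Packaged default table (wetlands overridden to CN=100)."""
        path = importlib.resources.files("estuarich.assets") / "cn_table.csv"
        with importlib.resources.as_file(path) as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path) -> "CurveNumberTable":
        df = pd.read_csv(path)
        entries = {
            (str(r.lulc_group), str(r.soil_group)): float(r.cn)
            for r in df.itertuples()
        }
        return cls(entries)


@dataclass
class WatershedComposition:
    """Land-cover x soil-group area breakdown for one estuary watershed.

    ``rows`` is a DataFrame with columns ``ccap_code``, ``soil_group``,
    ``area_m2``.  ``watershed_area_km2`` is the full (possibly partially
    unclassified) watershed area used for normalization.
    """

    estuary_id: str
    rows: pd.DataFrame
    watershed_area_km2: float

    def __post_init__(self) -> None:
        if self.watershed_area_km2 <= 0:
            raise ValueError("watershed_area_km2 must be positive")
        if (self.rows["area_m2"] < 0).any():
            raise ValueError("class areas must be non-negative")
        total = float(self.rows["area_m2"].sum())
        if total > self.watershed_area_km2 * 1e6 * (1 + 1e-9):
            raise ValueError(
                "classified area exceeds watershed area "
                f"({total:.3g} m2 > {self.watershed_area_km2} km2)"
            )

    def area_by_group_soil(self) -> dict[tuple[str, str], float]:
        """Aggregate row areas to (lulc_group, soil_group), dropping
        unmapped C-CAP codes."""
        out: dict[tuple[str, str], float] = {}
        for r in self.rows.itertuples():
            group = aggregate_ccap(r.ccap_code)
            if group is None:
                continue
            key = (group, str(r.soil_group))
            out[key] = out.get(key, 0.0) + float(r.area_m2)
        return out


@dataclass
class PrecipSeries:
    """Daily precipitation depths (mm/day) for one watershed."""

    estuary_id: str
    dates: pd.DatetimeIndex
    depths_mm: np.ndarray

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        if len(self.dates) != len(self.depths_mm):
            raise ValueError("dates and depths length mismatch")
        if (self.depths_mm < 0).any():
            raise ValueError("precipitation depths must be non-negative")

    def complete_years(self) -> list[int]:
        """Calendar years for which every day is present in the series."""
        s = pd.Series(self.depths_mm, index=self.dates)
        years = []
        for year, chunk in s.groupby(s.index.year):
            n_expected = pd.Timestamp(year=year, month=12, day=31).dayofyear
            if chunk.index.normalize().nunique() == n_expected:
                years.append(int(year))
        return years


@dataclass
class RunoffByClass:
    """Mean annual runoff volume per land-cover group, normalized by
    watershed area (m^3/km^2/yr)."""

    estuary_id: str
    values: dict[str, float] = field(default_factory=dict)

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[g] for g in LULC_GROUPS])


def potential_retention(curve_number: float) -> float:
    """Potential maximum retention S (inches) for a curve number."""
    cn = float(curve_number)
    if not (0.0 < cn <= 100.0):
        raise ValueError(f"curve number must be in (0, 100], got {cn}")
    return 1000.0 / cn - 10.0


def event_runoff(precip_depth, curve_number: float):
    """Event runoff depth Q (inches) for precipitation P (inches).

    Accepts scalar or array ``precip_depth``; vectorized over days.
    """
    p = np.asarray(precip_depth, dtype=float)
    if (p < 0).any():
        raise ValueError("precipitation depth must be non-negative")
    s = potential_retention(curve_number)
    ia = 0.2 * s
    excess = p - ia
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(excess > 0, excess**2 / (excess + s), 0.0)
    if np.ndim(precip_depth) == 0:
        return float(q)
    return q


def annual_runoff_by_class(
    comp: WatershedComposition,
    precip: PrecipSeries,
    cn: CurveNumberTable | None = None,
) -> RunoffByClass:
    """Mean annual runoff volume per land-cover group for one watershed.

    For each group g:  V_g = (1/Y) * sum over complete years of
    sum_days sum_soil Q(P_day, CN(g, s)) * area(g, s), converted to m^3
    and divided by watershed area in km^2.
    """
    if cn is None:
        cn = CurveNumberTable.default()
    years = precip.complete_years()
    if not years:
        raise ValueError(
            f"precipitation series for {precip.estuary_id} covers no complete year"
        )
    mask = np.isin(precip.dates.year, years)
    p_inch = precip.depths_mm[mask] / MM_PER_INCH

    areas = comp.area_by_group_soil()
    values = {g: 0.0 for g in LULC_GROUPS}
    for (group, soil), area_m2 in areas.items():
        if (group, soil) not in cn.entries:
            raise ConfigurationError(f"no curve number for {(group, soil)}")
        if area_m2 == 0.0:
            continue
        q_inch = event_runoff(p_inch, cn[(group, soil)])
        depth_m = q_inch.sum() * (MM_PER_INCH / 1000.0)
        values[group] += depth_m * area_m2  # m^3 over all complete years
    n_years = len(years)
    norm = comp.watershed_area_km2 * n_years
    return RunoffByClass(
        estuary_id=comp.estuary_id,
        values={g: v / norm for g, v in values.items()},
    )


def load_composition_csv(
    composition_path, watershed_path=None
) -> list[WatershedComposition]:
    """Load watershed compositions from CSV.

    The composition CSV has columns ``estuary_id, ccap_code, soil_group,
    area_m2`` and either a ``watershed_area_km2`` column or a companion
    watershed CSV (``estuary_id, watershed_area_km2``).
    """
    df = pd.read_csv(composition_path)
    if watershed_path is not None:
        wdf = pd.read_csv(watershed_path).set_index("estuary_id")
        area_of = wdf["watershed_area_km2"].to_dict()
    elif "watershed_area_km2" in df.columns:
        area_of = (
            df.groupby("estuary_id")["watershed_area_km2"].first().to_dict()
        )
    else:
        raise ValueError(
            "watershed area missing: provide a watershed CSV or a "
            "watershed_area_km2 column"
        )
    out = []
    for estuary_id, chunk in df.groupby("estuary_id", sort=True):
        rows = chunk[["ccap_code", "soil_group", "area_m2"]].reset_index(drop=True)
        out.append(
            WatershedComposition(
                estuary_id=str(estuary_id),
                rows=rows,
                watershed_area_km2=float(area_of[estuary_id]),
            )
        )
    return out


def load_precip_csv(path) -> list[PrecipSeries]:
    """Load daily precipitation series: columns estuary_id, date, precip_mm."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for estuary_id, chunk in df.groupby("estuary_id", sort=True):
        chunk = chunk.sort_values("date")
        out.append(
            PrecipSeries(
                estuary_id=str(estuary_id),
                dates=pd.DatetimeIndex(chunk["date"]),
                depths_mm=chunk["precip_mm"].to_numpy(dtype=float),
            )
        )
    return out


def composition_from_grids(
    estuary_id: str,
    ccap_grid,
    soil_grid,
    cell_area_m2: float,
    watershed_area_km2: float | None = None,
) -> WatershedComposition:
    """Tabulate a raster pair (C-CAP codes, soil groups) into a
    WatershedComposition.

    ``ccap_grid`` holds integer class codes, ``soil_grid`` holds soil-group
    letters (or empty string / "-" for no-data).  Both grids must share a
    shape; each cell contributes ``cell_area_m2``.  When
    ``watershed_area_km2`` is omitted it defaults to the full grid extent.
    """
    ccap = np.asarray(ccap_grid)
    soil = np.asarray(soil_grid, dtype=object)
    if ccap.shape != soil.shape:
        raise ValueError("ccap and soil grids must share a shape")
    records: dict[tuple[int, str], int] = {}
    for code, sg in zip(ccap.ravel(), soil.ravel()):
        sg = str(sg)
        if sg not in SOIL_GROUPS:
            continue
        key = (int(code), sg)
        records[key] = records.get(key, 0) + 1
    rows = pd.DataFrame(
        [
            {"ccap_code": code, "soil_group": sg, "area_m2": n * cell_area_m2}
            for (code, sg), n in sorted(records.items())
        ],
        columns=["ccap_code", "soil_group", "area_m2"],
    )
    if watershed_area_km2 is None:
        watershed_area_km2 = ccap.size * cell_area_m2 / 1e6
    return WatershedComposition(
        estuary_id=estuary_id, rows=rows, watershed_area_km2=watershed_area_km2
    )


def runoff_table(runoffs: list[RunoffByClass]) -> pd.DataFrame:
    """Stack per-estuary runoff covariates into a tidy DataFrame."""
    recs = []
    for r in runoffs:
        rec = {"estuary_id": r.estuary_id}
        rec.update({g: r.values[g] for g in LULC_GROUPS})
        recs.append(rec)
    return pd.DataFrame(recs)
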