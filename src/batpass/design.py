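"""Fixed- and random-effect design construction for nightly pass counts.

The activity models regress nightly pass counts on distance from the road
(treatment-coded against the 300 m control), centered daily maximum
temperature, site, year and presence of a light within 100 m (all
sum-coded), plus distance x temperature and distance x site interactions:
14 fixed-effect columns in total.  Night and transect enter as crossed
random intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_COLUMNS",
    "Design",
    "ModelSpec",
    "NightRecord",
    "SITE_CODES",
    "build_design",
    "records_frame",
]

#: Canonical column order of the full fixed-effects matrix.
DESIGN_COLUMNS: tuple[str, ...] = (
    "intercept",
    "dist_road_100",
    "dist_road_0",
    "temp_max",
    "dist_road_100:temp_max",
    "dist_road_0:temp_max",
    "site1",
    "site2",
    "dist_road_100:site1",
    "dist_road_0:site1",
    "dist_road_100:site2",
    "dist_road_0:site2",
    "year",
    "light",
)

#: Sum-contrast coding of the three study sites: adding site1 gives San
#: Pablo Bay, adding site2 gives Don Edwards, subtracting both gives
#: Hayward Shoreline.
SITE_CODES: dict[str, tuple[float, float]] = {
    "SAPA": (1.0, 0.0),
    "DOED": (0.0, 1.0),
    "HAYW": (-1.0, -1.0),
}

#: Sum-contrast coding of year: 2010 adds the coefficient, 2011 subtracts.
YEAR_CODES: dict[int, float] = {2010: 1.0, 2011: -1.0}

DIST_LEVELS = (0, 100, 300)


@dataclass
class NightRecord:
    """One detector-night: design covariates plus the nightly pass count."""

    site: str
    transect: str
    dist_road: int          # metres: 0, 100 or 300
    night_id: str           # calendar-night identifier (shared across points)
    year: int
    temp_max: float         # daily maximum temperature, degrees C
    light_100: bool
    count: int = 0
    species: str = "all"

    def __post_init__(self) -> None:
        if self.dist_road not in DIST_LEVELS:
            raise ValueError(f"dist_road must be one of {DIST_LEVELS}")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError("count must be a non-negative integer")


def records_frame(records) -> pd.DataFrame:
    """Coerce a list of NightRecord (or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class ModelSpec:
    """Model formula settings (contrast conventions are fixed by design)."""

    response: str = "all"
    temp_center_c: float = 24.0
    family: str = "nb1"               # "poisson" or "nb1"
    columns: tuple[str, ...] = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "nb1"):
            raise ValueError("family must be 'poisson' or 'nb1'")
        unknown = set(self.columns) - set(DESIGN_COLUMNS)
        if unknown:
            raise ValueError(f"unknown design columns: {sorted(unknown)}")


@dataclass
class Design:
    """A realized design: fixed-effect matrix plus random-effect maps."""

    X: np.ndarray
    columns: tuple[str, ...]
    y: np.ndarray | None
    night_index: np.ndarray
    transect_index: np.ndarray
    night_levels: tuple[str, ...]
    transect_levels: tuple[str, ...]
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_nights(self) -> int:
        return len(self.night_levels)

    @property
    def n_transects(self) -> int:
        return len(self.transect_levels)

    def subset(self, columns: tuple[str, ...]) -> "Design":
        """Restrict to a subset of fixed-effect columns (for nested models)."""
        missing = set(columns) - set(self.columns)
        if missing:
            raise ValueError(f"columns not in design: {sorted(missing)}")
        idx = [self.columns.index(c) for c in columns]
        return Design(
            X=self.X[:, idx],
            columns=tuple(columns),
            y=self.y,
            night_index=self.night_index,
            transect_index=self.transect_index,
            night_levels=self.night_levels,
            transect_levels=self.transect_levels,
            spec=self.spec,
        )


def _full_matrix(df: pd.DataFrame, temp_center: float) -> np.ndarray:
    n = len(df)
    d100 = (df["dist_road"].to_numpy() == 100).astype(float)
    d0 = (df["dist_road"].to_numpy() == 0).astype(float)
    bad = set(df["dist_road"]) - set(DIST_LEVELS)
    if bad:
        raise ValueError(f"unseen dist_road levels: {sorted(bad)}")
    try:
        site12 = np.array([SITE_CODES[s] for s in df["site"]])
    except KeyError as e:
        raise ValueError(f"unseen site level: {e.args[0]!r}") from None
    try:
        year = np.array([YEAR_CODES[int(y)] for y in df["year"]])
    except KeyError as e:
        raise ValueError(f"unseen year level: {e.args[0]!r}") from None
    # light sum contrast: unlit points add the coefficient, lit subtract
    light = np.where(df["light_100"].to_numpy().astype(bool), -1.0, 1.0)
    temp = df["temp_max"].to_numpy(dtype=float) - temp_center
    s1, s2 = site12[:, 0], site12[:, 1]
    cols = [
        np.ones(n),
        d100,
        d0,
        temp,
        d100 * temp,
        d0 * temp,
        s1,
        s2,
        d100 * s1,
        d0 * s1,
        d100 * s2,
        d0 * s2,
        year,
        light,
    ]
    return np.column_stack(cols)


def build_design(records, spec: ModelSpec | None = None) -> Design:
    """Build the fixed-effects matrix and night/transect indicator maps.

    ``records`` is a list of :class:`NightRecord` or an equivalent
    DataFrame.  The full spec yields exactly 14 columns in the canonical
    order; ``spec.columns`` may select a subset for reduced (nested) models.
    """
    spec = spec or ModelSpec()
    df = records_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    X_full = _full_matrix(df, spec.temp_center_c)
    idx = [DESIGN_COLUMNS.index(c) for c in spec.columns]
    X = X_full[:, idx]

    night_levels = tuple(pd.unique(df["night_id"]))
    transect_levels = tuple(pd.unique(df["transect"]))
    night_index = np.array([night_levels.index(v) for v in df["night_id"]])
    transect_index = np.array(
        [transect_levels.index(v) for v in df["transect"]]
    )
    y = None
    if "count" in df.columns and df["count"].notna().all():
        y = df["count"].to_numpy(dtype=float)
    return Design(
        X=X,
        columns=tuple(spec.columns),
        y=y,
        night_index=night_index,
        transect_index=transect_index,
        night_levels=night_levels,
        transect_levels=transect_levels,
        spec=spec,
    )
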