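"""Scenario configuration for the synthetic Mediterranean test bed.

Every input the indicator pipeline consumes is produced from a single
:class:`ScenarioConfig`, so a config plus its ``seed`` fully determines every
downstream indicator, trend symbol and sustainability flag.  The geography is
deliberately stylised: a regular lon/lat grid with an explicit per-cell area,
a land strip along the northern rows standing in for the Euro-Mediterranean
coast, and four sub-basins defined by longitude bands plus a rectangular
Adriatic carve-out.

The ``trend_spec`` dictionary is the experimental dial of the whole package:
each entry is the relative change of one generated variable between the first
and the last assessment period (e.g. ``{"hk_bmi": -0.44}`` makes the hake
recruit biomass index end 44% below its starting level).  The middle period
sits halfway.  With ``noise_sd = 0`` every injected trend propagates exactly
to the matching indicator, which is what makes the pipeline testable end to
end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


class InvalidConfigError(ValueError):
    """Raised when a ScenarioConfig violates one of its invariants."""


#: trend_spec keys the generators understand
TREND_KEYS = (
    "biomass_pilchard_anchovy",
    "biomass_hake",
    "catch",
    "tlc",
    "eke",
    "ppr",
    "sed",
    "cp_capacity",
    "cp_exposure",
    "cp_demand",
    "bft_hab",
    "hk_hab",
    "hk_bmi",
    "rpi",
)


@dataclass(frozen=True)
class GroupSpec:
    """One functional group of the food-web emulator.

    ``base_biomass`` is the basin-scale mean standing stock (t km-2) and
    ``exploitation`` the fraction of that stock caught per year.  The trophic
    level is constant per group, on the 1 (primary producer) to 4 (top
    predator) scale used throughout.
    """

    name: str
    trophic_level: float
    retained: bool
    base_biomass: float
    exploitation: float


def default_groups() -> list[GroupSpec]:
    """Functional groups retained for the food-provisioning indicators.

    Pilchard + anchovy (treated as one group) and hake are the commercially
    dominant species; two further retained groups and one discarded benthic
    group exercise the retained/discarded distinction in the trophic-level
    indicator.
    """
    return [
        GroupSpec("pilchard_anchovy", 3.1, True, 6.0, 0.25),
        GroupSpec("hake", 3.9, True, 1.2, 0.25),
        GroupSpec("red_mullet", 3.2, True, 0.8, 0.20),
        GroupSpec("deepwater_shrimp", 2.6, True, 0.5, 0.20),
        GroupSpec("benthic_invertebrates", 2.1, False, 10.0, 0.02),
    ]


def default_trends() -> dict[str, float]:
    """Study-condition trend injection (see docs/methods.md for rationale)."""
    return {
        "biomass_pilchard_anchovy": -0.30,
        "biomass_hake": -0.30,
        "catch": 0.30,
        "tlc": 0.0,
        "eke": 0.30,
        "ppr": 0.30,
        "sed": 0.10,
        "cp_capacity": -0.30,
        "cp_exposure": 0.0,
        "cp_demand": 0.30,
        "bft_hab": 0.0,
        "hk_hab": -0.30,
        "hk_bmi": -0.44,
        "rpi": -0.005,
    }


@dataclass
class ScenarioConfig:
    # randomness
    seed: int = 0
    noise_sd: float = 0.05     # relative noise level; 0 = fully deterministic

    # grid geometry (regular lon/lat, explicit cell area)
    nlat: int = 16
    nlon: int = 36
    lon_min: float = 0.0
    lon_max: float = 36.0
    lat_min: float = 30.0
    lat_max: float = 46.0
    cell_area_km2: float = 1000.0
    n_land_rows: int = 3       # northernmost rows are land (the "coast")

    # sub-basin partition: two longitude splits + Adriatic box
    basin_boundaries: tuple = (9.0, 22.0)
    adriatic_lon: tuple = (12.0, 20.0)
    adriatic_lat: tuple = (41.0, 46.0)

    # ocean / biogeochemistry emulator
    spatial_amp: float = 0.3   # relative amplitude of the spatial pattern
    base_speed: float = 0.15   # m s-1
    base_ppr: float = 2.0      # mmolN m-2 d-1
    base_sed: float = 60.0     # mmolN m-2

    # food web emulator
    groups: list = field(default_factory=default_groups)
    max_exploitation: float = 0.5   # hard catch <= rate * biomass bound

    # coastal protection emulator
    coast_target_km: float = 30.0
    n_units: int | None = None      # None: derive from coastline length

    # lifecycle maintenance emulator
    days_per_period: int = 60
    base_recruit_biomass: float = 120.0  # kg km-2
    hauls_per_basin: int = 30
    eastern_sparse: bool = True     # emulate the data-poor Eastern basin

    # recreation emulator
    n_lau: int = 12
    rec_cell_km: float = 5.0        # finer, local-scale cell size (km)
    zone_threshold_roads_km: float = 5.0
    zone_threshold_residential_km: float = 10.0

    # injected trends (relative change first -> last period)
    trend_spec: dict = field(default_factory=default_trends)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.nlat <= 0 or self.nlon <= 0:
            raise InvalidConfigError("grid shape must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.cell_area_km2 <= 0:
            raise InvalidConfigError("cell_area_km2 must be > 0")
        if not 0 <= self.n_land_rows < self.nlat:
            raise InvalidConfigError("n_land_rows must leave at least one sea row")
        for key, value in self.trend_spec.items():
            if key not in TREND_KEYS:
                raise InvalidConfigError(f"unknown trend key {key!r}")
            if value <= -1:
                raise InvalidConfigError(f"trend {key}={value} must be > -1")
        b1, b2 = self.basin_boundaries
        if not b1 < b2:
            raise InvalidConfigError("basin boundaries must be strictly increasing")
        for g in self.groups:
            if not 1.0 <= g.trophic_level <= 4.0:
                raise InvalidConfigError(
                    f"trophic level of {g.name} outside [1, 4]"
                )
            if g.base_biomass < 0 or not 0 <= g.exploitation <= self.max_exploitation:
                raise InvalidConfigError(f"invalid biomass/exploitation for {g.name}")
        if not 1 <= self.n_lau <= self.nlon:
            raise InvalidConfigError("n_lau must be between 1 and nlon")
        if self.n_units is not None and self.n_units < 2:
            raise InvalidConfigError("n_units must be >= 2")

    # -- derived geometry -------------------------------------------------
    def lat_centers(self) -> np.ndarray:
        step = (self.lat_max - self.lat_min) / self.nlat
        return self.lat_min + step * (np.arange(self.nlat) + 0.5)

    def lon_centers(self) -> np.ndarray:
        step = (self.lon_max - self.lon_min) / self.nlon
        return self.lon_min + step * (np.arange(self.nlon) + 0.5)

    def sea_mask(self) -> np.ndarray:
        """Boolean (nlat, nlon) mask; the northernmost rows are land."""
        mask = np.ones((self.nlat, self.nlon), dtype=bool)
        if self.n_land_rows:
            mask[-self.n_land_rows :, :] = False
        return mask

    @property
    def cell_km(self) -> float:
        """Linear cell size assuming square cells."""
        return float(np.sqrt(self.cell_area_km2))

    @property
    def coast_lat(self) -> float:
        """Latitude of the land/sea boundary."""
        step = (self.lat_max - self.lat_min) / self.nlat
        return self.lat_max - self.n_land_rows * step

    # -- (de)serialisation ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["groups"] = [asdict(g) for g in self.groups]
        for key in ("basin_boundaries", "adriatic_lon", "adriatic_lat"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "groups" in payload:
            payload["groups"] = [GroupSpec(**g) for g in payload["groups"]]
        for key in ("basin_boundaries", "adriatic_lon", "adriatic_lat"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)
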