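"""Shared domain types: daily climate records and treatment definitions.

The simulation clock is DAFLA (days after first leaf appearance). A
treatment combines a day/night temperature regime (LT = 22/18 °C,
HT = 32/28 °C) with a NaCl concentration in the nutrient solution,
applied from a given DAFLA onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Day/night temperature targets (°C) per regime.
REGIME_TEMPS = {"LT": (22.0, 18.0), "HT": (32.0, 28.0)}

#: Harvest days of the evaluation experiment (DAFLA).
HARVEST_DAYS = (28, 35, 43, 50, 56, 63, 70, 77)

#: Inter-harvest intervals, labelled by the days whose growth they contain.
K_INTERVALS = tuple(
    (HARVEST_DAYS[i] + 1, HARVEST_DAYS[i + 1]) for i in range(len(HARVEST_DAYS) - 1)
)


@dataclass(frozen=True)
class ClimateDay:
    """One day of greenhouse climate.

    Attributes
    ----------
    dafla : int
        Day after first leaf appearance.
    t_day, t_night : float
        Mean day / night air temperature (°C).
    vpd : float
        Daytime mean vapour pressure deficit (kPa).
    par : float
        Daily photosynthetically active radiation above the canopy
        (MJ m^-2 d^-1).
    """

    dafla: int
    t_day: float
    t_night: float
    vpd: float
    par: float

    def __post_init__(self) -> None:
        if self.dafla < 0:
            raise ValueError(f"dafla must be >= 0, got {self.dafla}")
        if self.par < 0:
            raise ValueError(f"par must be >= 0, got {self.par}")
        if self.vpd < 0:
            raise ValueError(f"vpd must be >= 0, got {self.vpd}")

    @property
    def t_mean(self) -> float:
        """Daily mean temperature assuming a 12 h / 12 h photoperiod."""
        return 0.5 * (self.t_day + self.t_night)


@dataclass(frozen=True)
class Treatment:
    """Temperature regime x salinity treatment.

    ``salinity_x`` is the NaCl concentration (mM) in the nutrient
    solution; ``salinity_start`` is the DAFLA from which it acts on
    growth (inclusive).
    """

    regime: str = "LT"
    salinity_x: float = 0.0
    salinity_start: int = 21

    def __post_init__(self) -> None:
        if self.regime not in REGIME_TEMPS:
            raise ValueError(f"regime must be one of {sorted(REGIME_TEMPS)}")
        if self.salinity_x < 0:
            raise ValueError("salinity_x must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.regime}-{self.salinity_x:g}"

    def active_salinity(self, dafla: int) -> float:
        """Salinity felt by the plant on a given day (0 before application)."""
        return self.salinity_x if dafla >= self.salinity_start else 0.0


def climate_to_frame(days: list[ClimateDay]) -> pd.DataFrame:
    """Tabulate a climate series (columns dafla,t_day,t_night,vpd,par)."""
    return pd.DataFrame(
        {
            "dafla": [d.dafla for d in days],
            "t_day": [d.t_day for d in days],
            "t_night": [d.t_night for d in days],
            "vpd": [d.vpd for d in days],
            "par": [d.par for d in days],
        }
    )


def frame_to_climate(frame: pd.DataFrame) -> list[ClimateDay]:
    """Inverse of :func:`climate_to_frame`."""
    return [
        ClimateDay(int(r.dafla), float(r.t_day), float(r.t_night), float(r.vpd), float(r.par))
        for r in frame.itertuples(index=False)
    ]
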