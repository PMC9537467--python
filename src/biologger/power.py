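"""Operating-mode power and lifetime arithmetic, and the duty-cycled
recording scheduler that drives it.

Power is computed against the 1.8 V regulated main rail (every
component hangs off it), so mode power = average current × 1.8 V
exactly.  Lifetime on the 240 mAh 3 V coin cell is capacity / current /
24 in days, displayed truncated toward zero (one decimal below 10 days,
none above) — the convention the device's published mode table follows.

Two catalog modes (Shelf, Beacon) quote lifetimes that are not
capacity/current-consistent — their currents are evidently peak draws
with radio duty cycling behind the quoted endurance — so their quoted
lifetimes are carried as metadata, never recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "OperatingMode",
    "Battery",
    "RecordingSchedule",
    "PowerEstimate",
    "DEFAULT_MODES",
    "MAIN_RAIL_V",
    "power_mw",
    "truncate_toward_zero",
    "lifetime_days",
    "schedule_stats",
    "reproduce_mode_table",
]

MAIN_RAIL_V = 1.8


@dataclass(frozen=True)
class OperatingMode:
    """One catalog operating mode of the device.

    ``current_unit`` records whether the catalog prints this row in μA
    or mA (display only); ``power_decimals`` the printed precision.
    """

    name: str
    current_ma: float
    description: str = ""
    current_unit: str = "mA"
    power_decimals: int = 2
    lifetime_consistent: bool = True
    quoted_lifetime: Optional[str] = None

    def __post_init__(self) -> None:
        if self.current_ma <= 0:
            raise ValueError("current_ma must be positive")
        if self.current_unit not in ("mA", "uA"):
            raise ValueError("current_unit must be 'mA' or 'uA'")


@dataclass(frozen=True)
class Battery:
    """The 2032 coin cell: 3 V nominal, 240 mAh."""

    capacity_mah: float = 240.0
    nominal_v: float = 3.0

    def __post_init__(self) -> None:
        if self.capacity_mah <= 0:
            raise ValueError("capacity must be positive")


@dataclass(frozen=True)
class RecordingSchedule:
    """Duty-cycled recording: ``on_s`` seconds of every ``period_s``."""

    on_s: float
    period_s: float
    channels: tuple = ()
    axy_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.period_s < 0 or not 0 <= self.on_s <= max(self.period_s, 0):
            raise ValueError("need 0 ≤ on_s ≤ period_s")


@dataclass(frozen=True)
class PowerEstimate:
    power_mw: float
    lifetime_days: float  # truncated at display precision
    raw_lifetime_days: float


def power_mw(current_ma: float, rail_v: float = MAIN_RAIL_V) -> float:
    """Average power at the regulated rail: exact current × voltage."""
    if current_ma < 0:
        raise ValueError("current must be non-negative")
    return current_ma * rail_v


def truncate_toward_zero(value: float, decimals: int) -> float:
    """Floor at ``decimals`` places (4.35 → 4.3, never 4.4).

    A tiny epsilon absorbs binary-float fuzz on exact products
    (0.5·1.8 = 0.9 must not truncate to 0.8).
    """
    scale = 10**decimals
    return math.floor(value * scale + 1e-9) / scale


def _display_decimals(raw_days: float) -> int:
    return 1 if raw_days < 10 else 0


def lifetime_days(
    battery: Battery, current_ma: float, display_decimals: Optional[int] = None
) -> PowerEstimate:
    """Battery endurance at a constant average draw.

    Raw lifetime is capacity / current / 24 (days); the displayed value
    truncates toward zero at one decimal below 10 days, zero decimals
    otherwise (or at an explicit ``display_decimals``).
    """
    if current_ma <= 0:
        raise ValueError("current must be positive")
    raw = battery.capacity_mah / current_ma / 24.0
    d = _display_decimals(raw) if display_decimals is None else display_decimals
    return PowerEstimate(
        power_mw=power_mw(current_ma),
        lifetime_days=truncate_toward_zero(raw, d),
        raw_lifetime_days=raw,
    )


def schedule_stats(
    schedule: RecordingSchedule, i_on_ma: float, i_off_ma: float
) -> tuple[float, float]:
    """Duty fraction and duty-weighted average current of a schedule."""
    if schedule.period_s == 0:
        raise ValueError("period_s must be positive")
    duty = schedule.on_s / schedule.period_s
    return duty, duty * i_on_ma + (1.0 - duty) * i_off_ma


#: The device's published operating-mode catalog: average current per
#: mode, display conventions, and which rows have capacity-consistent
#: quoted lifetimes.
DEFAULT_MODES: tuple[OperatingMode, ...] = (
    OperatingMode(
        "Shelf",
        0.044,
        "BLE radio off until motion wake",
        current_unit="uA",
        power_decimals=1,
        lifetime_consistent=False,
        quoted_lifetime="6.8 years",
    ),
    OperatingMode(
        "Beacon",
        0.5,
        "advertises and becomes connectable every 30-60 s",
        power_decimals=1,
        lifetime_consistent=False,
        quoted_lifetime="40 days",
    ),
    OperatingMode("Connected", 2.3, "actively connected to a central device"),
    OperatingMode(
        "Biopotentials", 2.8, "all 4 biopotential channels on, 1 Hz accelerometer"
    ),
    OperatingMode(
        "Recording Ex. 1",
        0.48,
        "2 biopotentials + 1 Hz accelerometer, 1 min every 5 min (20% duty cycle)",
    ),
    OperatingMode(
        "Recording Ex. 2",
        0.13,
        "10 Hz accelerometer always recording",
        current_unit="uA",
        power_decimals=0,
    ),
)


def reproduce_mode_table(
    modes: Sequence[OperatingMode] = DEFAULT_MODES,
    battery: Battery = Battery(),
) -> pd.DataFrame:
    """Recompute the operating-mode power/lifetime table.

    ``power_display`` is in each row's printed unit (μW for μA rows,
    mW for mA rows), truncated at the row's printed precision;
    ``lifetime_display`` is the truncated day count, NaN for the rows
    whose quoted lifetimes are not capacity/current-consistent (those
    keep only ``quoted_lifetime``).
    """
    rows = []
    for mode in modes:
        est = lifetime_days(battery, mode.current_ma)
        p_mw = est.power_mw
        p_disp = p_mw * 1000 if mode.current_unit == "uA" else p_mw
        rows.append(
            {
                "name": mode.name,
                "current_ma": mode.current_ma,
                "power_mw": p_mw,
                "power_display": truncate_toward_zero(p_disp, mode.power_decimals),
                "power_unit": "uW" if mode.current_unit == "uA" else "mW",
                "raw_lifetime_days": est.raw_lifetime_days,
                "lifetime_display": (
                    est.lifetime_days if mode.lifetime_consistent else float("nan")
                ),
                "lifetime_consistent": mode.lifetime_consistent,
                "quoted_lifetime": mode.quoted_lifetime,
            }
        )
    return pd.DataFrame(rows)
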