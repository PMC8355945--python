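"""Cross-species sensory-update arithmetic and wingbeat allometry.

Echolocators spread enormously in size and locomotor mode; a fair
comparison of sonar sampling normalizes the update (call/click) rate by
travel speed — updates per meter — and additionally by body size —
updates per body length traveled (rate x length / speed).  A commuting
bat sampling at its wingbeat rate manages about one update per meter and
one per ~13 body lengths, while toothed whales, whose pneumatic click
production is decoupled from locomotion, sample hundreds of times faster
per body length.

The allometric wingbeat-frequency regression
``f = 5.54 - 3.068 log10(mass) - 2.857 log10(speed)`` (mass in kg, speed
in m/s) predicts the commuting wingbeat rate from body mass and flight
speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass
class SpeciesProfile:
    """Sensory-flow parameters of one echolocating species."""

    name: str
    body_length_m: float
    rate_commute_hz: float
    rate_capture_hz: float
    speed_commute_ms: float
    speed_capture_ms: float

    def validate(self) -> None:
        vals = [
            self.body_length_m,
            self.rate_commute_hz,
            self.rate_capture_hz,
            self.speed_commute_ms,
            self.speed_capture_ms,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError(f"{self.name}: all profile values must be positive")
        if not 0.01 <= self.body_length_m <= 50.0:
            raise ValueError(f"{self.name}: body length {self.body_length_m} m implausible")


@dataclass
class UpdateMetrics:
    """Sensory updates per meter and per body length traveled, both modes."""

    per_meter_commute: float
    per_meter_capture: float
    per_body_length_commute: float
    per_body_length_capture: float


def update_metrics(profile: SpeciesProfile) -> UpdateMetrics:
    """Pure arithmetic: rate/speed and rate*length/speed per mode."""
    profile.validate()
    pm_c = profile.rate_commute_hz / profile.speed_commute_ms
    pm_k = profile.rate_capture_hz / profile.speed_capture_ms
    return UpdateMetrics(
        per_meter_commute=pm_c,
        per_meter_capture=pm_k,
        per_body_length_commute=pm_c * profile.body_length_m,
        per_body_length_capture=pm_k * profile.body_length_m,
    )


def fold_ratio(metric_a: float, metric_b: float) -> float:
    """Exact ratio A/B of two update metrics."""
    if metric_b <= 0:
        raise ValueError("denominator metric must be > 0")
    return metric_a / metric_b


def allometric_wingbeat_frequency(body_mass_kg: float, flight_speed_ms: float) -> float:
    """Predicted wingbeat frequency (Hz) from body mass (kg) and speed (m/s)."""
    if body_mass_kg <= 0 or flight_speed_ms <= 0:
        raise ValueError("mass and speed must be positive")
    return 5.54 - 3.068 * np.log10(body_mass_kg) - 2.857 * np.log10(flight_speed_ms)


def load_species_table(path=None) -> pd.DataFrame:
    """Default echolocator profiles (bat, sperm whale, harbor porpoise) or a user CSV."""
    if path is None:
        with resources.files("echowing.data").joinpath("species.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def profiles_from_table(table: pd.DataFrame) -> list:
    return [
        SpeciesProfile(
            name=row["name"],
            body_length_m=row["length_m"],
            rate_commute_hz=row["rate_commute"],
            rate_capture_hz=row["rate_capture"],
            speed_commute_ms=row["speed_commute"],
            speed_capture_ms=row["speed_capture"],
        )
        for _, row in table.iterrows()
    ]


def update_table(table: pd.DataFrame = None) -> pd.DataFrame:
    """Table-style report: per-meter and per-body-length update rates per species."""
    if table is None:
        table = load_species_table()
    rows = []
    for p in profiles_from_table(table):
        m = update_metrics(p)
        rows.append(
            {
                "name": p.name,
                "length_m": p.body_length_m,
                "rate_commute": p.rate_commute_hz,
                "rate_capture": p.rate_capture_hz,
                "speed_commute": p.speed_commute_ms,
                "speed_capture": p.speed_capture_ms,
                "per_m_commute": m.per_meter_commute,
                "per_m_capture": m.per_meter_capture,
                "per_bl_commute": m.per_body_length_commute,
                "per_bl_capture": m.per_body_length_capture,
            }
        )
    return pd.DataFrame(rows)
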