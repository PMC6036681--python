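"""Mole balances for closed serum-bottle headspace gas time series.

A sealed bottle cultivation is monitored by repeated sampling events: a
manometer reading before and after each sampling, a micro-GC mole-fraction
analysis of the headspace, and an OD600 reading on withdrawn culture.  Each
event removes a few millilitres of gas and liquid, so raw headspace amounts
understate what the culture actually turned over.  This module converts an
ordered series of such observations into per-species molar amounts via the
ideal gas law,

    n_j = x_j * P * V_h / (R * T),

and accumulates a withdrawal-corrected net-production ledger

    Q_j(i) = n_j(i) - n_j(0) + sum_{k<i} removed_j(k),

so that Q_j(i) is the cumulative amount of species j produced (negative:
consumed) by reaction inside the bottle up to sampling i, with gas lost to
the syringe credited back.  Derived summaries (H2/CO yield, H2 onset time,
O2 depletion time, growth maxima) mirror how closed-bottle hydrogenogenesis
experiments are usually reported.

Conventions
-----------
* Amounts in mmol, volumes in ml, pressures in bar, temperatures in K,
  times in h; R = 0.0831446 ml·bar·mmol⁻¹·K⁻¹.
* Incubation-phase pressure readings are converted at the incubation
  temperature; the initial gas fill is characterised at the (cooler) fill
  temperature.
* The headspace grows by every liquid withdrawal; dissolved gas in the
  withdrawn liquid is ignored (no liquid-phase state is tracked).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SPECIES",
    "GAS_CONSTANT_ML_BAR",
    "BottleSpec",
    "GasComposition",
    "SpeciesAmounts",
    "SamplePoint",
    "MeasurementSeries",
    "BalanceSummary",
    "BalanceResult",
    "GrowthSummary",
    "normalize_composition",
    "headspace_amounts",
    "withdrawal_amounts",
    "headspace_volume_at",
    "cumulative_balance",
    "yield_h2_per_co",
    "detect_h2_onset",
    "o2_depletion_time",
    "growth_summary",
]

#: Fixed headspace species set, in column order (H2, O2, N2, CO, CO2).
SPECIES: tuple[str, ...] = ("h2", "o2", "n2", "co", "co2")

#: Ideal gas constant in ml·bar·mmol⁻¹·K⁻¹.
GAS_CONSTANT_ML_BAR: float = 0.0831446

#: Default detection threshold for cumulative H2 (mmol).
DEFAULT_ONSET_THRESHOLD: float = 0.02

#: Default headspace-O2 depletion threshold (mmol).
DEFAULT_O2_THRESHOLD: float = 0.05


@dataclass(frozen=True)
class _SpeciesVector:
    """Five non-negative numbers keyed by the fixed species set."""

    h2: float = 0.0
    o2: float = 0.0
    n2: float = 0.0
    co: float = 0.0
    co2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.h2, self.o2, self.n2, self.co, self.co2], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]):
        vals = [float(v) for v in values]
        if len(vals) != len(SPECIES):
            raise ValueError(f"expected {len(SPECIES)} species values, got {len(vals)}")
        return cls(**dict(zip(SPECIES, vals)))

    def total(self) -> float:
        return self.h2 + self.o2 + self.n2 + self.co + self.co2

    def __getitem__(self, species: str) -> float:
        key = species.lower()
        if key not in SPECIES:
            raise KeyError(f"unknown species {species!r}")
        return getattr(self, key)


@dataclass(frozen=True)
class GasComposition(_SpeciesVector):
    """Headspace mole fractions as reported by the GC (possibly unnormalized)."""

    def __post_init__(self) -> None:
        for name in SPECIES:
            x = getattr(self, name)
            if not math.isfinite(x) or x < 0.0 or x > 1.0:
                raise ValueError(f"mole fraction {name}={x!r} outside [0, 1]")

    def normalize(self) -> "GasComposition":
        return normalize_composition(self)


@dataclass(frozen=True)
class SpeciesAmounts(_SpeciesVector):
    """Molar amounts (mmol) per species; headspace contents or a withdrawal ledger."""

    def __post_init__(self) -> None:
        for name in SPECIES:
            n = getattr(self, name)
            if not math.isfinite(n) or n < -1e-9:
                raise ValueError(f"amount {name}={n!r} must be >= 0 mmol")


@dataclass(frozen=True)
class BottleSpec:
    """Physical configuration of one closed serum-bottle run.

    Defaults describe a 250 ml bottle with 50 ml of medium, filled at room
    temperature and 1 bar and incubated at 60 °C.
    """

    total_volume: float = 250.0  # ml
    initial_liquid_volume: float = 50.0  # ml
    fill_temperature: float = 298.15  # K
    incubation_temperature: float = 333.15  # K
    fill_pressure: float = 1.0  # bar
    gas_constant: float = GAS_CONSTANT_ML_BAR

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_liquid_volume < self.total_volume:
            raise ValueError(
                "initial_liquid_volume must satisfy 0 < liquid < total_volume"
            )
        if self.fill_temperature <= 0 or self.incubation_temperature <= 0:
            raise ValueError("temperatures must be positive (K)")
        if self.fill_pressure <= 0:
            raise ValueError("fill_pressure must be positive (bar)")
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be positive")

    @property
    def initial_headspace_volume(self) -> float:
        """Gas-phase volume (ml) before any liquid has been withdrawn."""
        return self.total_volume - self.initial_liquid_volume

    def initial_total_moles(self) -> float:
        """Total gas moles sealed in at fill pressure/temperature (mmol)."""
        return (
            self.fill_pressure
            * self.initial_headspace_volume
            / (self.gas_constant * self.fill_temperature)
        )


@dataclass(frozen=True)
class SamplePoint:
    """One sampling event: pressures, GC composition, OD and sampled volumes."""

    time: float  # h
    pressure_before: float  # bar
    pressure_after: float | None  # bar; None -> nominal-volume fallback
    composition: GasComposition  # raw, pre-normalization
    od600: float | None = None
    gas_sample_volume: float = 3.0  # ml
    liquid_sample_volume: float = 1.0  # ml

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time {self.time} must be >= 0 h")
        if self.pressure_before <= 0:
            raise ValueError(f"pressure_before {self.pressure_before} must be > 0 bar")
        if self.pressure_after is not None:
            if self.pressure_after <= 0:
                raise ValueError(f"pressure_after {self.pressure_after} must be > 0 bar")
            if self.pressure_after > self.pressure_before + 1e-12:
                raise ValueError(
                    "pressure_after exceeds pressure_before "
                    f"({self.pressure_after} > {self.pressure_before} bar)"
                )
        if self.gas_sample_volume < 0 or self.liquid_sample_volume < 0:
            raise ValueError("sample volumes must be >= 0 ml")


@dataclass(frozen=True)
class MeasurementSeries:
    """Ordered sampling events from a single bottle."""

    bottle: BottleSpec
    points: tuple[SamplePoint, ...]

    def __init__(self, bottle: BottleSpec, points: Sequence[SamplePoint]) -> None:
        object.__setattr__(self, "bottle", bottle)
        object.__setattr__(self, "points", tuple(points))
        times = [p.time for p in self.points]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise ValueError(
                    f"sampling times must be strictly increasing; "
                    f"t={times[i]} h at position {i} follows t={times[i - 1]} h"
                )

    def __len__(self) -> int:
        return len(self.points)


def normalize_composition(raw: GasComposition) -> GasComposition:
    """Rescale GC mole fractions so they sum to exactly 1.

    Raises ``ValueError`` for an all-zero record (an empty GC injection).
    """
    total = raw.total()
    if total <= 0.0:
        raise ValueError("empty GC record: all mole fractions are zero")
    return GasComposition.from_array(raw.as_array() / total)


def headspace_amounts(
    comp: GasComposition,
    pressure: float,
    headspace_volume: float,
    temperature: float,
    gas_constant: float = GAS_CONSTANT_ML_BAR,
) -> SpeciesAmounts:
    """Per-species headspace amounts n_j = x_j·P·V_h/(R·T), in mmol."""
    if pressure <= 0 or headspace_volume <= 0 or temperature <= 0:
        raise ValueError("pressure, headspace_volume and temperature must be > 0")
    total = pressure * headspace_volume / (gas_constant * temperature)
    return SpeciesAmounts.from_array(comp.as_array() * total)


def withdrawal_amounts(
    comp: GasComposition,
    pressure_before: float,
    pressure_after: float,
    headspace_volume: float,
    temperature: float,
    gas_constant: float = GAS_CONSTANT_ML_BAR,
) -> SpeciesAmounts:
    """Moles removed by one gas sampling, from the before/after pressure drop.

    removed_j = x_j·(P_before − P_after)·V_h/(R·T).  The withdrawn gas is
    assumed to carry the same composition the GC measured at that point.
    """
    if pressure_after > pressure_before + 1e-12:
        raise ValueError(
            "inconsistent manometer readings: pressure_after > pressure_before"
        )
    if headspace_volume <= 0 or temperature <= 0:
        raise ValueError("headspace_volume and temperature must be > 0")
    delta = max(pressure_before - pressure_after, 0.0)
    total = delta * headspace_volume / (gas_constant * temperature)
    return SpeciesAmounts.from_array(comp.as_array() * total)


def headspace_volume_at(
    bottle: BottleSpec, series: MeasurementSeries, index: int
) -> float:
    """Headspace volume (ml) in effect at sampling ``index``.

    Every earlier liquid withdrawal enlarges the gas phase:
    V_h(i) = total − initial_liquid + Σ_{k<i} v_liq(k).
    """
    if not 0 <= index < len(series.points):
        raise IndexError(f"point index {index} out of range 0..{len(series.points) - 1}")
    drawn = sum(p.liquid_sample_volume for p in series.points[:index])
    return bottle.total_volume - bottle.initial_liquid_volume + drawn


class GrowthSummary(NamedTuple):
    max_od: float
    max_od_time: float
    final_od: float


@dataclass(frozen=True)
class BalanceSummary:
    """Headline numbers of one balance: yield, onset/depletion times, growth."""

    yield_h2_per_co: float | None
    h2_onset_time: float | None
    o2_depletion_time: float | None
    max_od: float | None
    max_od_time: float | None
    final_od: float | None
    net_production_mmol: dict[str, float]


@dataclass
class BalanceResult:
    """Per-point amounts, withdrawal ledger and cumulative net production.

    Arrays are indexed ``[point, species]`` with species in :data:`SPECIES`
    order.  ``cumulative[i, j]`` is Q_j(i): net mmol of species j produced
    (negative: consumed) by reaction inside the bottle up to point i.
    """

    times: np.ndarray  # (n,) h
    headspace_volumes: np.ndarray  # (n,) ml
    headspace: np.ndarray  # (n, 5) mmol, from pressure_before
    removed: np.ndarray  # (n, 5) mmol withdrawn at each point
    cumulative: np.ndarray  # (n, 5) mmol net production Q
    summary: BalanceSummary

    def species_index(self, name: str) -> int:
        return SPECIES.index(name.lower())

    def cumulative_for(self, name: str) -> np.ndarray:
        return self.cumulative[:, self.species_index(name)]

    def headspace_for(self, name: str) -> np.ndarray:
        return self.headspace[:, self.species_index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Per-point balance as a tidy table (one row per sampling)."""
        data: dict[str, np.ndarray] = {"time_h": self.times}
        data["headspace_volume_ml"] = self.headspace_volumes
        for j, sp in enumerate(SPECIES):
            data[f"n_{sp}_mmol"] = self.headspace[:, j]
        for j, sp in enumerate(SPECIES):
            data[f"removed_{sp}_mmol"] = self.removed[:, j]
        for j, sp in enumerate(SPECIES):
            data[f"q_{sp}_mmol"] = self.cumulative[:, j]
        return pd.DataFrame(data)


def _effective_pressure_after(point: SamplePoint, headspace_volume: float) -> float:
    """Measured after-pressure, or a nominal-sample-volume fallback."""
    if point.pressure_after is not None:
        return point.pressure_after
    fallback = point.pressure_before * (
        1.0 - point.gas_sample_volume / headspace_volume
    )
    logger.warning(
        "missing pressure_after at t=%.3g h; assuming nominal %.3g ml draw "
        "(P_after=%.5g bar)",
        point.time,
        point.gas_sample_volume,
        fallback,
    )
    return fallback


def cumulative_balance(
    series: MeasurementSeries,
    onset_threshold: float = DEFAULT_ONSET_THRESHOLD,
    o2_threshold: float = DEFAULT_O2_THRESHOLD,
) -> BalanceResult:
    """Withdrawal-corrected cumulative gas balance of a measurement series.

    For each point i the headspace content n_j(i) is computed from the
    pre-sampling pressure at the incubation temperature and the current
    headspace volume; the withdrawal at point k (credited to all later
    points) is derived from the before/after pressure pair and the same
    point's GC composition.  Q_j(0) = 0 by construction.
    """
    if len(series.points) < 2:
        raise ValueError("a balance needs at least 2 sampling points")
    bottle = series.bottle
    n_pts = len(series.points)
    temperature = bottle.incubation_temperature

    times = np.array([p.time for p in series.points], dtype=float)
    volumes = np.array(
        [headspace_volume_at(bottle, series, i) for i in range(n_pts)], dtype=float
    )
    headspace = np.zeros((n_pts, len(SPECIES)))
    removed = np.zeros((n_pts, len(SPECIES)))
    for i, point in enumerate(series.points):
        comp = normalize_composition(point.composition)
        headspace[i] = headspace_amounts(
            comp, point.pressure_before, volumes[i], temperature, bottle.gas_constant
        ).as_array()
        p_after = _effective_pressure_after(point, volumes[i])
        removed[i] = withdrawal_amounts(
            comp,
            point.pressure_before,
            p_after,
            volumes[i],
            temperature,
            bottle.gas_constant,
        ).as_array()

    credited = np.vstack(
        [np.zeros(len(SPECIES)), np.cumsum(removed[:-1], axis=0)]
    )
    cumulative = headspace - headspace[0] + credited

    balance = BalanceResult(
        times=times,
        headspace_volumes=volumes,
        headspace=headspace,
        removed=removed,
        cumulative=cumulative,
        summary=None,  # type: ignore[arg-type]
    )

    q_co_final = balance.cumulative_for("co")[-1]
    y = yield_h2_per_co(balance) if q_co_final < 0.0 else None
    try:
        growth: GrowthSummary | None = growth_summary(series)
    except ValueError:
        growth = None
    balance.summary = BalanceSummary(
        yield_h2_per_co=y,
        h2_onset_time=detect_h2_onset(balance, onset_threshold),
        o2_depletion_time=o2_depletion_time(balance, o2_threshold),
        max_od=growth.max_od if growth else None,
        max_od_time=growth.max_od_time if growth else None,
        final_od=growth.final_od if growth else None,
        net_production_mmol={sp: float(cumulative[-1, j]) for j, sp in enumerate(SPECIES)},
    )
    return balance


def yield_h2_per_co(balance: BalanceResult) -> float:
    """Molar H2-per-CO yield: Q_H2(final) / (−Q_CO(final)).

    Defined only when CO was net consumed; raises otherwise.
    """
    q_h2 = float(balance.cumulative_for("h2")[-1])
    q_co = float(balance.cumulative_for("co")[-1])
    if q_co >= 0.0:
        raise ValueError("H2/CO yield undefined: no net CO consumption")
    return q_h2 / (-q_co)


def detect_h2_onset(
    balance: BalanceResult, threshold: float = DEFAULT_ONSET_THRESHOLD
) -> float | None:
    """Time of the first point with cumulative H2 above ``threshold`` mmol."""
    if threshold <= 0:
        raise ValueError("onset threshold must be > 0 mmol")
    q_h2 = balance.cumulative_for("h2")
    above = np.nonzero(q_h2 > threshold)[0]
    if above.size == 0:
        return None
    return float(balance.times[above[0]])


def o2_depletion_time(
    balance: BalanceResult, threshold: float = DEFAULT_O2_THRESHOLD
) -> float | None:
    """Time of the first point with headspace O2 strictly below ``threshold`` mmol.

    The inequality is strict, so a zero threshold can never be crossed.
    """
    if threshold < 0:
        raise ValueError("O2 depletion threshold must be >= 0 mmol")
    n_o2 = balance.headspace_for("o2")
    below = np.nonzero(n_o2 < threshold)[0]
    if below.size == 0:
        return None
    return float(balance.times[below[0]])


def growth_summary(series: MeasurementSeries) -> GrowthSummary:
    """Maximum OD600, its (earliest) time, and the last recorded OD600."""
    observed = [(p.time, p.od600) for p in series.points if p.od600 is not None]
    if not observed:
        raise ValueError("no OD600 values present in the series")
    max_time, max_od = max(observed, key=lambda to: (to[1], -to[0]))
    return GrowthSummary(max_od=max_od, max_od_time=max_time, final_od=observed[-1][1])
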