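"""Readers and writers: measurement tables, run configs, summaries, FASTA.

The measurement table is a tab-separated file with one header row and the
fixed column set

    time_h  p_before_bar  p_after_bar  x_h2  x_o2  x_n2  x_co  x_co2
    od600  v_gas_ml  v_liq_ml

(``od600`` and ``p_after_bar`` may be ``NA``).  Run configuration is a flat
YAML key-value file mirroring the bottle geometry, analysis thresholds,
noise settings and seed.  Result summaries are JSON with a fixed key set and
tool/version metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .accounting import (
    SPECIES,
    BalanceResult,
    BottleSpec,
    GasComposition,
    MeasurementSeries,
    SamplePoint,
)
from .genomics import OrthologyCall, ProteinRecord
from .simulator import NoiseModel

__all__ = [
    "MEASUREMENT_COLUMNS",
    "SCHEMA_VERSION",
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "read_config",
    "write_config",
    "write_summary",
    "summary_dict",
    "read_proteins",
    "read_nucleotide",
    "write_orthology_table",
]

MEASUREMENT_COLUMNS = (
    "time_h",
    "p_before_bar",
    "p_after_bar",
    "x_h2",
    "x_o2",
    "x_n2",
    "x_co",
    "x_co2",
    "od600",
    "v_gas_ml",
    "v_liq_ml",
)

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration: bottle geometry, thresholds, noise, seed."""

    bottle: BottleSpec = field(default_factory=BottleSpec)
    onset_threshold: float = 0.02  # mmol cumulative H2
    o2_threshold: float = 0.05  # mmol headspace O2
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "total_volume_ml": self.bottle.total_volume,
            "initial_liquid_volume_ml": self.bottle.initial_liquid_volume,
            "fill_temperature_k": self.bottle.fill_temperature,
            "incubation_temperature_k": self.bottle.incubation_temperature,
            "fill_pressure_bar": self.bottle.fill_pressure,
            "onset_threshold_mmol": self.onset_threshold,
            "o2_threshold_mmol": self.o2_threshold,
            "gc_cv": self.noise.gc_cv,
            "pressure_sd_bar": self.noise.pressure_sd_bar,
            "od_sd": self.noise.od_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        bottle_defaults = BottleSpec()
        bottle = BottleSpec(
            total_volume=data.get("total_volume_ml", bottle_defaults.total_volume),
            initial_liquid_volume=data.get(
                "initial_liquid_volume_ml", bottle_defaults.initial_liquid_volume
            ),
            fill_temperature=data.get(
                "fill_temperature_k", bottle_defaults.fill_temperature
            ),
            incubation_temperature=data.get(
                "incubation_temperature_k", bottle_defaults.incubation_temperature
            ),
            fill_pressure=data.get("fill_pressure_bar", bottle_defaults.fill_pressure),
        )
        noise = NoiseModel(
            gc_cv=data.get("gc_cv", 0.0),
            pressure_sd_bar=data.get("pressure_sd_bar", 0.0),
            od_sd=data.get("od_sd", 0.0),
        )
        return cls(
            bottle=bottle,
            onset_threshold=data.get("onset_threshold_mmol", 0.02),
            o2_threshold=data.get("o2_threshold_mmol", 0.05),
            noise=noise,
            seed=int(data.get("seed", 0)),
        )


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _optional(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_measurements(
    path: str | Path, bottle: BottleSpec | None = None
) -> MeasurementSeries:
    """Read a measurement table into a validated series.

    Validation failures name the offending row (1-based, excluding the
    header) and column.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    extra = [c for c in frame.columns if c not in MEASUREMENT_COLUMNS]
    if extra:
        raise ValueError(f"{path}: unexpected columns {extra}")

    points: list[SamplePoint] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            comp = GasComposition(
                h2=float(row.x_h2),
                o2=float(row.x_o2),
                n2=float(row.x_n2),
                co=float(row.x_co),
                co2=float(row.x_co2),
            )
            points.append(
                SamplePoint(
                    time=float(row.time_h),
                    pressure_before=float(row.p_before_bar),
                    pressure_after=_optional(row.p_after_bar),
                    composition=comp,
                    od600=_optional(row.od600),
                    gas_sample_volume=float(row.v_gas_ml),
                    liquid_sample_volume=float(row.v_liq_ml),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
    try:
        return MeasurementSeries(bottle=bottle or BottleSpec(), points=points)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_measurements(series: MeasurementSeries, path: str | Path) -> None:
    def fmt(value) -> str:
        # shortest repr keeps the write -> read round trip exact
        return "NA" if value is None else repr(float(value))

    rows = []
    for p in series.points:
        rows.append(
            {
                "time_h": p.time,
                "p_before_bar": p.pressure_before,
                "p_after_bar": p.pressure_after,
                "x_h2": p.composition.h2,
                "x_o2": p.composition.o2,
                "x_n2": p.composition.n2,
                "x_co": p.composition.co,
                "x_co2": p.composition.co2,
                "od600": p.od600,
                "v_gas_ml": p.gas_sample_volume,
                "v_liq_ml": p.liquid_sample_volume,
            }
        )
    frame = pd.DataFrame(
        [{k: fmt(v) for k, v in row.items()} for row in rows],
        columns=list(MEASUREMENT_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def summary_dict(balance: BalanceResult) -> dict:
    """Fixed-schema summary of one balance (display values rounded to 2 d.p.)."""
    s = balance.summary
    return {
        "tool": "cowgas",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "yield_h2_per_co": (
            None if s.yield_h2_per_co is None else round(s.yield_h2_per_co, 2)
        ),
        "h2_onset_time_h": s.h2_onset_time,
        "o2_depletion_time_h": s.o2_depletion_time,
        "max_od": s.max_od,
        "max_od_time_h": s.max_od_time,
        "final_od": s.final_od,
        "net_production_mmol": {
            sp: round(v, 2) for sp, v in s.net_production_mmol.items()
        },
        "raw": {
            "yield_h2_per_co": s.yield_h2_per_co,
            "net_production_mmol": dict(s.net_production_mmol),
        },
    }


def write_summary(balance: BalanceResult, path: str | Path) -> None:
    """Write the JSON summary block for one balance."""
    with open(path, "w") as fh:
        json.dump(summary_dict(balance), fh, indent=2)
        fh.write("\n")


def read_proteins(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_nucleotide(path: str | Path) -> str:
    """Concatenated nucleotide sequence of all records in a FASTA file."""
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return "".join(seqs)


def write_orthology_table(calls: Sequence[OrthologyCall], path: str | Path) -> None:
    rows = [
        {
            "query": c.query_id,
            "subject": c.subject_id,
            "score": c.alignment.score,
            "identity_pct": c.alignment.identity_pct,
            "query_coverage": c.alignment.query_coverage,
            "subject_coverage": c.alignment.subject_coverage,
            "is_ortholog": c.is_ortholog,
        }
        for c in calls
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "query",
            "subject",
            "score",
            "identity_pct",
            "query_coverage",
            "subject_coverage",
            "is_ortholog",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
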