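"""Tabular input/output, packaged reference parameters, and assay utilities.

Measurement tables are long-format CSV (one row per sample x temperature x
replicate x day).  Temperatures are stored internally in kelvin only; the
reference parameter table uses the integer kelvins 277/281/289/293 for the
nominal 4/8/16/20 degC storage conditions.  Results are serialized to JSON
documents carrying a ``schema_version`` field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TBARSSeries",
    "AssayRecord",
    "SecondaryParameters",
    "SAMPLE_GROUPS",
    "CELSIUS_OFFSET",
    "SchemaError",
    "DataError",
    "read_tbars_table",
    "write_tbars_table",
    "load_assay_fixture",
    "load_secondary_fixture",
    "pearson_r",
    "write_results",
    "read_results",
]

CELSIUS_OFFSET = 273.15

#: Canonical sample groups: control meat plus the 13 plant-extract treatments.
SAMPLE_GROUPS = (
    "Allspice",
    "Basil",
    "Bay leaf",
    "Black seed",
    "Caraway",
    "Cardamom",
    "Clove",
    "Control",
    "Garlic",
    "Nutmeg",
    "Onion",
    "Oregano",
    "Rosemary",
    "Thyme",
)


class SchemaError(ValueError):
    """A table does not match the declared column schema."""


class DataError(ValueError):
    """A table parses but its values violate a data invariant."""


@dataclass
class TBARSSeries:
    """One replicate's TBARS time series at one storage temperature.

    Parameters
    ----------
    sample_label : str
        Sample group name ("Control" or an extract name).
    temperature : float
        Storage temperature in kelvin.
    replicate_id : int
        1-based replicate index.
    times : sequence of float
        Sampling days, strictly increasing, starting at day 0.
    raw_values : sequence of float, optional
        TBARS in mg MDA/kg meat; strictly positive.
    percent_values : sequence of float, optional
        TBARS as percent of the initial value; first entry exactly 100.
    """

    sample_label: str
    temperature: float
    replicate_id: int
    times: Sequence[float]
    raw_values: Sequence[float] | None = None
    percent_values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise DataError("series must contain at least one time point")
        if self.times[0] != 0.0:
            raise DataError(f"first sampling day must be 0, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("sampling days must be strictly increasing")
        if self.temperature <= 0:
            raise DataError("temperature must be positive (kelvin)")
        if self.replicate_id < 1:
            raise DataError("replicate_id must be >= 1")
        for name in ("raw_values", "percent_values"):
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise DataError(f"{name} length does not match times")
            setattr(self, name, vals)
        if self.raw_values is not None and np.any(self.raw_values <= 0):
            raise DataError("raw TBARS values must be strictly positive")
        if self.percent_values is not None and self.percent_values[0] != 100.0:
            raise DataError("percent_values must start at exactly 100")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def key(self) -> tuple[str, float, int]:
        return (self.sample_label, float(self.temperature), int(self.replicate_id))


@dataclass(frozen=True)
class AssayRecord:
    """Antioxidant assay summary for one extract.

    ``teac_dpph`` is the Trolox-equivalent antioxidant capacity by DPPH
    radical scavenging (uM TE per g dry sample); ``tpc`` is total phenolic
    content (mg GAE per g dry weight).
    """

    extract: str
    teac_dpph: float
    tpc: float

    def __post_init__(self) -> None:
        if self.teac_dpph < 0 or self.tpc < 0:
            raise DataError("assay values must be non-negative")


@dataclass(frozen=True)
class SecondaryParameters:
    """Published secondary-model parameters for one sample group.

    ``k_by_temperature`` maps kelvin to the first-order TBARS rate constant
    (day^-1); ``ea`` (J/mol) and ``k0`` (day^-1) are the Arrhenius activation
    energy and pre-exponential factor; ``c`` (K^-1) and ``tc`` (K) are the
    log-logistic constants.  Printed standard deviations are kept for the
    parameters that have comparison uses (``ea_sd``, ``k0_sd``).
    """

    sample_label: str
    k_by_temperature: Mapping[float, float]
    ea: float
    k0: float
    c: float
    tc: float
    ea_sd: float = float("nan")
    k0_sd: float = float("nan")


_SCHEMA_DEFAULT = {
    "sample": "sample",
    "temperature": "temperature",
    "replicate": "replicate",
    "day": "day",
    "value": "value",
    "temperature_unit": "celsius",
}


def read_tbars_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[TBARSSeries]:
    """Read a long-format TBARS CSV into one series per (sample, T, replicate).

    ``schema`` maps the roles ``sample``, ``temperature``, ``replicate``,
    ``day`` and ``value`` to column names, and declares the temperature unit
    under ``temperature_unit`` ("celsius" or "kelvin").  Rows are grouped and
    day-sorted; celsius temperatures are converted to kelvin.
    """
    sch = dict(_SCHEMA_DEFAULT)
    if schema:
        sch.update(schema)
    unit = sch["temperature_unit"].lower()
    if unit not in ("celsius", "kelvin"):
        raise SchemaError(f"unknown temperature unit {unit!r}")
    df = pd.read_csv(path)
    roles = ["sample", "temperature", "replicate", "day", "value"]
    missing = [sch[r] for r in roles if sch[r] not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.rename(columns={sch[r]: r for r in roles})
    dup = df.duplicated(subset=["sample", "temperature", "replicate", "day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataError(
            "duplicate measurement for "
            f"({row['sample']}, {row['temperature']}, {row['replicate']}, day {row['day']})"
        )
    bad = df["value"] <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise DataError(
            f"non-positive TBARS value {row['value']} for ({row['sample']}, "
            f"{row['temperature']}, rep {row['replicate']}, day {row['day']})"
        )
    series: list[TBARSSeries] = []
    for (sample, temp, rep), grp in df.groupby(
        ["sample", "temperature", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        kelvin = float(temp) + (CELSIUS_OFFSET if unit == "celsius" else 0.0)
        series.append(
            TBARSSeries(
                sample_label=str(sample),
                temperature=kelvin,
                replicate_id=int(rep),
                times=grp["day"].to_numpy(dtype=float),
                raw_values=grp["value"].to_numpy(dtype=float),
            )
        )
    return series


def write_tbars_table(
    path: str | Path, series: Sequence[TBARSSeries], temperature_unit: str = "celsius"
) -> None:
    """Write series back to the long CSV format accepted by `read_tbars_table`."""
    rows = []
    for s in series:
        values = s.raw_values if s.raw_values is not None else s.percent_values
        if values is None:
            raise DataError(f"series {s.key()} has no values to write")
        temp = s.temperature - (CELSIUS_OFFSET if temperature_unit == "celsius" else 0.0)
        for t, v in zip(s.times, values):
            rows.append(
                {
                    "sample": s.sample_label,
                    "temperature": temp,
                    "replicate": s.replicate_id,
                    "day": t,
                    "value": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("tbarskinetics.data").joinpath(name)


def load_assay_fixture() -> list[AssayRecord]:
    """Antioxidant capacity (TEAC by DPPH) and total phenolics per extract."""
    with resources.as_file(_data_path("extract_assays.csv")) as p:
        df = pd.read_csv(p)
    return [
        AssayRecord(extract=r.extract, teac_dpph=float(r.teac_dpph), tpc=float(r.tpc))
        for r in df.itertuples()
    ]


def load_secondary_fixture() -> dict[str, SecondaryParameters]:
    """Published per-group rate constants and secondary-model parameters.

    Rates are keyed by the integer kelvins 277/281/289/293 used in the source
    table for the nominal 4/8/16/20 degC conditions.
    """
    with resources.as_file(_data_path("secondary_parameters.csv")) as p:
        df = pd.read_csv(p)
    out: dict[str, SecondaryParameters] = {}
    for r in df.itertuples():
        out[r.sample] = SecondaryParameters(
            sample_label=r.sample,
            k_by_temperature={
                277.0: float(r.k277),
                281.0: float(r.k281),
                289.0: float(r.k289),
                293.0: float(r.k293),
            },
            ea=float(r.ea),
            k0=float(r.k0),
            c=float(r.c),
            tc=float(r.tc),
            ea_sd=float(r.ea_sd),
            k0_sd=float(r.k0_sd),
        )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


_SCHEMA_VERSION = 1


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(path: str | Path, payload: Any) -> None:
    """Serialize a result record (dataclass, dict or list) to a JSON document."""
    doc = {"schema_version": _SCHEMA_VERSION, "payload": _to_jsonable(payload)}
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> Any:
    """Read a JSON result document written by `write_results` (as plain data)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {doc.get('schema_version')}")
    return doc["payload"]
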