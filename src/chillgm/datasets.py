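"""Bundled carcass-chilling surveillance datasets and their loading rules.

Three datasets ship with the package, all recorded at a single Japanese
slaughterhouse over one operating year (April 2016 - March 2017) under the
HACCP daily-report system:

``beef``
    44 complete data units, 8 continuous surveillance variables.
``pork``
    44 complete data units, 10 continuous surveillance variables.
``seasonal``
    12 monthly facility-level records (electricity, operating days, outside
    temperature, throughput) used for a seasonal-fluctuation correlation
    check.

Each daily record ("data unit") is one row; a row with any blank entry is
excluded wholesale as a missing value, so a loaded dataset is always a
complete numeric matrix.  Variables carry a three-tier layer label -- cause,
intermediate effect, effect -- that supplies edge direction in the final
path diagram; the seasonal variables have no layer structure.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataUnit",
    "VariableSpec",
    "LayeredDataset",
    "SeasonalRecord",
    "DatasetParseError",
    "load_dataset",
    "load_seasonal_records",
    "read_dataset",
    "clock_to_decimal",
    "standardize_carcass_volume",
    "FIXTURE_NAMES",
]

LAYERS = ("cause", "intermediate", "effect")
LAYER_RANK = {"cause": 1, "intermediate": 2, "effect": 3}

FIXTURE_NAMES = ("beef", "pork", "seasonal")


class DatasetParseError(ValueError):
    """A fixture or user CSV contained a token that is neither numeric nor blank."""

    def __init__(self, message: str, row: int, column: int):
        super().__init__(f"{message} (row {row}, column {column})")
        self.row = row
        self.column = column


@dataclass(frozen=True)
class VariableSpec:
    """One surveillance variable: machine name, physical unit, causal layer.

    ``layer`` is one of ``"cause"``, ``"intermediate"``, ``"effect"`` or
    ``None`` for variables outside the layered analysis (seasonal data).
    """

    name: str
    unit: str
    layer: Optional[str] = None

    def __post_init__(self):
        if self.layer is not None and self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r} for variable {self.name!r}")

    @property
    def rank(self) -> Optional[int]:
        return LAYER_RANK[self.layer] if self.layer is not None else None


@dataclass(frozen=True)
class DataUnit:
    """One daily record: sample id plus one value (or ``None``) per variable."""

    sample_id: str
    values: tuple

    @property
    def is_complete(self) -> bool:
        return all(v is not None for v in self.values)


@dataclass
class LayeredDataset:
    """A complete numeric sample matrix with per-variable names, units, layers."""

    variables: list
    samples: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.variables):
            raise ValueError("sample matrix shape does not match variable count")
        if len(self.sample_ids) != self.samples.shape[0]:
            raise ValueError("sample_ids length does not match sample count")
        if np.isnan(self.samples).any():
            raise ValueError("a LayeredDataset must not contain missing entries")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def p(self) -> int:
        return self.samples.shape[1]

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.variables]

    @property
    def has_layers(self) -> bool:
        return all(v.layer is not None for v in self.variables)

    def layer_ranks(self) -> dict:
        """Map variable name -> layer rank (1 cause, 2 intermediate, 3 effect)."""
        if not self.has_layers:
            raise ValueError("dataset has variables without a layer assignment")
        return {v.name: v.rank for v in self.variables}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, index=self.sample_ids, columns=self.variable_names)

    def to_csv(self) -> str:
        """Round-trippable CSV rendering in the same dialect ``read_dataset`` reads."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["sample_id", *self.variable_names])
        for sid, row in zip(self.sample_ids, self.samples):
            writer.writerow([sid, *(_format_number(v) for v in row)])
        return buf.getvalue()


@dataclass(frozen=True)
class SeasonalRecord:
    """One month of facility-level operation data.

    ``carcass_volume`` expresses total throughput in pork-equivalent head:
    one beef carcass counts as four pork carcasses.
    """

    month: str
    electric_consumption: float  # kWh
    operating_days: int          # days
    outside_temp: float          # deg C, monthly mean of daily maxima
    beef_carcasses: int          # head
    pork_carcasses: int          # head
    carcass_volume: int          # head, pork-equivalent

    def __post_init__(self):
        expected = standardize_carcass_volume(self.beef_carcasses, self.pork_carcasses)
        if expected != self.carcass_volume:
            raise ValueError(
                f"{self.month}: carcass_volume {self.carcass_volume} != "
                f"4*beef + pork = {expected}"
            )


def clock_to_decimal(hours: int, minutes: int) -> float:
    """Convert a clock time to a continuous variable as hh + mm/60.

    >>> clock_to_decimal(12, 30)
    12.5
    """
    if not (0 <= hours <= 23):
        raise ValueError(f"hours out of range: {hours}")
    if not (0 <= minutes <= 59):
        raise ValueError(f"minutes out of range: {minutes}")
    return hours + minutes / 60.0


def standardize_carcass_volume(beef: int, pork: int) -> int:
    """Total carcass throughput in pork-equivalent head (one beef = four pork)."""
    if beef < 0 or pork < 0:
        raise ValueError("carcass counts must be non-negative")
    return 4 * beef + pork


# Layer assignments and units for the two layered fixtures.
_BEEF_VARIABLES = [
    VariableSpec("Outside_temp", "degC", "cause"),
    VariableSpec("Outside_humidity", "%", "cause"),
    VariableSpec("Carcass_in_the_day", "head", "cause"),
    VariableSpec("Loading_completion", "clock time", "intermediate"),
    VariableSpec("Preset_temp", "degC", "intermediate"),
    VariableSpec("Room_temp_at_16_30", "degC", "intermediate"),
    VariableSpec("Room_temp_next_8_00", "degC", "intermediate"),
    VariableSpec("Surface_temp", "degC", "effect"),
]

_PORK_VARIABLES = [
    VariableSpec("Outside_temp", "degC", "cause"),
    VariableSpec("Outside_humidity", "%", "cause"),
    VariableSpec("Carcass_in_the_day", "head", "cause"),
    VariableSpec("Carcass_after_noon", "head", "intermediate"),
    VariableSpec("Loading_completion", "clock time", "intermediate"),
    VariableSpec("Preset_temp", "degC", "intermediate"),
    VariableSpec("Room_temp_at_16_30", "degC", "intermediate"),
    VariableSpec("Room_temp_next_8_00", "degC", "intermediate"),
    VariableSpec("Surface_temp", "degC", "effect"),
    VariableSpec("Core_temp", "degC", "effect"),
]

_SEASONAL_VARIABLES = [
    VariableSpec("Electric_consumption", "kWh", None),
    VariableSpec("Operating_days", "day", None),
    VariableSpec("Outside_temperature", "degC", None),
    VariableSpec("Carcass_volume", "head", None),
]

_FIXTURE_VARIABLES = {
    "beef": _BEEF_VARIABLES,
    "pork": _PORK_VARIABLES,
    "seasonal": _SEASONAL_VARIABLES,
}


def _fixture_text(name: str) -> str:
    return resources.files("chillgm.data").joinpath(f"{name}.csv").read_text()


def _parse_cell(token: str, row: int, col: int):
    token = token.strip()
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise DatasetParseError(f"non-numeric token {token!r}", row, col) from None


def _format_number(v: float) -> str:
    return f"{v:g}"


def read_dataset(source, variables: Optional[Sequence[VariableSpec]] = None) -> LayeredDataset:
    """Parse a dataset CSV (path or text) into a :class:`LayeredDataset`.

    The dialect is: header row ``sample_id,<var>,<var>,...``; one data unit
    per row; blank cells mark missing values.  Data units containing a
    missing value are excluded.  Any non-numeric, non-blank token raises
    :class:`DatasetParseError` with its row/column location.

    ``variables`` supplies units and layer labels; when omitted, variables
    are taken from the header with unknown units and no layers.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    rows = list(csv.reader(io.StringIO(text)))
    if not rows:
        raise DatasetParseError("empty file", 1, 1)
    header = [h.strip() for h in rows[0]]
    if len(header) < 2:
        raise DatasetParseError("header must name sample_id plus at least one variable", 1, 1)
    names = header[1:]
    if variables is None:
        variables = [VariableSpec(name, "unknown", None) for name in names]
    else:
        variables = list(variables)
        if [v.name for v in variables] != names:
            raise DatasetParseError(
                f"header {names} does not match expected variables "
                f"{[v.name for v in variables]}", 1, 1,
            )
    units = []
    for irow, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise DatasetParseError(
                f"expected {len(header)} fields, found {len(row)}", irow, 1
            )
        values = tuple(
            _parse_cell(tok, irow, icol) for icol, tok in enumerate(row[1:], start=2)
        )
        units.append(DataUnit(row[0].strip(), values))
    complete = [u for u in units if u.is_complete]
    samples = np.array([u.values for u in complete], dtype=float).reshape(len(complete), len(names))
    return LayeredDataset(variables, samples, [u.sample_id for u in complete])


def load_dataset(fixture_name: str) -> LayeredDataset:
    """Load a bundled dataset: ``"beef"``, ``"pork"`` or ``"seasonal"``.

    Incomplete data units are dropped.  The seasonal fixture is reduced to
    its four analysis variables (electricity, operating days, outside
    temperature, pork-equivalent carcass volume); use
    :func:`load_seasonal_records` for the full monthly records.
    """
    if fixture_name not in FIXTURE_NAMES:
        raise KeyError(
            f"unavailable dataset {fixture_name!r}; bundled fixtures are {FIXTURE_NAMES}"
        )
    text = _fixture_text(fixture_name)
    if fixture_name == "seasonal":
        frame = pd.read_csv(io.StringIO(text), index_col=0)
        cols = [v.name for v in _SEASONAL_VARIABLES]
        return LayeredDataset(
            list(_SEASONAL_VARIABLES),
            frame[cols].to_numpy(dtype=float),
            list(frame.index),
        )
    return read_dataset(text, _FIXTURE_VARIABLES[fixture_name])


def load_seasonal_records() -> list:
    """The 12 monthly facility records, with the 4:1 volume invariant checked."""
    frame = pd.read_csv(io.StringIO(_fixture_text("seasonal")), index_col=0)
    records = []
    for month, row in frame.iterrows():
        records.append(
            SeasonalRecord(
                month=month,
                electric_consumption=float(row["Electric_consumption"]),
                operating_days=int(row["Operating_days"]),
                outside_temp=float(row["Outside_temperature"]),
                beef_carcasses=int(row["Beef_carcass"]),
                pork_carcasses=int(row["Pork_carcass"]),
                carcass_volume=int(row["Carcass_volume"]),
            )
        )
    return records
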