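"""Delimited-text readers/writers for concentration and response tables.

Schemas (documented in ``schema.md`` shipped with the package):

concentration table
    substance, matrix, animal_id, group, day, time_h, value, censored
response table (adds)
    role in {blank, calibrator, qc, sample}, nominal_conc

Readers validate rather than coerce: unknown matrices, missing columns,
non-numeric values and duplicated (substance, matrix, animal, day, time)
keys are all rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panel import MATRICES

__all__ = [
    "ConcentrationSeries",
    "CONCENTRATION_COLUMNS",
    "RESPONSE_COLUMNS",
    "SchemaError",
    "read_concentration_table",
    "write_concentration_table",
    "series_to_frame",
    "frame_to_series",
]

CONCENTRATION_COLUMNS = [
    "substance", "matrix", "animal_id", "group", "day", "time_h", "value", "censored",
]
RESPONSE_COLUMNS = CONCENTRATION_COLUMNS[:-2] + ["role", "nominal_conc", "response_ratio"]

GROUPS = ("vehicle", "half", "one", "two")


class SchemaError(ValueError):
    """A table violates the documented schema."""


@dataclass
class ConcentrationSeries:
    """Timestamped values for one substance x matrix x animal.

    Samples are (day, time_h, value, censored) sorted by (day, time_h);
    censored samples carry value 0 with the flag set.
    """

    substance: str
    matrix: str
    animal_id: str
    group: str
    samples: list[tuple[int, float, float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise SchemaError(f"unknown matrix {self.matrix!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r}")
        keys = [(d, t) for d, t, _, _ in self.samples]
        if keys != sorted(keys):
            self.samples.sort(key=lambda s: (s[0], s[1]))
            keys.sort()
        if len(set(keys)) != len(keys):
            raise SchemaError(
                f"duplicated (day, time) key in {self.substance}/{self.matrix}/{self.animal_id}"
            )
        for d, t, v, c in self.samples:
            if c and v != 0:
                raise SchemaError("censored samples must carry value 0")


def series_to_frame(series: list[ConcentrationSeries]) -> pd.DataFrame:
    rows = [
        (s.substance, s.matrix, s.animal_id, s.group, d, t, v, bool(c))
        for s in series
        for d, t, v, c in s.samples
    ]
    return pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS)


def frame_to_series(frame: pd.DataFrame) -> list[ConcentrationSeries]:
    _check_columns(frame, CONCENTRATION_COLUMNS)
    out: list[ConcentrationSeries] = []
    if frame.empty:
        return out
    for (sub, mat, animal, grp), g in frame.groupby(
        ["substance", "matrix", "animal_id", "group"], sort=True
    ):
        samples = [
            (int(r.day), float(r.time_h), float(r.value), bool(r.censored))
            for r in g.itertuples()
        ]
        out.append(ConcentrationSeries(str(sub), str(mat), str(animal), str(grp), samples))
    return out


def _check_columns(frame: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _numeric(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    frame = frame.copy()
    for c in cols:
        vals = pd.to_numeric(frame[c], errors="coerce")
        bad = vals.isna() & frame[c].notna()
        if bad.any():
            raise SchemaError(f"non-numeric value in column {c!r}: {frame.loc[bad, c].iloc[0]!r}")
        if vals.isna().any():
            raise SchemaError(f"empty value in column {c!r}")
        frame[c] = vals
    return frame


def read_concentration_table(path: str | Path) -> list[ConcentrationSeries]:
    """Read a concentration CSV into typed series, validating the schema."""
    frame = pd.read_csv(path, dtype={"animal_id": str, "substance": str},
                        float_precision="round_trip")
    _check_columns(frame, CONCENTRATION_COLUMNS)
    frame = _numeric(frame, ["day", "time_h", "value"])
    bad_matrix = set(frame["matrix"]) - set(MATRICES)
    if bad_matrix:
        raise SchemaError(f"unknown matrix name(s): {sorted(bad_matrix)}")
    frame["censored"] = frame["censored"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
    )
    if frame["censored"].isna().any():
        raise SchemaError("censored column must be boolean")
    return frame_to_series(frame)


def write_concentration_table(series: list[ConcentrationSeries], path: str | Path) -> None:
    """Write series to CSV; read(write(x)) round-trips values exactly."""
    frame = series_to_frame(series)
    # default float repr is the shortest round-trip representation
    frame.to_csv(path, index=False)
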