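"""Packaged study tables and generic CSV plumbing for kinetic rate tables.

The three measurement tables of the study ship as CSV fixtures inside the
package (``data/``):

* ``table1_rates.csv`` — apparent (k) and speciation-corrected (k1)
  second-order rate constants for eight para-substituted benzenediazonium
  cations at pH 1 and 2, with Hammett sigma_p / sigma_p+ constants and Mayr
  electrophilicities E, plus deuterio values where measured.
* ``table2_nucleophiles.csv`` — rate constants of seven pi-excess
  C-nucleophiles toward the reference superelectrophile
  4,6-dinitrobenzofuroxan (E = -5.06) and the nucleophilicity parameters N
  estimated from them.
* ``table3_predictions.csv`` — experimental vs calculated rate constants of
  three 3-substituted thiophenes with 4,6-dinitrobenzotriazole (E = -9.56).

All rate constants are in M^-1 s^-1 throughout; no unit conversion layer.
Empty CSV cells mean "not measured / not tabulated" and load as ``None``.

``read_rate_table`` / ``write_rate_table`` give a lossless, case-insensitive
round trip for user-supplied tables in the same column vocabulary.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, fields
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .records import ElectrophileRecord, NucleophileRecord, PredictionRecord

__all__ = [
    "load_table1",
    "load_table2",
    "load_table3",
    "load_substituent_constants",
    "read_rate_table",
    "write_rate_table",
    "RATE_TABLE_COLUMNS",
]

#: Canonical column vocabulary for electrophile rate tables (header matching
#: is case-insensitive on read; this casing is used on write).
RATE_TABLE_COLUMNS = tuple(f.name for f in fields(ElectrophileRecord))

_TEXT_COLUMNS = frozenset({"label", "substituent", "name", "nucleophile_name"})


class FixtureError(RuntimeError):
    """A packaged data fixture is missing or corrupt."""


def _fixture_path(name: str) -> Path:
    path = resources.files("nucleokin.data").joinpath(name)
    try:
        with resources.as_file(path) as p:
            if not p.exists():
                raise FileNotFoundError(p)
            return p
    except FileNotFoundError as exc:
        raise FixtureError(f"packaged fixture {name!r} is missing") from exc


def _parse_cell(column: str, raw: str, row_index: int):
    raw = raw.strip()
    if column in _TEXT_COLUMNS:
        return raw
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValueError(
            f"non-numeric value {raw!r} in column {column!r}, data row {row_index}"
        ) from exc


def _read_records(path, record_type, required: Sequence[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        canonical = {f.name.lower(): f.name for f in fields(record_type)}
        header_map = {}
        for col in reader.fieldnames:
            key = col.strip().lower()
            if key in canonical:
                header_map[col] = canonical[key]
        for col in required:
            if col not in header_map.values():
                raise ValueError(f"{path}: missing required column {col!r}")
        records = []
        for i, row in enumerate(reader):
            kwargs = {
                header_map[col]: _parse_cell(header_map[col], (row[col] or ""), i)
                for col in header_map
            }
            records.append(record_type(**kwargs))
    return records


def load_table1() -> list[ElectrophileRecord]:
    """The eight diazonium electrophiles with their rate constants.

    Returns the records in table order (labels 7a-7h). 7d carries no Mayr
    electrophilicity; only 7a, 7c and 7g carry deuterio rate constants.
    """
    path = _fixture_path("table1_rates.csv")
    try:
        records = _read_records(path, ElectrophileRecord, ("label", "substituent"))
    except (ValueError, TypeError) as exc:
        raise FixtureError(f"fixture table1_rates.csv is corrupt: {exc}") from exc
    if len(records) != 8 or len({r.label for r in records}) != 8:
        raise FixtureError("fixture table1_rates.csv must hold records 7a-7h exactly once")
    return records


def load_table2() -> list[NucleophileRecord]:
    """The seven reference nucleophiles benchmarked against DNBF (E = -5.06)."""
    path = _fixture_path("table2_nucleophiles.csv")
    try:
        return _read_records(path, NucleophileRecord, ("name",))
    except (ValueError, TypeError) as exc:
        raise FixtureError(f"fixture table2_nucleophiles.csv is corrupt: {exc}") from exc


def load_table3() -> list[PredictionRecord]:
    """Experimental vs predicted rates with 4,6-dinitrobenzotriazole."""
    path = _fixture_path("table3_predictions.csv")
    try:
        return _read_records(path, PredictionRecord, ("nucleophile_name",))
    except (ValueError, TypeError) as exc:
        raise FixtureError(f"fixture table3_predictions.csv is corrupt: {exc}") from exc


def load_substituent_constants() -> dict[str, dict[str, Optional[float]]]:
    """Hammett sigma_p / sigma_p+ per substituent, keyed by substituent label."""
    path = _fixture_path("substituent_constants.csv")
    out: dict[str, dict[str, Optional[float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            out[row["substituent"]] = {
                "sigma_p": _parse_cell("sigma_p", row["sigma_p"] or "", i),
                "sigma_p_plus": _parse_cell("sigma_p_plus", row["sigma_p_plus"] or "", i),
            }
    return out


def read_rate_table(
    path: Union[str, Path],
    schema: type = ElectrophileRecord,
    required: Sequence[str] = ("label",),
) -> list:
    """Read a rate table CSV into ``schema`` records.

    Column names are matched case-insensitively against the schema's field
    names; empty cells become ``None``. Raises ``ValueError`` naming the
    column when a required one is missing, and naming the row index when a
    numeric cell fails to parse.
    """
    return _read_records(Path(path), schema, required)


def write_rate_table(records: Sequence, path: Union[str, Path]) -> Path:
    """Write records to CSV losslessly (floats via ``repr``, full precision).

    ``write_rate_table(records, p)`` followed by ``read_rate_table(p)``
    reproduces the records exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    cols = [f.name for f in fields(type(records[0]))]
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            d = asdict(rec)
            writer.writerow(
                ["" if d[c] is None else (d[c] if c in _TEXT_COLUMNS else repr(float(d[c])))
                 for c in cols]
            )
    return path
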