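"""Reading and writing EMA record files and study configurations.

Record files are delimited text (comma by default, tab accepted), UTF-8,
one header row, one row per assessment.  Columns: ``participant``,
``group``, ``phase``, one column per situation dimension and one per
attribute.  Ratings are stored by response *label* in files and converted
to 1-based ordinal indices in memory; an empty cell is a missing rating.
The participant->group assignment may come from the ``group`` column or
from per-group subdirectories; the column wins on conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .frame import ConfigurationError, EmaDataset, EmaFrame, EmaRecord

__all__ = ["FileDialect", "load_dataset", "write_dataset", "read_config", "write_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FileDialect:
    """Column naming and separator conventions for record files."""

    sep: str = ","
    participant_col: str = "participant"
    group_col: str = "group"
    phase_col: str = "phase"
    suffix: str = ".csv"


class DatasetError(ValueError):
    """Raised when a directory yields no valid EMA records."""


def _iter_record_files(directory: Path, dialect: FileDialect):
    """Yield (file, group-from-subdirectory-or-None) pairs."""
    for path in sorted(directory.rglob(f"*{dialect.suffix}")) + sorted(
        directory.rglob("*.tsv") if dialect.suffix != ".tsv" else []
    ):
        rel = path.relative_to(directory)
        subdir_group = rel.parts[0] if len(rel.parts) > 1 else None
        yield path, subdir_group


def load_dataset(
    directory: str | Path,
    frame: EmaFrame,
    dialect: FileDialect = FileDialect(),
) -> EmaDataset:
    """Load and validate all EMA record files under ``directory``.

    Every malformed row is rejected with a logged ``file:row`` diagnostic;
    the full list is attached to the returned dataset as
    ``dataset.load_diagnostics``.  Missing ratings are preserved as
    missing, never imputed.

    Raises
    ------
    DatasetError
        If the directory contains no valid records at all.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DatasetError(f"data directory not found: {directory}")
    records: list[EmaRecord] = []
    diagnostics: list[str] = []
    n_files = 0
    for path, subdir_group in _iter_record_files(directory, dialect):
        n_files += 1
        sep = "\t" if path.suffix == ".tsv" else dialect.sep
        try:
            table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        except Exception as e:  # unparseable file: diagnose, continue
            diagnostics.append(f"{path}: unreadable ({e})")
            continue
        known = (
            {dialect.participant_col, dialect.group_col, dialect.phase_col}
            | set(frame.situation_dims)
            | set(frame.attributes)
        )
        extra = [c for c in table.columns if c not in known]
        if extra:
            log.warning("%s: ignoring unknown column(s) %s", path, extra)
        for idx, row in enumerate(table.itertuples(index=False), start=2):
            row = dict(zip(table.columns, row))
            try:
                records.append(_parse_row(row, frame, dialect, path, subdir_group))
            except (ValueError, KeyError) as e:
                diagnostics.append(f"{path}:{idx}: {e}")
    if n_files == 0:
        raise DatasetError(f"no record files (*{dialect.suffix}) under {directory}")
    for msg in diagnostics:
        log.warning("rejected record: %s", msg)
    if not records:
        raise DatasetError(
            f"no valid records under {directory} "
            f"({len(diagnostics)} rejected; first: {diagnostics[0] if diagnostics else 'n/a'})"
        )
    dataset = EmaDataset(frame, records)
    dataset.load_diagnostics = diagnostics  # type: ignore[attr-defined]
    return dataset


def _parse_row(
    row: dict, frame: EmaFrame, dialect: FileDialect, path: Path, subdir_group: str | None
) -> EmaRecord:
    pid = row.get(dialect.participant_col) or path.stem
    group = row.get(dialect.group_col) or subdir_group or frame.groups[0]
    if dialect.phase_col in row:
        phase = row[dialect.phase_col]
    elif frame.n_phases == 1:
        phase = frame.phases[0]
    else:
        raise ValueError(f"missing phase column {dialect.phase_col!r}")
    situation = {}
    for dim in frame.situation_dims:
        if dim not in row:
            raise ValueError(f"missing situation column {dim!r}")
        situation[dim] = row[dim]
    ratings: dict[str, int | None] = {}
    for attr, scale in frame.attributes.items():
        raw = row.get(attr, "")
        if raw == "" or raw is None:
            ratings[attr] = None
        else:
            try:
                ratings[attr] = scale.index(raw) + 1
            except ValueError:
                raise ValueError(
                    f"rating label {raw!r} not in scale of attribute {attr!r}"
                ) from None
    return EmaRecord.validate(frame, pid, group, phase, situation, ratings)


def write_dataset(
    dataset: EmaDataset,
    directory: str | Path,
    dialect: FileDialect = FileDialect(),
) -> list[Path]:
    """Write one record file per participant; inverse of :func:`load_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = dataset.frame
    written = []
    for pid in dataset.participants:
        rows = []
        for rec in dataset.records_of(pid):
            row = {
                dialect.participant_col: rec.participant_id,
                dialect.group_col: rec.group,
                dialect.phase_col: rec.phase,
            }
            row.update(dict(zip(frame.situation_dims, rec.situation)))
            for attr, scale in frame.attributes.items():
                v = rec.ratings.get(attr)
                row[attr] = "" if v is None else scale[v - 1]
            rows.append(row)
        path = directory / f"{_safe_name(pid)}{dialect.suffix}"
        pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)
        written.append(path)
    return written


def _safe_name(pid: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in str(pid))


def read_config(path: str | Path) -> dict:
    """Read a structured study configuration (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"configuration file {path} is not a mapping")
    return config


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
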