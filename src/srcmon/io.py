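"""Delimited-text I/O for frequency tables, trial records, configs and reports.

All tabular formats are plain comma-separated text with a header row.
Frequency tables use the layout::

    trial_type,resp_expected,resp_unexpected,resp_new
    expected,1632,248,424
    ...

2AFC tables omit the ``resp_new`` column (there is no "new" option in the
source-attribution task).  Malformed rows are rejected with the offending
line number.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from srcmon.mpt import TRIAL_TYPES, FrequencyTable, MPTDomainError

FREQ_COLUMNS_3AFC = ["trial_type", "resp_expected", "resp_unexpected", "resp_new"]
FREQ_COLUMNS_2AFC = ["trial_type", "resp_expected", "resp_unexpected"]

TRIAL_COLUMNS = [
    "participant",
    "group",
    "phase",
    "item",
    "source",
    "expectancy",
    "response",
    "jos",
    "restudy_choice",
    "restudied",
]


class FileFormatError(ValueError):
    """A file does not follow the declared delimited-text schema."""


def read_frequency_table(path: str | Path, label: str | None = None) -> FrequencyTable:
    """Read a 3AFC or 2AFC frequency table; the task is inferred from columns."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header == FREQ_COLUMNS_3AFC:
            task, n_resp, types = "3afc", 3, TRIAL_TYPES
        elif header == FREQ_COLUMNS_2AFC:
            task, n_resp, types = "2afc", 2, TRIAL_TYPES[:2]
        else:
            raise FileFormatError(
                f"{path}: line 1: unrecognized header {header!r} "
                f"(expected {FREQ_COLUMNS_3AFC} or {FREQ_COLUMNS_2AFC})"
            )
        counts = np.zeros((len(types), n_resp), dtype=np.int64)
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != n_resp + 1:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected {n_resp + 1} fields, "
                    f"got {len(fields)}"
                )
            ttype = fields[0]
            if ttype not in types:
                raise FileFormatError(
                    f"{path}: line {lineno}: unknown trial type {ttype!r}"
                )
            if ttype in seen:
                raise FileFormatError(
                    f"{path}: line {lineno}: duplicate trial type {ttype!r}"
                )
            seen.add(ttype)
            try:
                row = [int(v) for v in fields[1:]]
            except ValueError:
                raise FileFormatError(
                    f"{path}: line {lineno}: non-integer count in {fields[1:]!r}"
                ) from None
            if any(v < 0 for v in row):
                raise FileFormatError(f"{path}: line {lineno}: negative count")
            counts[types.index(ttype)] = row
        missing = set(types) - seen
        if missing:
            raise FileFormatError(f"{path}: missing trial type rows {sorted(missing)}")
    try:
        return FrequencyTable(counts, label=label or path.stem, task=task)
    except MPTDomainError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    path = Path(path)
    if table.task == "3afc":
        header, types = FREQ_COLUMNS_3AFC, TRIAL_TYPES
    else:
        header, types = FREQ_COLUMNS_2AFC, TRIAL_TYPES[:2]
    lines = [",".join(header)]
    for i, ttype in enumerate(types):
        lines.append(",".join([ttype] + [str(int(v)) for v in table.counts[i]]))
    path.write_text("\n".join(lines) + "\n")


def load_reference_frequencies() -> dict[str, FrequencyTable]:
    """The packaged reference dataset: aggregate response frequencies from the
    two-group judgment-timing experiment (72 participants and 32 items per
    trial type in each group).

    Keys: ``immediate_3afc``, ``delayed_3afc``, ``delayed_2afc``.
    """
    out: dict[str, FrequencyTable] = {}
    pkg = resources.files("srcmon.data")
    for key, fname in [
        ("immediate_3afc", "reference_immediate_3afc.csv"),
        ("delayed_3afc", "reference_delayed_3afc.csv"),
        ("delayed_2afc", "reference_delayed_2afc.csv"),
    ]:
        with resources.as_file(pkg / fname) as path:
            out[key] = read_frequency_table(path, label=key)
    return out


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-record file, validating the required columns."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
        df = df[TRIAL_COLUMNS]
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FileFormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping for provenance stamping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_rows_csv(rows: Iterable[dict], path: str | Path) -> None:
    """Write a list of homogeneous dict rows as CSV."""
    pd.DataFrame(list(rows)).to_csv(path, index=False)
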