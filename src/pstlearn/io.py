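"""File formats: trial-log CSV, traits CSV, fit-result TSV, YAML configs.

Trial logs are UTF-8 comma-separated files with mandatory header
``participant_id,phase,block,trial,pair,chosen,outcome``; the outcome field
is empty on test-phase trials (no feedback is given) and on non-responses.
Validation reports the offending row number.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cohort import CohortConfig
from .task import (
    NOVEL_PAIRS,
    SYMBOLS,
    TRAINED_PAIRS,
    PairSpec,
    TaskConfig,
    TrialRecord,
)

__all__ = [
    "TrialLogError",
    "TRIAL_LOG_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "read_trial_log",
    "write_trial_log",
    "read_traits",
    "write_traits",
    "write_fit_table",
    "read_fit_table",
    "split_cohort",
    "load_task_config",
    "load_cohort_config",
    "dump_config",
]

TRIAL_LOG_COLUMNS = (
    "participant_id", "phase", "block", "trial", "pair", "chosen", "outcome",
)

_VALID_PAIRS = set(TRAINED_PAIRS) | set(NOVEL_PAIRS)


class TrialLogError(ValueError):
    """Malformed trial log; the message names the file and row."""


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records -> trial-log DataFrame (orientation preserved in
    ``pair`` as first+second)."""
    rows = [
        {
            "participant_id": t.participant_id,
            "phase": t.phase,
            "block": "" if t.block_index is None else t.block_index,
            "trial": t.trial_index,
            "pair": t.pair.first + t.pair.second,
            "chosen": "" if t.chosen is None else t.chosen,
            "outcome": "" if t.outcome is None else t.outcome,
        }
        for t in records
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS))


def _parse_row(row: Mapping, where: str) -> TrialRecord:
    pair_str = str(row["pair"])
    key = "".join(sorted(pair_str))
    if len(pair_str) != 2 or key not in _VALID_PAIRS:
        raise TrialLogError(f"{where}: invalid pair {pair_str!r}")
    role = "trained" if key in TRAINED_PAIRS else "novel"
    phase = str(row["phase"])
    if phase not in ("training", "test"):
        raise TrialLogError(f"{where}: invalid phase {phase!r}")
    chosen_raw = row["chosen"]
    chosen = None if pd.isna(chosen_raw) or chosen_raw == "" else str(chosen_raw)
    if chosen is not None and chosen not in SYMBOLS:
        raise TrialLogError(f"{where}: invalid symbol {chosen!r}")
    out_raw = row["outcome"]
    if pd.isna(out_raw) or out_raw == "":
        outcome = None
    else:
        try:
            outcome = int(out_raw)
        except (TypeError, ValueError):
            outcome = -1
        if outcome not in (0, 1):
            raise TrialLogError(
                f"{where}: outcome must be 0, 1 or empty, got {out_raw!r}"
            )
    block_raw = row["block"]
    block = None if pd.isna(block_raw) or block_raw == "" else int(block_raw)
    try:
        return TrialRecord(
            participant_id=str(row["participant_id"]),
            phase=phase,
            block_index=block,
            trial_index=int(row["trial"]),
            pair=PairSpec(pair_str[0], pair_str[1], role),
            chosen=chosen,
            outcome=outcome,
        )
    except ValueError as exc:
        raise TrialLogError(f"{where}: {exc}") from exc


def frame_to_records(frame: pd.DataFrame, source: str = "trial log") -> list[TrialRecord]:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"{source}: missing columns {missing}")
    records = []
    for i, row in enumerate(frame.to_dict("records")):
        records.append(_parse_row(row, f"{source}, row {i + 2}"))
    return records


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; returns the DataFrame (validated
    row by row — use :func:`frame_to_records` for TrialRecord objects)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != list(TRIAL_LOG_COLUMNS):
        raise TrialLogError(
            f"{path}: expected header {','.join(TRIAL_LOG_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    frame_to_records(frame, str(path))
    return frame


def write_trial_log(
    data: pd.DataFrame | Sequence[TrialRecord], path: str | Path
) -> None:
    frame = data if isinstance(data, pd.DataFrame) else records_to_frame(data)
    frame.to_csv(path, index=False, encoding="utf-8")


def split_cohort(
    frame: pd.DataFrame,
) -> dict[str, tuple[list[TrialRecord], list[TrialRecord]]]:
    """Trial-log DataFrame -> {participant_id: (train, test)} record lists,
    each ordered by trial index."""
    out: dict[str, tuple[list[TrialRecord], list[TrialRecord]]] = {}
    for pid, grp in frame.groupby("participant_id", sort=True):
        records = frame_to_records(grp)
        train = sorted(
            (t for t in records if t.phase == "training"),
            key=lambda t: t.trial_index,
        )
        test = sorted(
            (t for t in records if t.phase == "test"), key=lambda t: t.trial_index
        )
        out[str(pid)] = (train, test)
    return out


def read_traits(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["participant_id"] = frame["participant_id"].astype(str)
    return frame


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False, encoding="utf-8")


def write_fit_table(fits: pd.DataFrame, path: str | Path) -> None:
    fits.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_fit_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["participant_id"] = frame["participant_id"].astype(str)
    if "at_bound" in frame.columns:
        frame["at_bound"] = frame["at_bound"].fillna("")
    if "error" in frame.columns:
        frame["error"] = frame["error"].fillna("")
    return frame


def load_task_config(source: str | Path | Mapping) -> TaskConfig:
    data = _load_mapping(source, key="task")
    return TaskConfig(**data)


def load_cohort_config(source: str | Path | Mapping) -> CohortConfig:
    data = _load_mapping(source, key="cohort")
    for name, value in data.items():
        if isinstance(value, list):
            data[name] = tuple(value)
    return CohortConfig(**data)


def _load_mapping(source: str | Path | Mapping, key: str) -> dict:
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if key in data and isinstance(data[key], Mapping):
        data = dict(data[key])
    return data


def dump_config(config: TaskConfig | CohortConfig, path: str | Path) -> None:
    data = asdict(config)
    if isinstance(config, TaskConfig):
        data["contingencies"] = dict(data["contingencies"])
        data = {"task": data}
    else:
        data = {"cohort": data}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
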