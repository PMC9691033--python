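"""Canonical session CSV format: lossless, validated, inspectable.

Columns: ``day_id, block_index, trial_in_block, rule, color_morph,
shape_morph, action, reward`` plus optional ``latent_*`` ground-truth
columns. Morph levels are stored as percentages; angles are always derived,
never stored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from ruleswitch.synthetic import LATENT_COLUMNS, SESSION_COLUMNS, SessionTable, as_frame


class SessionFormatError(ValueError):
    """A session file violated the canonical layout; the message names the first bad row."""


_VALID_RULES = {"R1", "R2", "R3"}
_VALID_ACTIONS = {"UL", "UR", "LL", "LR"}


def write_session(table: Union[SessionTable, pd.DataFrame], path) -> None:
    """Write a session table to CSV (UTF-8, header, no index)."""
    frame = as_frame(table)
    header_meta = ""
    if isinstance(table, SessionTable) and table.config_hash:
        header_meta = f"# config_hash={table.config_hash} seed={table.seed}\n"
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header_meta)
        frame.to_csv(fh, index=False)


def read_session(path) -> SessionTable:
    """Read and validate a canonical session CSV.

    Raises :class:`SessionFormatError` naming the first offending row for
    missing columns, bad enum values, out-of-range rewards, or
    non-contiguous 1-based trial numbering within a block.
    """
    path = Path(path)
    config_hash, seed = "", None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            tokens = dict(
                part.split("=", 1) for part in first.lstrip("#").split() if "=" in part
            )
            config_hash = tokens.get("config_hash", "")
            seed = int(tokens["seed"]) if tokens.get("seed", "None") not in ("None", "") else None
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    if frame.empty:
        raise SessionFormatError(f"{path}: no trials")
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing required columns {missing}")

    def first_bad(mask) -> int:
        return int(np.flatnonzero(np.asarray(mask))[0]) + 2  # 1-based + header line

    bad = ~frame["rule"].astype(str).isin(_VALID_RULES)
    if bad.any():
        raise SessionFormatError(f"{path}: invalid rule at row {first_bad(bad)}")
    bad = ~frame["action"].astype(str).isin(_VALID_ACTIONS)
    if bad.any():
        raise SessionFormatError(f"{path}: invalid action at row {first_bad(bad)}")
    bad = ~frame["reward"].isin([0, 1])
    if bad.any():
        raise SessionFormatError(f"{path}: reward outside {{0,1}} at row {first_bad(bad)}")

    offset = 0
    for (day, block), g in frame.groupby(["day_id", "block_index"], sort=False):
        expected = np.arange(1, len(g) + 1)
        got = g["trial_in_block"].to_numpy()
        if not np.array_equal(got, expected):
            row = offset + int(np.flatnonzero(got != expected[: len(got)])[0]) + 2
            raise SessionFormatError(
                f"{path}: non-contiguous trial_in_block in day {day} block {block} at row {row}"
            )
        offset += len(g)

    keep = SESSION_COLUMNS + [c for c in LATENT_COLUMNS if c in frame.columns]
    return SessionTable(frame=frame[keep], config_hash=config_hash, seed=seed)
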