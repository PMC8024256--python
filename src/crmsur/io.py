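"""CSV/JSON artifact reading and writing with embedded provenance.

Tables are UTF-8 comma-separated CSV with a header row and ``.`` decimals;
provenance (software version, seed, config echo) rides in ``#``-prefixed
comment lines before the header, which readers skip, so a written table
reads back exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__


class MissingColumnError(ValueError):
    """A required column is absent from an input table."""


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    out: dict = {"software": f"crmsur {__version__}"}
    if seed is not None:
        out["seed"] = seed
    if config:
        out["config"] = config
    return out


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> Path:
    """Write a CSV artifact; provenance goes into leading comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {json.dumps(value) if not isinstance(value, str) else value}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(
    path: str | Path, required: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read a CSV artifact, validating that required columns are present."""
    df = pd.read_csv(path, comment="#")
    for col in required or ():
        if col not in df.columns:
            raise MissingColumnError(
                f"{path}: missing required column '{col}'"
            )
    return df


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> Path:
    """Write a JSON artifact with provenance under the ``provenance`` key."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["provenance"] = meta
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
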