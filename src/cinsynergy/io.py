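"""Reading, writing and configuration for tidy screen tables.

The on-disk interchange format is a long-format CSV with one row per
(plate, well, time point): plate, well, cell_line, drug, dose_um, bio_rep,
tech_rep, time_h, confluency_pct.  Header matching is case-insensitive
(``dose_uM`` and ``dose_um`` are the same column).  Output CSVs carry
``#``-prefixed header comments naming the producing stage and a hash of the
configuration, so every result file records how it was made.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ScreenValidationError

REQUIRED_COLUMNS = [
    "plate",
    "well",
    "cell_line",
    "drug",
    "dose_um",
    "bio_rep",
    "tech_rep",
    "time_h",
    "confluency_pct",
]

_NUMERIC = ["dose_um", "bio_rep", "tech_rep", "time_h", "confluency_pct"]


def read_screen_table(
    path, vehicle: str = "DMSO", max_confluency: float = 100.0
) -> pd.DataFrame:
    """Read and validate a tidy screen CSV.

    Fails closed: missing required columns, non-numeric time/confluency,
    out-of-range confluency, duplicate (plate, well, time_h) keys, or a
    cell line without any vehicle rows all raise
    :class:`ScreenValidationError`; value problems are reported with file
    line numbers.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_offset = 0
        for line in fh:
            if line.startswith("#"):
                header_offset += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(
            [f"missing required column(s): {', '.join(missing)}"]
        )
    # file line of data row i: header comments + header line + 1-based offset
    lineno = df.index.to_numpy() + header_offset + 2
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        for ln in lineno[bad.to_numpy()][:10]:
            problems.append(f"line {ln}: non-numeric value in column {col!r}")
        df[col] = converted
    conf = df["confluency_pct"]
    bad = conf.notna() & ((conf < 0) | (conf > max_confluency))
    for ln in lineno[bad.to_numpy()][:10]:
        problems.append(
            f"line {ln}: confluency outside [0, {max_confluency:g}]"
        )
    dup = df.duplicated(subset=["plate", "well", "time_h"], keep=False)
    if dup.any():
        for ln in lineno[dup.to_numpy()][:10]:
            problems.append(f"line {ln}: duplicate (plate, well, time_h) key")
    if problems:
        raise ScreenValidationError(problems)
    lines_with_vehicle = set(df.loc[df["drug"] == vehicle, "cell_line"])
    missing_ctrl = set(df["cell_line"]) - lines_with_vehicle
    if missing_ctrl:
        raise ScreenValidationError(
            [
                f"cell line {line!r} has no {vehicle!r} vehicle rows"
                for line in sorted(missing_ctrl)
            ]
        )
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    return df


def config_hash(config) -> str:
    """Stable short hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    elif isinstance(config, Mapping):
        payload = dict(config)
    else:
        payload = {"repr": repr(config)}
    payload = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in payload.items()}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return digest[:12]


def write_table(df: pd.DataFrame, path, stage: str, config=None) -> None:
    """Write a result CSV with stage/config header comments."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# stage: {stage}\n")
        fh.write(f"# generator: cinsynergy {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        # default float repr: exact binary round trip through read_csv
        df.to_csv(fh, index=False)


@dataclass
class PipelineConfig:
    """End-to-end analysis settings (YAML round-trip stable)."""

    auc_method: str = "sum"
    r2_min: float = 0.99
    min_points: int = 4
    windows: list[float] | None = field(default_factory=lambda: [4.0])
    alpha: float = 0.05
    effect_min: float = 1.0
    sides: str = "two"
    family_size: int | None = None
    replicate_unit: str = "bio"
    normalize_per: str = "bio_rep"
    synergy_replicate_mode: str = "well"
    vehicle: str = "DMSO"
    reference_line: str = "RPE1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must lie in (0, 1]")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.auc_method not in ("sum", "trapezoid"):
            raise ValueError("auc_method must be 'sum' or 'trapezoid'")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
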