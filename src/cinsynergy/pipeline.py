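"""End-to-end screen analysis: metrics -> differential -> synergy."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import DifferentialScreen
from .errors import CinSynergyError
from .growth import metrics_table, split_time_windows
from .io import PipelineConfig, config_hash, read_screen_table, write_table
from .synergy import BlissSynergy


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    differential: pd.DataFrame
    synergy: pd.DataFrame
    out_dir: Path | None = None


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except CinSynergyError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def run_pipeline(
    config: PipelineConfig,
    screen,
    out_dir=None,
) -> PipelineResult:
    """Run metrics, differential-sensitivity and Bliss-synergy stages.

    ``screen`` is a path to a tidy screen CSV or an already-loaded
    DataFrame.  Cell lines other than ``config.reference_line`` are treated
    as perturbations and each is compared against the reference, per drug
    and per time window.  With ``out_dir`` set, writes ``metrics.csv``,
    ``differential.csv``, ``synergy.csv`` and ``run_log.txt``; re-running
    with identical inputs reproduces the files byte for byte.
    """
    if isinstance(screen, (str, Path)):
        table = _stage("read", read_screen_table, screen, vehicle=config.vehicle)
    else:
        table = screen

    metrics = _stage(
        "metrics",
        metrics_table,
        table,
        auc_method=config.auc_method,
        r2_min=config.r2_min,
        min_points=config.min_points,
        vehicle=config.vehicle,
    )

    lines = sorted(set(table["cell_line"]) - {config.reference_line})
    windowed: list[tuple[str, pd.DataFrame]] = [("full", table)]
    if config.windows:
        windowed += split_time_windows(table, config.windows)

    diff_frames = []
    for line in lines:
        for label, tab in windowed:
            model = _stage(
                "differential",
                DifferentialScreen.from_screen,
                tab,
                line_a=line,
                line_b=config.reference_line,
                vehicle=config.vehicle,
                auc_method=config.auc_method,
                replicate_unit=config.replicate_unit,
                normalize_per=config.normalize_per,
                sides=config.sides,
                family_size=config.family_size,
            )
            res = _stage("differential", model.fit)
            frame = res.volcano_table(
                effect_min=config.effect_min, alpha=config.alpha
            )
            frame.insert(0, "window", label)
            frame.insert(0, "cell_line", line)
            diff_frames.append(frame)
    differential = pd.concat(diff_frames, ignore_index=True)

    syn_frames = []
    for line in lines:
        model = BlissSynergy(
            table,
            perturbation=line,
            reference_line=config.reference_line,
            vehicle=config.vehicle,
            auc_method=config.auc_method,
            sides=config.sides,
            replicate_mode=config.synergy_replicate_mode,
            windows=config.windows,
            seed=config.seed,
        )
        syn_frames.append(_stage("synergy", model.fit).records)
    synergy = pd.concat(syn_frames, ignore_index=True)

    result = PipelineResult(metrics=metrics, differential=differential, synergy=synergy)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(metrics, out_dir / "metrics.csv", "metrics", config)
        write_table(differential, out_dir / "differential.csv", "differential", config)
        write_table(synergy, out_dir / "synergy.csv", "synergy", config)
        _write_log(out_dir / "run_log.txt", config, table)
        result.out_dir = out_dir
    return result


def _write_log(path: Path, config: PipelineConfig, table: pd.DataFrame) -> None:
    from . import __version__

    lines = [
        f"cinsynergy {__version__} (python {sys.version.split()[0]},"
        f" numpy {np.__version__}, pandas {pd.__version__})",
        f"config_hash: {config_hash(config)}",
        f"config: {config}",
        f"rows: {len(table)}",
        f"cell_lines: {sorted(set(table['cell_line']))}",
        f"drugs: {sorted(set(table['drug']))}",
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
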