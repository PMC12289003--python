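"""File formats: transcript JSONL, subject/metric CSVs, draws, manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dialogue import GroundTruthRecord, Transcript
from .errors import IntegrityError
from .extraction import AnalysisTable
from .model import FitSummary, PosteriorDraws, SUMMARY_QUANTITIES
from .params import StudyConfig, config_to_dict
from .study import MetricsTable

__all__ = [
    "write_transcripts", "read_transcripts",
    "write_ground_truth", "read_ground_truth",
    "write_analysis_table", "read_analysis_table",
    "write_draws", "write_fit_summary",
    "write_metrics", "write_manifest",
]


def write_transcripts(transcripts: list[Transcript], path: str | Path) -> Path:
    """One JSON object per line: {subject_id, arm, turns: [{role, node_id, text}]}."""
    path = Path(path)
    with path.open("w") as fh:
        for t in transcripts:
            fh.write(json.dumps(t.to_dict()) + "\n")
    return path


def read_transcripts(path: str | Path) -> list[Transcript]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            out.append(Transcript.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError) as exc:
            raise IntegrityError(f"{path}, line {lineno}: malformed transcript: {exc}") from exc
    return out


def write_ground_truth(records: list[GroundTruthRecord], path: str | Path) -> Path:
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "x": [r.x for r in records],
            "z": [r.z for r in records],
            "m": [r.m for r in records],
            "y": [r.y for r in records],
        }
    )
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    frame = _read_csv(path, required={"subject_id", "x", "z", "m", "y"})
    return [
        GroundTruthRecord(
            subject_id=str(r.subject_id), x=int(r.x), z=float(r.z),
            m=float(r.m), y=float(r.y),
        )
        for r in frame.itertuples(index=False)
    ]


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise IntegrityError(f"cannot parse CSV {path}: {exc}") from exc
    missing = sorted(required - set(frame.columns))
    if missing:
        raise IntegrityError(f"{path}: missing column(s): {', '.join(missing)}")
    return frame


def write_analysis_table(table: AnalysisTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_analysis_table(path: str | Path) -> AnalysisTable:
    return AnalysisTable.from_frame(_read_csv(path, required={"subject_id", "x", "z", "m", "y"}))


def write_draws(draws: PosteriorDraws, path: str | Path) -> Path:
    """Columnar draw file: chain, iteration, then one column per quantity."""
    n_chains, n_draws = draws.n_chains, draws.n_draws
    data = {
        "chain": np.repeat(np.arange(n_chains), n_draws),
        "iteration": np.tile(np.arange(n_draws), n_chains),
    }
    for name in SUMMARY_QUANTITIES:
        data[name] = draws.draws[name].reshape(-1)
    path = Path(path)
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def write_fit_summary(summary: FitSummary, path: str | Path) -> Path:
    path = Path(path)
    summary.table.reset_index().to_csv(path, index=False)
    return path


def write_metrics(metrics: MetricsTable, path: str | Path) -> Path:
    path = Path(path)
    metrics.table.reset_index().to_csv(path, index=False)
    return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: StudyConfig,
    outputs: list[Path],
    name: str = "manifest.json",
) -> Path:
    """Record the resolved config, seed and output digests for reproducibility."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "promediate",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_to_dict(config),
        "master_seed": config.master_seed,
        "outputs": {p.name: file_digest(p) for p in outputs},
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
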