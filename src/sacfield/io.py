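"""Delimited-table and manifest I/O for the pipeline.

SRT tables are comma-separated with a header row; millisecond values are
integers (the model is 1-ms resolved).  Every artifact-producing run
writes exactly one JSON manifest recording the command, configuration
hash, seeds and outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .srt_analysis import ComparisonReport, SRTSample

SRT_CORE_COLUMNS = ["trial", "srt_ms", "direction", "no_saccade"]


@dataclass
class RunManifest:
    command: str
    seed: Optional[int]
    config_hash: str
    outputs: List[str]
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_srt_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_srt_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "srt_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'srt_ms'")
    if "no_saccade" in df.columns:
        df["no_saccade"] = df["no_saccade"].astype(bool)
    df["srt_ms"] = pd.array(
        [None if pd.isna(v) else int(v) for v in df["srt_ms"]], dtype="Int64"
    )
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    return df


def sample_to_table(sample: SRTSample) -> pd.DataFrame:
    df = sample.to_frame()
    df.insert(0, "trial", np.arange(len(df)))
    df["direction"] = "right"
    df["no_saccade"] = False
    return df


def table_to_sample(df: pd.DataFrame, species: Optional[str] = None) -> SRTSample:
    ok = ~df["no_saccade"] if "no_saccade" in df.columns else df["srt_ms"].notna()
    sub = df.loc[ok]
    return SRTSample(
        values=sub["srt_ms"].to_numpy(dtype=float),
        correct=sub["correct"].to_numpy() if "correct" in sub.columns else None,
        landing_x_deg=(
            sub["landing_x_deg"].to_numpy() if "landing_x_deg" in sub.columns else None
        ),
        subject=sub["subject"].to_numpy() if "subject" in sub.columns else None,
        species=species
        or (str(sub["species"].iloc[0]) if "species" in sub.columns and len(sub) else None),
    )


def write_comparison_report(report: ComparisonReport, out_dir) -> Dict[str, str]:
    """Export a ComparisonReport as delimited tables plus a flat summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bins = pd.DataFrame(
        {
            "bin_left_ms": report.edges[:-1],
            "bin_right_ms": report.edges[1:],
            "observed_proportion": report.observed_proportions,
            "model_proportion": report.model_proportions,
            "observed_cdf": report.observed_cdf,
            "model_cdf": report.model_cdf,
        }
    )
    paths = {
        "bins": str(out / "comparison_bins.csv"),
        "quantiles": str(out / "comparison_quantiles.csv"),
        "summary": str(out / "comparison_summary.csv"),
    }
    bins.to_csv(paths["bins"], index=False)
    report.quantiles.to_csv(paths["quantiles"], index=False)
    pd.Series(report.summary()).rename_axis("key").rename("value").to_csv(
        paths["summary"]
    )
    return paths
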