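"""Delimited-text I/O, run configs, and run manifests.

All tables are tab-separated with a header row. Numeric fields may carry
thousands separators (as printed tables often do); they are stripped on read.
Validation failures are reported with file and line numbers.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import DataError
from .fluctuation import FluctuationExperiment, RateEstimate
from .gelquant import LaneProfile
from .spectra import SubstitutionCall

__all__ = [
    "read_counts",
    "write_counts",
    "read_experiments",
    "read_lane_profiles",
    "write_lane_profiles",
    "read_gel_config",
    "read_calls",
    "write_calls",
    "read_fasta",
    "write_rate_table",
    "write_manifest",
]

SEP = "\t"


def _parse_number(value, path: Path, line: int, column: str) -> float:
    try:
        return float(str(value).replace(",", ""))
    except (TypeError, ValueError):
        raise DataError(f"{path}:{line}: column {column!r}: not a number: {value!r}") from None


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        print(f"warning: {path} is empty", file=sys.stderr)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    return df


def read_counts(path: str | Path) -> dict[str, list[int]]:
    """Read per-culture colony counts: columns ``label``, ``count``."""
    path = Path(path)
    df = _read_table(path, ["label", "count"])
    out: dict[str, list[int]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        value = _parse_number(row["count"], path, line, "count")
        if value < 0 or value != int(value):
            raise DataError(f"{path}:{line}: colony count must be a non-negative integer")
        out.setdefault(str(row["label"]), []).append(int(value))
    return out


def write_counts(path: str | Path, counts: Mapping[str, Sequence[int]]) -> None:
    rows = [(label, int(c)) for label, cs in counts.items() for c in cs]
    pd.DataFrame(rows, columns=["label", "count"]).to_csv(path, sep=SEP, index=False)


def read_experiments(counts_path: str | Path, meta_path: str | Path) -> list[FluctuationExperiment]:
    """Combine a counts table with per-experiment metadata (epsilon, Nt)."""
    meta_path = Path(meta_path)
    counts = read_counts(counts_path)
    meta = _read_table(meta_path, ["label", "epsilon", "Nt"])
    experiments = []
    seen = set()
    for i, row in meta.iterrows():
        line = i + 2
        label = str(row["label"])
        seen.add(label)
        if label not in counts:
            raise DataError(f"{meta_path}:{line}: no counts for experiment {label!r}")
        experiments.append(
            FluctuationExperiment(
                counts=tuple(counts[label]),
                epsilon=_parse_number(row["epsilon"], meta_path, line, "epsilon"),
                Nt=_parse_number(row["Nt"], meta_path, line, "Nt"),
                label=label,
            )
        )
    orphans = set(counts) - seen
    if orphans:
        raise DataError(f"{counts_path}: counts without metadata for {sorted(orphans)}")
    return experiments


def read_lane_profiles(path: str | Path) -> dict[str, LaneProfile]:
    """Read long-format lane densitometry: columns ``lane, distance, intensity``."""
    path = Path(path)
    df = _read_table(path, ["lane", "distance", "intensity"])
    profiles = {}
    for lane, group in df.groupby("lane", sort=False):
        d = np.array(
            [_parse_number(v, path, i + 2, "distance") for i, v in group["distance"].items()]
        )
        y = np.array(
            [_parse_number(v, path, i + 2, "intensity") for i, v in group["intensity"].items()]
        )
        order = np.argsort(d)
        profiles[str(lane)] = LaneProfile(distances=d[order], intensities=y[order], label=str(lane))
    return profiles


def write_lane_profiles(path: str | Path, profiles: Sequence[LaneProfile]) -> None:
    frames = [
        pd.DataFrame(
            {"lane": p.label, "distance": p.distances, "intensity": p.intensities}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=SEP, index=False)


def read_gel_config(path: str | Path) -> dict:
    """YAML run config for the gel pipeline.

    Required keys: ``marker_lanes`` (list of lane names), ``ladder_sizes``
    (nt), ``lanes`` (mapping lane name -> {genotype, rnhB}). Optional:
    ``sz_min`` (default 500), ``genome_size`` (default 9.28e6).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("marker_lanes", "ladder_sizes", "lanes"):
        if key not in cfg:
            raise DataError(f"{path}: gel config missing key {key!r}")
    cfg.setdefault("sz_min", 500.0)
    cfg.setdefault("genome_size", 9.28e6)
    return cfg


def read_calls(path: str | Path) -> list[SubstitutionCall]:
    """Read substitution calls: columns ``isolate, position, ref, alt``."""
    path = Path(path)
    df = _read_table(path, ["isolate", "position", "ref", "alt"])
    calls = []
    for i, row in df.iterrows():
        line = i + 2
        pos = _parse_number(row["position"], path, line, "position")
        if pos != int(pos) or pos < 1:
            raise DataError(f"{path}:{line}: position must be a positive integer")
        try:
            calls.append(
                SubstitutionCall(
                    position=int(pos),
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]).upper(),
                    isolate=str(row["isolate"]),
                )
            )
        except DataError as err:
            raise DataError(f"{path}:{line}: {err}") from None
    return calls


def write_calls(path: str | Path, calls: Sequence[SubstitutionCall]) -> None:
    pd.DataFrame(
        [
            {"isolate": c.isolate, "position": c.position, "ref": c.ref, "alt": c.alt}
            for c in calls
        ],
        columns=["isolate", "position", "ref", "alt"],
    ).to_csv(path, sep=SEP, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_rate_table(path: str | Path, estimates: Sequence[RateEstimate]) -> None:
    """Rate table on the conventional x1e9 display scale."""
    pd.DataFrame(
        [
            {
                "label": e.label,
                "rate_x1e9": e.rate * 1e9,
                "ci_low_x1e9": e.ci_low * 1e9,
                "ci_high_x1e9": e.ci_high * 1e9,
                "m_hat": e.m_hat,
            }
            for e in estimates
        ]
    ).to_csv(path, sep=SEP, index=False, float_format="%.6g")


def write_manifest(out_dir: str | Path, stage: str, params: Mapping, inputs: Mapping) -> Path:
    """Machine-readable record of one run (stage, inputs, parameters, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": {k: v for k, v in params.items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
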