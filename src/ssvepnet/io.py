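"""Plain-text I/O: cohort manifests, weight matrices, edge lists.

A cohort on disk is a JSON manifest plus one whitespace-delimited numeric
matrix (channels × samples) per segment.  Ground truth from the synthetic
generator, network edge lists, and result tables are JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GroundTruth
from .connectivity import CoherenceNetwork
from .recording import Recording

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "network_to_edge_frame",
    "write_network_matrix",
    "read_network_matrix",
]

MANIFEST_NAME = "manifest.json"


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write segments as delimited text plus a JSON manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        seg_files = []
        for k, seg in enumerate(rec.segments):
            name = f"{rec.subject}_{rec.condition}_seg{k:02d}.tsv"
            np.savetxt(out_dir / name, seg, fmt="%.10g", delimiter="\t")
            seg_files.append(name)
        entries.append(
            {
                "subject": rec.subject,
                "condition": rec.condition,
                "fs": rec.fs,
                "channels": list(rec.channel_labels),
                "segments": seg_files,
            }
        )
    manifest = out_dir / MANIFEST_NAME
    manifest.write_text(json.dumps({"recordings": entries}, indent=2, sort_keys=True))
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Read a cohort written by :func:`write_cohort` (or equivalent)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        spec = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest {manifest_path}: {exc}") from exc
    if "recordings" not in spec:
        raise ValueError(f"manifest {manifest_path} lacks a 'recordings' list")
    recordings = []
    for entry in spec["recordings"]:
        segments = []
        for name in entry["segments"]:
            path = base / name
            if not path.exists():
                raise FileNotFoundError(f"segment file missing: {path}")
            segments.append(np.atleast_2d(np.loadtxt(path, delimiter="\t")))
        recordings.append(
            Recording(
                subject=entry["subject"],
                condition=entry["condition"],
                fs=float(entry["fs"]),
                channel_labels=tuple(entry["channels"]),
                segments=segments,
            )
        )
    return recordings


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "entrain_factors": list(truth.entrain_factors),
        "edge_class": {f"{a}--{b}": c for (a, b), c in sorted(truth.edge_class.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    edge_class = {
        tuple(key.split("--")): cls
        for key, cls in payload["edge_class"].items()
    }
    return GroundTruth(
        entrain_factors=tuple(payload["entrain_factors"]),
        edge_class=edge_class,
    )


def network_to_edge_frame(network: CoherenceNetwork) -> pd.DataFrame:
    """Long-format (node_i, node_j, weight) rows for the nonzero edges."""
    labels = network.node_labels
    iu, ju = np.nonzero(np.triu(network.weights, k=1))
    return pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu],
            "node_j": [labels[j] for j in ju],
            "weight": network.weights[iu, ju],
        }
    )


def write_network_matrix(network: CoherenceNetwork, path: str | Path) -> None:
    """Square weight matrix as TSV with a '#'-prefixed label header."""
    header = "\t".join(network.node_labels)
    np.savetxt(path, network.weights, fmt="%.10g", delimiter="\t", header=header)


def read_network_matrix(
    path: str | Path, stim_freq: float = float("nan")
) -> CoherenceNetwork:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    labels = tuple(first.lstrip("# ").strip().split("\t"))
    weights = np.loadtxt(path, delimiter="\t")
    return CoherenceNetwork(node_labels=labels, weights=weights, stim_freq=stim_freq)
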