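"""End-to-end orchestration: recordings in, networks, metrics and stats out.

Stage order: generate or load recordings → extract 2.4 s / 1.2 s-overlap
epochs → stimulus-band SNR → per-epoch narrow-band coherence → average into
each subject's original whole network → group sparsity search over all
networks of all conditions → Network 0 per subject → edge-wise SNR
correlation and partition into Networks 1/2/3 → weighted topology metrics
for Networks 0, 1, 2 → metric–SNR correlation tables → high- vs low-SNR
group permutation test.  A fixed seed and config reproduce every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GeneratorConfig, GroundTruth, generate_cohort
from .connectivity import CoherenceNetwork, recording_network
from .graph_metrics import (
    DisconnectedNetworkError,
    TopologyMetrics,
    mean_connectivity,
    network_metrics,
)
from .io import network_to_edge_frame, read_cohort, write_ground_truth
from .network_build import SparsityResult, apply_sparsity, find_sparsity
from .partition import (
    EdgeCorrelation,
    NetworkPartition,
    classify_edges,
    edgewise_correlation,
    subnetwork,
)
from .recording import Recording
from .spectral import compute_snr, epochs_from_recording
from .stats import PermutationResult, group_permutation_test, metric_snr_correlations

__all__ = ["RunConfig", "RunResult", "run_pipeline", "condition_label"]

logger = logging.getLogger(__name__)

#: Networks whose topology is analysed. Network 3 (negative class) is
#: typically too sparse for meaningful metrics and is reported only as a
#: partition class.
ANALYSED_NETWORKS = {0: None, 1: "positive", 2: "nonsig"}


def condition_label(freq: float) -> str:
    return f"{freq:.4g}Hz"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    manifest: str | None = None  # files mode: path to a cohort manifest
    stim_freqs: tuple[float, ...] = (12.5, 1000.0 / 60.0)
    window_s: float = 2.4
    overlap_s: float = 1.2
    subwindow_s: float = 1.2
    sub_overlap_frac: float = 0.5
    sparsity_step: float = 0.01
    alpha: float = 0.05
    n_perm: int = 5000
    #: Group size of the high-/low-SNR comparison (4 vs 4 by default).
    n_group: int = 4
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.manifest:
            raise ValueError("files mode requires a manifest path")
        for f in self.stim_freqs:
            if f <= 4.0:
                raise ValueError(
                    f"stimulus frequency {f} Hz outside the steady-state "
                    "regime (> 4 Hz)"
                )
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError("need 0 <= overlap < window")


@dataclass
class RunResult:
    """All in-memory products of one run (also written to out_dir if set)."""

    config: RunConfig
    sparsity: SparsityResult
    snr_table: pd.DataFrame
    metrics_table: pd.DataFrame
    correlations: pd.DataFrame
    original_networks: dict[str, list[CoherenceNetwork]]
    networks0: dict[str, list[CoherenceNetwork]]
    subjects: dict[str, list[str]]
    mean_snrs: dict[str, np.ndarray]
    edge_correlations: dict[str, EdgeCorrelation]
    partitions: dict[str, NetworkPartition]
    permutations: dict[str, PermutationResult]
    ground_truth: GroundTruth | None
    report: dict


def _collect_recordings(
    config: RunConfig,
) -> tuple[dict[str, list[Recording]], GroundTruth | None]:
    by_condition: dict[str, list[Recording]] = {}
    truth: GroundTruth | None = None
    if config.mode == "synthetic":
        for f in config.stim_freqs:
            gen = dataclasses.replace(
                config.generator, stim_freq=f, seed=config.seed
            )
            recs, truth = generate_cohort(gen)
            by_condition[condition_label(f)] = recs
            logger.info(
                "generated %d subjects for %s (%d segments of %g s each)",
                len(recs), condition_label(f), gen.n_segments, gen.segment_s,
            )
    else:
        all_recs = read_cohort(config.manifest)
        for f in config.stim_freqs:
            label = condition_label(f)
            recs = [r for r in all_recs if r.condition == label]
            if not recs:
                raise ValueError(
                    f"manifest {config.manifest} has no recordings for "
                    f"condition {label!r}"
                )
            by_condition[label] = recs
            logger.info("loaded %d subjects for %s", len(recs), label)
    return by_condition, truth


def _safe_metrics(net: CoherenceNetwork) -> TopologyMetrics:
    """Metrics with NaN path length when every pair is disconnected."""
    try:
        return network_metrics(net)
    except DisconnectedNetworkError:
        n = net.n_nodes
        return TopologyMetrics(
            clustering=0.0,
            clustering_per_node=np.zeros(n),
            path_length=float("nan"),
            global_eff=0.0,
            local_eff=0.0,
            local_eff_per_node=np.zeros(n),
        )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and return (and optionally write) all products."""
    by_condition, truth = _collect_recordings(config)
    freqs = {condition_label(f): f for f in config.stim_freqs}

    # Spectral stage: SNR per subject/condition; coherence networks.
    original: dict[str, list[CoherenceNetwork]] = {}
    subjects: dict[str, list[str]] = {}
    mean_snrs: dict[str, np.ndarray] = {}
    snr_rows = []
    for label, recs in by_condition.items():
        f0 = freqs[label]
        nets, snrs = [], []
        for rec in recs:
            epochs = epochs_from_recording(rec, config.window_s, config.overlap_s)
            snr = compute_snr(epochs, f0)
            net = recording_network(
                rec, f0, config.window_s, config.overlap_s,
                config.subwindow_s, config.sub_overlap_frac,
            )
            nets.append(net)
            snrs.append(snr.mean_snr)
            snr_rows.append(
                dict(
                    subject=rec.subject,
                    condition=label,
                    mean_snr=snr.mean_snr,
                    n_epochs=epochs.n_epochs,
                )
            )
        original[label] = nets
        subjects[label] = [rec.subject for rec in recs]
        mean_snrs[label] = np.asarray(snrs)
        logger.info(
            "%s: %d original networks of %d nodes (%d epochs each)",
            label, len(nets), nets[0].n_nodes, nets[0].n_epochs_averaged,
        )
    snr_table = pd.DataFrame(snr_rows)

    # Group sparsity over all original networks of all conditions.
    all_nets = [net for nets in original.values() for net in nets]
    sparsity = find_sparsity(all_nets, step=config.sparsity_step)
    logger.info(
        "sparsity %.4f (%d edges kept; critical threshold %.2f)",
        sparsity.sparsity, sparsity.n_edges_kept, sparsity.critical_threshold,
    )
    networks0 = {
        label: [apply_sparsity(net, sparsity.sparsity) for net in nets]
        for label, nets in original.items()
    }

    # Partition, metrics, correlations, permutation test per condition.
    edge_corrs: dict[str, EdgeCorrelation] = {}
    partitions: dict[str, NetworkPartition] = {}
    permutations: dict[str, PermutationResult] = {}
    metric_rows = []
    corr_frames = []
    for label in by_condition:
        nets0 = networks0[label]
        snrs = mean_snrs[label]
        corr = edgewise_correlation(nets0, snrs)
        part = classify_edges(corr, config.alpha)
        edge_corrs[label] = corr
        partitions[label] = part
        logger.info(
            "%s: partition of %d edges -> %d positive, %d nonsig, %d negative",
            label, len(corr.edges),
            len(part.edges_of("positive")),
            len(part.edges_of("nonsig")),
            len(part.edges_of("negative")),
        )

        per_network_metrics: dict[int, list[TopologyMetrics]] = {}
        per_network_conn: dict[int, list[float]] = {}
        for net_id, cls in ANALYSED_NETWORKS.items():
            mts, conns = [], []
            for subj, net0 in zip(subjects[label], nets0):
                net = net0 if cls is None else subnetwork(net0, part, cls)
                tm = _safe_metrics(net)
                conn = mean_connectivity(net)
                mts.append(tm)
                conns.append(conn)
                metric_rows.append(
                    dict(
                        subject=subj,
                        condition=label,
                        network_id=net_id,
                        clustering=tm.clustering,
                        path_length=tm.path_length,
                        global_eff=tm.global_eff,
                        local_eff=tm.local_eff,
                        mean_connectivity=conn,
                    )
                )
            per_network_metrics[net_id] = mts
            per_network_conn[net_id] = conns
            corr_frames.append(
                metric_snr_correlations(mts, conns, snrs, label, net_id)
            )

        order = np.argsort(snrs, kind="stable")
        k = min(config.n_group, len(nets0) // 2)
        high = [nets0[i] for i in order[::-1][:k]]
        low = [nets0[i] for i in order[:k]]
        permutations[label] = group_permutation_test(
            high, low, n_perm=config.n_perm, seed=config.seed,
        )
        logger.info(
            "%s: permutation test (%s, %d permutations) on %d edges",
            label, permutations[label].method,
            permutations[label].n_permutations, len(permutations[label].edges),
        )

    metrics_table = pd.DataFrame(metric_rows)
    correlations = pd.concat(corr_frames, ignore_index=True)

    report = {
        "config": _config_dict(config),
        "sparsity": {
            "sparsity": sparsity.sparsity,
            "critical_threshold": sparsity.critical_threshold,
            "n_edges_kept": sparsity.n_edges_kept,
        },
        "conditions": {
            label: {
                "n_subjects": len(by_condition[label]),
                "n_edges_network0_union": len(edge_corrs[label].edges),
                "n_edges_positive": len(partitions[label].edges_of("positive")),
                "n_edges_nonsig": len(partitions[label].edges_of("nonsig")),
                "n_edges_negative": len(partitions[label].edges_of("negative")),
                "n_permutation_significant": int(
                    (permutations[label].p < config.alpha).sum()
                ),
            }
            for label in by_condition
        },
    }

    result = RunResult(
        config=config,
        sparsity=sparsity,
        snr_table=snr_table,
        metrics_table=metrics_table,
        correlations=correlations,
        original_networks=original,
        networks0=networks0,
        subjects=subjects,
        mean_snrs=mean_snrs,
        edge_correlations=edge_corrs,
        partitions=partitions,
        permutations=permutations,
        ground_truth=truth,
        report=report,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    gen = d["generator"]
    gen["pos_edges"] = [list(e) for e in gen["pos_edges"]]
    gen["neg_edges"] = [list(e) for e in gen["neg_edges"]]
    gen["channel_labels"] = list(gen["channel_labels"])
    d["stim_freqs"] = list(d["stim_freqs"])
    return d


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.snr_table.to_csv(out_dir / "snr.csv", index=False)
    result.metrics_table.to_csv(out_dir / "metrics.csv", index=False)
    result.correlations.to_csv(out_dir / "correlations.csv", index=False)
    for label, nets0 in result.networks0.items():
        frames = []
        for subj, net in zip(result.subjects[label], nets0):
            frame = network_to_edge_frame(net)
            frame.insert(0, "subject", subj)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"network0_{label}.csv", index=False
        )
        corr = result.edge_correlations[label]
        part = result.partitions[label]
        pd.DataFrame(
            {
                "node_i": [a for a, _ in corr.edges],
                "node_j": [b for _, b in corr.edges],
                "r": corr.r,
                "p": corr.p,
                "class": [part.edge_class[e] for e in corr.edges],
            }
        ).to_csv(out_dir / f"partition_{label}.csv", index=False)
        perm = result.permutations[label]
        pd.DataFrame(
            {
                "node_i": [a for a, _ in perm.edges],
                "node_j": [b for _, b in perm.edges],
                "observed_diff": perm.observed_diff,
                "p": perm.p,
            }
        ).to_csv(out_dir / f"permutation_{label}.csv", index=False)
    if result.ground_truth is not None:
        write_ground_truth(result.ground_truth, out_dir / "ground_truth.json")
    (out_dir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True)
    )
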