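"""End-to-end glue: fixture/sim inputs -> MPBS labeling -> tensors ->
training -> evaluation.  Used by the CLI subcommands and the test suite."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import auroc, fps_baseline_scores
from .footprint import FootprintConfig, footprint_scores
from .fragments import FragmentRecord, SizePartitionConfig
from .model import ModelConfig, ModelEnsemble, predict
from .motifs import (
    MPBS,
    PWM,
    LabelConfig,
    ScanConfig,
    SplitConfig,
    balance_and_split,
    label_mpbs,
    pvalue_threshold,
    restrict_to_open,
    scan,
)
from .formats import Peak
from .signal import genome_cut_matrix
from .simulate import SimResult
from .tensors import assemble_dataset
from .training import TrainConfig, train

__all__ = ["PipelineResult", "prepare_mpbs", "prepare_datasets", "run_pipeline"]


@dataclass
class PipelineResult:
    ensemble: ModelEnsemble
    trace: list[dict]
    splits: dict[str, list[MPBS]]
    tracks: dict[str, np.ndarray]
    test_probs: np.ndarray
    test_labels: np.ndarray
    test_auroc: float
    extras: dict = field(default_factory=dict)


def prepare_mpbs(
    genome: dict[str, str],
    pwm: PWM,
    atac_peaks: list[Peak],
    chip_peaks: list[Peak],
    scan_config: ScanConfig | None = None,
    label_config: LabelConfig | None = None,
) -> list[MPBS]:
    """Scan -> restrict to open chromatin -> label from ChIP summits."""
    scan_config = scan_config or ScanConfig()
    threshold = pvalue_threshold(pwm, scan_config)
    mpbss = scan(genome, pwm, threshold)
    mpbss = restrict_to_open(mpbss, atac_peaks)
    return label_mpbs(mpbss, chip_peaks, label_config)


def prepare_datasets(
    labeled: list[MPBS],
    fragments: list[FragmentRecord],
    chrom_sizes: dict[str, int],
    layout: str = "default",
    window_half: int = 500,
    split_config: SplitConfig | None = None,
    size_config: SizePartitionConfig | None = None,
    seed: int = 0,
):
    """Balance + split labeled MPBSs and assemble per-split tensors."""
    split_config = split_config or SplitConfig(seed=seed)
    splits = balance_and_split(labeled, split_config, seed=seed)
    tracks = genome_cut_matrix(fragments, chrom_sizes, size_config)
    data = {
        name: assemble_dataset(mpbss, tracks, layout=layout, window_half=window_half)
        for name, mpbss in splits.items()
    }
    return splits, tracks, data


def run_pipeline(
    sim: SimResult,
    layout: str = "default",
    window_half: int = 500,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    scan_config: ScanConfig | None = None,
) -> PipelineResult:
    """Full pipeline on a simulated fixture; returns the trained ensemble and
    held-out test AUROC plus everything needed for baseline comparisons."""
    train_config = train_config or TrainConfig(seed=seed)
    labeled = prepare_mpbs(
        sim.genome, sim.pwm, sim.atac_peaks, sim.chip_peaks, scan_config=scan_config
    )
    chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
    splits, tracks, data = prepare_datasets(
        labeled, sim.fragments, chrom_sizes,
        layout=layout, window_half=window_half, seed=seed,
    )
    Xtr, ytr, _ = data["train"]
    Xva, yva, _ = data["val"]
    Xte, yte, _ = data["test"]
    ensemble, trace = train(Xtr, ytr, Xva, yva, model_config, train_config)
    probs = predict(Xte, ensemble)
    return PipelineResult(
        ensemble=ensemble,
        trace=trace,
        splits=splits,
        tracks=tracks,
        test_probs=probs,
        test_labels=yte,
        test_auroc=auroc(probs, yte),
    )


def fps_baseline_auroc(
    result: PipelineResult, footprint_config: FootprintConfig | None = None
) -> float:
    """AUROC of mean-footprint-score baseline on the pipeline's test MPBSs."""
    fp_tracks = {
        chrom: footprint_scores(mat.sum(axis=0).astype(np.float64), footprint_config)
        for chrom, mat in result.tracks.items()
    }
    test_mpbss = result.splits["test"]
    scores = fps_baseline_scores(test_mpbss, fp_tracks)
    labels = np.array([1.0 if m.label == "bound" else 0.0 for m in test_mpbss])
    return auroc(scores, labels)
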