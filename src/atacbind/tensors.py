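"""Per-site input tensor assembly.

The default layout stacks, over a 1000-bp window centered on the motif
match:

* row 0 — footprint scores of the strand/size-pooled raw cut counts,
* rows 1-4 — normalized cleavage signal per channel
  (fwd/short, rev/short, fwd/long, rev/long),
* rows 5-8 — least-squares slopes of the normalized signals.

Variants drop the footprint row (``variant1``), keep only the footprint row
(``variant2``), pool strands (``variant3``) or pool fragment sizes
(``variant4``) before normalization; pooled variants recompute signal and
slope from the channel-summed raw counts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .footprint import FootprintConfig, footprint_scores
from .motifs import MPBS
from .signal import SignalConfig, normalize_track, slope_track

__all__ = [
    "SignalWindow",
    "LAYOUTS",
    "assemble",
    "shortened_window",
    "assemble_dataset",
    "save_dataset",
    "load_dataset",
]

LAYOUTS = {
    "default": 9,
    "variant1": 8,  # no footprint row
    "variant2": 1,  # footprint row only
    "variant3": 5,  # strands pooled: footprint + 2 signal + 2 slope
    "variant4": 5,  # sizes pooled: footprint + 2 signal + 2 slope
}


@dataclass
class SignalWindow:
    mpbs_id: str
    matrix: np.ndarray
    layout: str
    window_half: int
    clipped: bool = False

    def __post_init__(self):
        C, W = self.matrix.shape
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if C != LAYOUTS[self.layout]:
            raise ValueError(f"layout {self.layout} expects {LAYOUTS[self.layout]} channels, got {C}")
        if W != 2 * self.window_half:
            raise ValueError(f"width {W} != 2 * window_half {self.window_half}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite values in signal window")


def _window_counts(
    tracks: dict[str, np.ndarray], mpbs: MPBS, window_half: int
) -> tuple[np.ndarray, bool]:
    """Slice the 4-channel cut array over the window, zero-padding past ends."""
    if mpbs.chrom not in tracks:
        raise KeyError(f"no signal track for chromosome {mpbs.chrom!r}")
    chrom_counts = tracks[mpbs.chrom]
    chrom_len = chrom_counts.shape[1]
    lo = mpbs.center - window_half
    hi = mpbs.center + window_half
    out = np.zeros((4, hi - lo), dtype=np.float64)
    src_lo, src_hi = max(lo, 0), min(hi, chrom_len)
    clipped = (src_lo, src_hi) != (lo, hi)
    if src_hi > src_lo:
        out[:, src_lo - lo : src_hi - lo] = chrom_counts[:, src_lo:src_hi]
    return out, clipped


def _signal_and_slope(
    raw_channels: np.ndarray, signal_config: SignalConfig
) -> tuple[np.ndarray, np.ndarray]:
    signals = np.stack([normalize_track(ch, signal_config) for ch in raw_channels])
    slopes = np.stack([slope_track(s, signal_config) for s in signals])
    return signals, slopes


def assemble(
    mpbs: MPBS,
    tracks: dict[str, np.ndarray],
    layout: str = "default",
    window_half: int = 500,
    signal_config: SignalConfig | None = None,
    footprint_config: FootprintConfig | None = None,
) -> SignalWindow:
    """Build one input tensor for an MPBS from whole-chromosome cut arrays.

    ``tracks`` maps chromosome -> 4 x chrom_len cut-count array in channel
    order (fwd/short, rev/short, fwd/long, rev/long).
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    signal_config = signal_config or SignalConfig()
    footprint_config = footprint_config or FootprintConfig()
    counts, clipped = _window_counts(tracks, mpbs, window_half)
    rows: list[np.ndarray] = []
    if layout != "variant1":
        rows.append(footprint_scores(counts.sum(axis=0), footprint_config))
    if layout == "default" or layout == "variant1":
        signals, slopes = _signal_and_slope(counts, signal_config)
        rows.extend(signals)
        rows.extend(slopes)
    elif layout == "variant3":  # pool strands, keep size classes
        pooled = np.stack([counts[0] + counts[1], counts[2] + counts[3]])
        signals, slopes = _signal_and_slope(pooled, signal_config)
        rows.extend(signals)
        rows.extend(slopes)
    elif layout == "variant4":  # pool sizes, keep strands
        pooled = np.stack([counts[0] + counts[2], counts[1] + counts[3]])
        signals, slopes = _signal_and_slope(pooled, signal_config)
        rows.extend(signals)
        rows.extend(slopes)
    # variant2: footprint row only
    matrix = np.stack(rows)
    mpbs_id = f"{mpbs.chrom}:{mpbs.start}-{mpbs.end}({mpbs.strand})"
    return SignalWindow(mpbs_id, matrix, layout, window_half, clipped)


def shortened_window(
    mpbs: MPBS,
    tracks: dict[str, np.ndarray],
    window_half: int,
    layout: str = "default",
    **kwargs,
) -> SignalWindow:
    """`assemble` with a reduced window half-width (e.g. 50/100/250 bp)."""
    return assemble(mpbs, tracks, layout=layout, window_half=window_half, **kwargs)


_LABEL_CODE = {"unbound": 0, "bound": 1}


def assemble_dataset(
    mpbss: list[MPBS],
    tracks: dict[str, np.ndarray],
    layout: str = "default",
    window_half: int = 500,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, list[MPBS]]:
    """Stack tensors and 0/1 labels for a list of labeled MPBSs.

    Unlabeled MPBSs are rejected: datasets must be built from labeled sites.
    """
    X = np.empty((len(mpbss), LAYOUTS[layout], 2 * window_half), dtype=np.float32)
    y = np.empty(len(mpbss), dtype=np.float32)
    for i, m in enumerate(mpbss):
        if m.label not in _LABEL_CODE:
            raise ValueError(f"MPBS {i} has label {m.label!r}; dataset needs bound/unbound")
        X[i] = assemble(m, tracks, layout=layout, window_half=window_half, **kwargs).matrix
        y[i] = _LABEL_CODE[m.label]
    return X, y, mpbss


DATASET_VERSION = 1


def save_dataset(
    outdir: str,
    split_name: str,
    X: np.ndarray,
    y: np.ndarray,
    mpbss: list[MPBS],
    layout: str,
    window_half: int,
) -> None:
    """One array file per split plus a TSV manifest and JSON metadata."""
    os.makedirs(outdir, exist_ok=True)
    np.save(os.path.join(outdir, f"{split_name}.X.npy"), X)
    np.save(os.path.join(outdir, f"{split_name}.y.npy"), y)
    with open(os.path.join(outdir, f"{split_name}.manifest.tsv"), "w") as fh:
        fh.write("mpbs_id\tchrom\tstart\tend\tstrand\tpwm_score\tlabel\n")
        for m in mpbss:
            mid = f"{m.chrom}:{m.start}-{m.end}({m.strand})"
            fh.write(
                f"{mid}\t{m.chrom}\t{m.start}\t{m.end}\t{m.strand}\t"
                f"{m.pwm_score:.4f}\t{m.label}\n"
            )
    meta = {
        "version": DATASET_VERSION,
        "layout": layout,
        "window_half": window_half,
        "channel_order": [
            "footprint",
            "signal:fwd_short", "signal:rev_short", "signal:fwd_long", "signal:rev_long",
            "slope:fwd_short", "slope:rev_short", "slope:fwd_long", "slope:rev_long",
        ] if layout == "default" else layout,
    }
    with open(os.path.join(outdir, "dataset.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_dataset(outdir: str, split_name: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.load(os.path.join(outdir, f"{split_name}.X.npy"))
    y = np.load(os.path.join(outdir, f"{split_name}.y.npy"))
    return X, y
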