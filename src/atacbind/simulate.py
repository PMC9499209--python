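"""Self-contained synthetic fixture generator.

Produces a random genome with a motif consensus planted at bound and unbound
sites, paired-end fragment intervals whose Tn5 cut density is elevated inside
ATAC peaks and depleted (a footprint) around bound sites only, a bimodal
fragment-size mixture straddling one nucleosome length, an optional
strand-asymmetric cut pattern at bound sites, and ATAC/ChIP narrowPeak files
consistent with the planted truth.

Fragments are emitted as pre-shifted BED3 intervals (the fragment reader's
contract for interval input), keeping the simulator alignment-free.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    Peak,
    write_bed3,
    write_fasta,
    write_jaspar_pfm,
    write_narrowpeak,
)
from .fragments import FragmentRecord
from .motifs import PWM

__all__ = ["SimConfig", "SimResult", "simulate", "metaprofile", "default_pwm"]

# 12-mer with an 85/5/5/5 column profile; non-palindromic consensus
_CONSENSUS = "TGACGTCATAGC"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def default_pwm(name: str = "SIM1") -> PWM:
    mat = np.full((4, len(_CONSENSUS)), 5.0)
    for j, b in enumerate(_CONSENSUS):
        mat[_BASE_INDEX[b], j] = 85.0
    return PWM(name, mat)


@dataclass(frozen=True)
class SimConfig:
    genome_len: int = 200_000
    n_bound_sites: int = 100
    n_unbound_sites: int = 100
    background_cut_rate: float = 0.5  # expected cut events per bp inside peaks
    footprint_depth: float = 0.2  # cut-rate multiplier inside footprints; 0 = full protection
    footprint_halfwidth: int = 15
    strand_asymmetry: float = 0.0  # fraction of near-site forward cuts moved upstream
    frac_short: float = 0.7
    size_params: tuple[float, float, float] = (80.0, 220.0, 25.0)  # short mean, long mean, sd
    chip_noise_bp: float = 0.0  # ChIP summit jitter sd
    seed: int = 0
    peak_halfwidth: int = 300
    offpeak_rate_frac: float = 0.02
    chrom: str = "chrSim"

    def __post_init__(self):
        if self.background_cut_rate < 0:
            raise ValueError("background_cut_rate must be >= 0")
        for name in ("footprint_depth", "strand_asymmetry", "frac_short"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        n_sites = self.n_bound_sites + self.n_unbound_sites
        spacing = self.genome_len // (n_sites + 1)
        if spacing < 2 * self.peak_halfwidth + 100:
            raise ValueError(
                f"genome_len {self.genome_len} too small for {n_sites} sites "
                f"with peak halfwidth {self.peak_halfwidth}"
            )


@dataclass
class SimResult:
    genome: dict[str, str]
    fragments: list[FragmentRecord]
    atac_peaks: list[Peak]
    chip_peaks: list[Peak]
    truth: pd.DataFrame
    pwm: PWM
    config: SimConfig
    paths: dict[str, str] = field(default_factory=dict)


def _sample_sizes(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    short_mean, long_mean, sd = config.size_params
    is_short = rng.random(n) < config.frac_short
    means = np.where(is_short, short_mean, long_mean)
    sizes = np.maximum(np.round(rng.normal(means, sd)), 20).astype(np.int64)
    return sizes


def simulate(config: SimConfig, outdir: str | None = None) -> SimResult:
    """Generate the full fixture set; byte-identical output for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    pwm = default_pwm()
    L = pwm.length
    chrom = config.chrom
    n_sites = config.n_bound_sites + config.n_unbound_sites

    # --- site placement: evenly spaced centers, shuffled bound/unbound labels
    spacing = config.genome_len // (n_sites + 1)
    centers = (np.arange(1, n_sites + 1) * spacing).astype(np.int64)
    labels = np.array(
        ["bound"] * config.n_bound_sites + ["unbound"] * config.n_unbound_sites
    )
    rng.shuffle(labels)

    # --- genome with planted consensus
    seq = rng.choice(list("ACGT"), size=config.genome_len)
    for c in centers:
        start = c - L // 2
        seq[start : start + L] = list(_CONSENSUS)
    genome = {chrom: "".join(seq)}

    truth = pd.DataFrame(
        {
            "site_id": [f"site{i:05d}" for i in range(n_sites)],
            "chrom": chrom,
            "center": centers,
            "start": centers - L // 2,
            "end": centers - L // 2 + L,
            "label": labels,
        }
    )
    bound_centers = centers[labels == "bound"]

    # --- per-base cut-rate multiplier: footprint depletion at bound sites
    depletion = np.ones(config.genome_len)
    for c in bound_centers:
        lo = max(0, c - config.footprint_halfwidth)
        hi = min(config.genome_len, c + config.footprint_halfwidth + 1)
        depletion[lo:hi] = config.footprint_depth

    # --- fragments: left ends Poisson inside each peak, thinned at both cuts
    peak_lo = centers - config.peak_halfwidth
    peak_hi = centers + config.peak_halfwidth
    left_rate = config.background_cut_rate / 2.0  # each fragment carries 2 cuts
    lefts_all: list[np.ndarray] = []
    for lo, hi in zip(peak_lo, peak_hi):
        n_frag = rng.poisson(left_rate * (hi - lo))
        lefts_all.append(rng.integers(lo, hi, size=n_frag))
    # sparse background outside peaks
    n_bg = rng.poisson(left_rate * config.offpeak_rate_frac * config.genome_len)
    lefts_all.append(rng.integers(0, config.genome_len, size=n_bg))
    lefts = np.concatenate(lefts_all)
    keep = rng.random(lefts.size) < depletion[lefts]
    lefts = lefts[keep]

    # strand-asymmetric relocation: forward cuts near bound centers move to
    # a 10-30 bp band upstream of the center (dimer-like directional excess)
    if config.strand_asymmetry > 0 and bound_centers.size:
        order = np.argsort(bound_centers)
        sorted_centers = bound_centers[order]
        idx = np.searchsorted(sorted_centers, lefts)
        for shift in (0, -1):
            j = np.clip(idx + shift, 0, sorted_centers.size - 1)
            near = np.abs(lefts - sorted_centers[j]) <= 30
            move = near & (rng.random(lefts.size) < config.strand_asymmetry)
            lefts[move] = sorted_centers[j][move] - rng.integers(
                10, 31, size=int(move.sum())
            )

    sizes = _sample_sizes(rng, lefts.size, config)
    rights = lefts + sizes - 1  # right cut position; fragment end = rights + 1
    ok = rights < config.genome_len
    keep_right = rng.random(lefts.size) < np.where(ok, depletion[np.clip(rights, 0, config.genome_len - 1)], 0.0)
    lefts, rights = lefts[keep_right & ok], rights[keep_right & ok]
    order = np.lexsort((rights, lefts))
    fragments = [
        FragmentRecord(chrom, int(l), int(r) + 1)
        for l, r in zip(lefts[order], rights[order])
    ]

    # --- peak files
    atac_peaks = [
        Peak(chrom, int(lo), int(hi), f"atac{i}", 100, 10.0, int(c - lo))
        for i, (lo, hi, c) in enumerate(zip(peak_lo, peak_hi, centers))
    ]
    chip_peaks = []
    for i, c in enumerate(bound_centers):
        jitter = int(round(rng.normal(0, config.chip_noise_bp))) if config.chip_noise_bp > 0 else 0
        lo, hi = int(c) - 100, int(c) + 100
        summit = int(np.clip(c + jitter, lo, hi - 1))
        chip_peaks.append(Peak(chrom, lo, hi, f"chip{i}", 500, 50.0, summit - lo))

    result = SimResult(genome, fragments, atac_peaks, chip_peaks, truth, pwm, config)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "fragments": os.path.join(outdir, "fragments.bed"),
            "atac_peaks": os.path.join(outdir, "atac_peaks.narrowPeak"),
            "chip_peaks": os.path.join(outdir, "chip_peaks.narrowPeak"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "pwm": os.path.join(outdir, "motif.pfm"),
        }
        write_fasta(paths["genome"], genome)
        write_bed3(paths["fragments"], [(f.chrom, f.start, f.end) for f in fragments])
        write_narrowpeak(paths["atac_peaks"], atac_peaks)
        write_narrowpeak(paths["chip_peaks"], chip_peaks)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        write_jaspar_pfm(paths["pwm"], pwm.name, pwm.matrix)
        result.paths = paths
    return result


def metaprofile(
    grouped_windows: dict[str, list[np.ndarray]]
) -> dict[str, np.ndarray]:
    """Positionwise mean of raw per-channel cut counts for each truth group."""
    out = {}
    for group, windows in grouped_windows.items():
        if not windows:
            raise ValueError(f"group {group!r} has no windows")
        out[group] = np.mean(np.stack(windows), axis=0)
    return out
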