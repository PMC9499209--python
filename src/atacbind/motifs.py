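"""PWM motif scanning at a p-value-derived threshold, restriction to open
chromatin, bound/unbound labeling from ChIP-seq summits, and balanced
train/validation/test splitting.

Scores are log2 odds of the pseudocount-regularized position probabilities
against a background base distribution.  The score threshold for a given
p-value is derived by dynamic programming over the discretized per-column
score distribution under the background model, so that the probability of a
random background L-mer scoring at or above the threshold is at most p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import Peak

__all__ = [
    "PWM",
    "MPBS",
    "ScanConfig",
    "LabelConfig",
    "SplitConfig",
    "pvalue_threshold",
    "scan",
    "restrict_to_open",
    "label_mpbs",
    "balance_and_split",
    "BOUND",
    "UNBOUND",
    "UNLABELED",
]

BOUND = "bound"
UNBOUND = "unbound"
UNLABELED = "unlabeled"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PWM:
    """A position frequency/probability matrix with background and pseudocount."""

    name: str
    matrix: np.ndarray  # 4 x L counts or probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.8

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", mat)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "background", bg)
        if mat.ndim != 2 or mat.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularized per-column base probabilities."""
        col_tot = self.matrix.sum(axis=0)
        probs = (self.matrix + self.pseudocount * self.background[:, None]) / (
            col_tot + self.pseudocount
        )
        return probs

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds score matrix against the background."""
        probs = self.probabilities()
        if (probs <= 0).any():
            raise ValueError("degenerate PWM: zero probability cell")
        return np.log2(probs / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[::-1, ::-1])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds().min(axis=0).sum())


@dataclass
class MPBS:
    """A motif-predicted binding site (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    pwm_score: float
    label: str = UNLABELED
    name: str = "."

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ScanConfig:
    pvalue: float = 0.0001
    score_granularity: float = 0.1

    def __post_init__(self):
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")
        if self.score_granularity <= 0:
            raise ValueError("score_granularity must be > 0")


@dataclass(frozen=True)
class LabelConfig:
    summit_max_dist: int = 50

    def __post_init__(self):
        if self.summit_max_dist < 0:
            raise ValueError("summit_max_dist must be >= 0")


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.70
    val_frac: float = 0.20
    test_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if not np.isclose(total, 1.0):
            raise ValueError(f"split fractions sum to {total}, expected 1")


def pvalue_threshold(pwm: PWM, config: ScanConfig | None = None) -> float:
    """Smallest score t with P(score of a random background L-mer >= t) <= p.

    Exact dynamic programming over integer-binned per-column scores: each
    column score is rounded to a multiple of ``score_granularity`` and the
    distribution of the binned total under the background model is convolved
    column by column.
    """
    config = config or ScanConfig()
    g = config.score_granularity
    lods = pwm.log_odds()  # raises on degenerate PWM
    int_scores = np.round(lods / g).astype(np.int64)
    offset = int_scores.min(axis=0)  # shift each column to be >= 0
    shifted = int_scores - offset[None, :]
    max_total = int(shifted.max(axis=0).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    bg = pwm.background
    for col in range(pwm.length):
        col_dist = np.zeros(int(shifted[:, col].max()) + 1)
        for b in range(4):
            col_dist[shifted[b, col]] += bg[b]
        dist = np.convolve(dist, col_dist)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(total >= i)
    # smallest ACHIEVABLE binned score whose exceedance probability is <= p
    candidates = np.flatnonzero((tail <= config.pvalue + 1e-12) & (dist > 0))
    base = int(offset.sum())
    if candidates.size == 0:
        # p below the point mass at the maximum: threshold just above max
        return (np.flatnonzero(dist > 0)[-1] + base) * g + g / 2
    return float((candidates[0] + base) * g)


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(
    codes: np.ndarray, lods: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, scores) of windows scoring >= threshold."""
    L = lods.shape[1]
    n = codes.size
    if n < L:
        return np.empty(0, dtype=int), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = lods[safe, np.arange(L)[None, :]].sum(axis=1)
    hits = valid & (scores >= threshold - 1e-9)
    pos = np.flatnonzero(hits)
    return pos, scores[pos]


def scan(
    genome: dict[str, str], pwm: PWM, threshold: float
) -> list[MPBS]:
    """Scan both strands of every sequence; windows containing N are skipped.

    Minus-strand matches are reported on forward-strand coordinates.
    """
    lods_fwd = pwm.log_odds()
    lods_rev = pwm.reverse_complement().log_odds()
    out: list[MPBS] = []
    L = pwm.length
    for chrom, seq in genome.items():
        codes = _encode(seq)
        for strand, lods in (("+", lods_fwd), ("-", lods_rev)):
            pos, scores = _scan_one_strand(codes, lods, threshold)
            for p, s in zip(pos, scores):
                out.append(MPBS(chrom, int(p), int(p) + L, strand, float(s)))
    out.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return out


def restrict_to_open(mpbss: list[MPBS], atac_peaks: list[Peak]) -> list[MPBS]:
    """Keep only MPBSs fully contained in an open-chromatin peak interval."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in atac_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for peaks in by_chrom.values():
        peaks.sort(key=lambda p: p.start)
    kept = []
    for m in mpbss:
        for p in by_chrom.get(m.chrom, ()):
            if p.start > m.start:
                break
            if p.start <= m.start and m.end <= p.end:
                kept.append(m)
                break
    return kept


def label_mpbs(
    mpbss: list[MPBS],
    chip_peaks: list[Peak],
    config: LabelConfig | None = None,
) -> list[MPBS]:
    """Assign bound / unbound / unlabeled from ChIP peaks and summits.

    MPBSs outside every ChIP peak are unbound.  Within each peak, only the
    MPBS whose center is closest to the peak's highest summit (ties broken
    toward the lower coordinate) AND within ``summit_max_dist`` bp of it is
    bound; all other MPBSs inside the peak are left unlabeled.  Peak rows
    sharing identical coordinates are treated as multiple summits of one
    peak, keeping the summit with the largest signal value.
    """
    config = config or LabelConfig()
    for p in chip_peaks:
        if p.summit_offset < 0:
            raise ValueError(f"ChIP peak {p.chrom}:{p.start}-{p.end} has no summit")
    # collapse multi-summit rows to the highest summit per peak interval
    best: dict[tuple[str, int, int], Peak] = {}
    for p in chip_peaks:
        key = (p.chrom, p.start, p.end)
        if key not in best or p.signal > best[key].signal:
            best[key] = p
    peaks = sorted(best.values(), key=lambda p: (p.chrom, p.start))

    labeled = [replace_label(m, UNBOUND) for m in mpbss]
    assigned_to_peak: dict[int, list[int]] = {}  # peak idx -> mpbs indices
    for i, m in enumerate(labeled):
        for j, p in enumerate(peaks):
            if p.chrom == m.chrom and p.contains(m.center):
                assigned_to_peak.setdefault(j, []).append(i)
                labeled[i] = replace_label(m, UNLABELED)
                break
    for j, members in assigned_to_peak.items():
        summit = peaks[j].summit
        members.sort(key=lambda i: (abs(labeled[i].center - summit), labeled[i].start))
        chosen = members[0]
        if abs(labeled[chosen].center - summit) <= config.summit_max_dist:
            labeled[chosen] = replace_label(labeled[chosen], BOUND)
    return labeled


def replace_label(m: MPBS, label: str) -> MPBS:
    return MPBS(m.chrom, m.start, m.end, m.strand, m.pwm_score, label, m.name)


class ClassBalanceError(ValueError):
    """Raised when a bound or unbound class is empty before balancing."""


def balance_and_split(
    labeled: list[MPBS],
    split: SplitConfig | None = None,
    seed: int | None = None,
) -> dict[str, list[MPBS]]:
    """Subsample the majority class to the minority size, then split each
    class identically into train/val/test so every split is balanced."""
    split = split or SplitConfig()
    if seed is None:
        seed = split.seed
    bound = [m for m in labeled if m.label == BOUND]
    unbound = [m for m in labeled if m.label == UNBOUND]
    if not bound or not unbound:
        raise ClassBalanceError(
            f"need both classes, got {len(bound)} bound / {len(unbound)} unbound"
        )
    rng = np.random.default_rng(seed)
    n = min(len(bound), len(unbound))
    groups = []
    for cls in (bound, unbound):
        idx = rng.permutation(len(cls))[:n]
        groups.append([cls[i] for i in idx])
    n_train = int(np.floor(n * split.train_frac))
    n_val = int(np.floor(n * split.val_frac))
    n_test = n - n_train - n_val
    out = {"train": [], "val": [], "test": []}
    for cls in groups:
        out["train"].extend(cls[:n_train])
        out["val"].extend(cls[n_train : n_train + n_val])
        out["test"].extend(cls[n_train + n_val : n_train + n_val + n_test])
    for key in out:
        order = rng.permutation(len(out[key]))
        out[key] = [out[key][i] for i in order]
    return out
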