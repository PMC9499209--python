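"""Single-base footprint scores from aggregate (strand/size-pooled) cut counts.

At each base and each candidate center width ``c`` the score is the mean
count over the two flanks immediately outside the centered ``c``-window minus
the mean count inside it; the reported score is the maximum over center
widths, floored at zero.  High scores mark protected (protein-bound) bases,
zero marks accessible or flat regions.  Scores are computed on raw pooled
counts; depth effects are left to the downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FootprintConfig", "footprint_scores"]


@dataclass(frozen=True)
class FootprintConfig:
    center_widths: tuple[int, ...] = (5, 7, 9, 11)
    flank_width: int = 30

    def __post_init__(self):
        for c in self.center_widths:
            if c < 3 or c % 2 == 0:
                raise ValueError(f"center widths must be odd and >= 3, got {c}")
        if self.flank_width < max(self.center_widths):
            raise ValueError("flank_width must be >= max center width")


def _window_sums(csum: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sum of counts over [lo, hi) per position, bounds already clipped."""
    return csum[hi] - csum[lo]


def footprint_scores(
    aggregate: np.ndarray, config: FootprintConfig | None = None
) -> np.ndarray:
    """Flank-minus-center depletion score per base, max over center widths.

    Edge positions use truncated flanks (whatever bases are available).
    """
    config = config or FootprintConfig()
    x = np.asarray(aggregate, dtype=np.float64)
    n = x.size
    min_len = 2 * config.flank_width + max(config.center_widths)
    if n < min_len:
        raise ValueError(f"track length {n} < required {min_len}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    pos = np.arange(n)
    best = np.full(n, -np.inf)
    fw = config.flank_width
    for c in config.center_widths:
        half = c // 2
        c_lo = np.clip(pos - half, 0, n)
        c_hi = np.clip(pos + half + 1, 0, n)
        center_mean = _window_sums(csum, c_lo, c_hi) / (c_hi - c_lo)
        l_lo = np.clip(pos - half - fw, 0, n)
        l_hi = c_lo
        r_lo = c_hi
        r_hi = np.clip(pos + half + 1 + fw, 0, n)
        flank_n = (l_hi - l_lo) + (r_hi - r_lo)
        flank_sum = _window_sums(csum, l_lo, l_hi) + _window_sums(csum, r_lo, r_hi)
        with np.errstate(invalid="ignore"):
            flank_mean = np.where(flank_n > 0, flank_sum / np.maximum(flank_n, 1), 0.0)
        best = np.maximum(best, flank_mean - center_mean)
    return np.maximum(best, 0.0)
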