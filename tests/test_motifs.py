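import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacbind.formats import Peak
from atacbind.motifs import (
    BOUND,
    UNBOUND,
    UNLABELED,
    MPBS,
    PWM,
    ClassBalanceError,
    LabelConfig,
    ScanConfig,
    SplitConfig,
    balance_and_split,
    label_mpbs,
    pvalue_threshold,
    restrict_to_open,
    scan,
)


def enumerate_scores(pwm: PWM) -> np.ndarray:
    """Oracle: score every possible L-mer explicitly."""
    lods = pwm.log_odds()
    L = pwm.length
    return np.array(
        [lods[list(kmer), range(L)].sum() for kmer in itertools.product(range(4), repeat=L)]
    )


def brute_force_scan(genome, pwm, threshold):
    """Oracle: score every window on both strands with explicit loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    lods = pwm.log_odds()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.length
    hits = set()
    for chrom, seq in genome.items():
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if any(b not in idx for b in window):
                continue
            fwd = sum(lods[idx[b], j] for j, b in enumerate(window))
            rc = "".join(comp[b] for b in reversed(window))
            rev = sum(lods[idx[b], j] for j, b in enumerate(rc))
            if fwd >= threshold - 1e-9:
                hits.add((chrom, i, i + L, "+", round(fwd, 6)))
            if rev >= threshold - 1e-9:
                hits.add((chrom, i, i + L, "-", round(rev, 6)))
    return hits


class TestPvalueThreshold:
    def test_single_column_uniform(self):
        pwm = PWM("one", np.array([[9.0], [3.0], [2.0], [1.0]]))
        t = pvalue_threshold(pwm, ScanConfig(pvalue=0.25, score_granularity=1e-4))
        assert t == pytest.approx(pwm.max_score(), abs=1e-3)

    def test_p_one_gives_min_score(self, toy_pwm):
        t = pvalue_threshold(toy_pwm, ScanConfig(pvalue=1.0, score_granularity=1e-4))
        assert t == pytest.approx(toy_pwm.min_score(), abs=1e-3)

    def test_top1_of_256(self, toy_pwm):
        t = pvalue_threshold(
            toy_pwm, ScanConfig(pvalue=1 / 256, score_granularity=1e-4)
        )
        assert t == pytest.approx(enumerate_scores(toy_pwm).max(), abs=1e-3)

    @pytest.mark.parametrize("p", [1 / 256, 0.01, 0.05, 0.25])
    def test_enumeration_oracle_hit_sets(self, toy_pwm, p):
        scores = enumerate_scores(toy_pwm)
        t = pvalue_threshold(toy_pwm, ScanConfig(pvalue=p, score_granularity=1e-4))
        # smallest achievable threshold with tail probability <= p
        uniq = np.unique(scores)
        expected = next(
            v for v in uniq if (scores >= v - 1e-9).sum() / 256 <= p + 1e-12
        )
        assert t == pytest.approx(expected, abs=4e-4)
        # the selected k-mer set must match the oracle's exactly
        assert ((scores >= t - 1e-9) == (scores >= expected - 1e-9)).all()

    def test_empirical_exceedance(self, toy_pwm, rng):
        p = 0.05
        t = pvalue_threshold(toy_pwm, ScanConfig(pvalue=p, score_granularity=1e-4))
        lods = toy_pwm.log_odds()
        draws = rng.integers(0, 4, size=(100_000, 4))
        scores = lods[draws, np.arange(4)].sum(axis=1)
        freq = (scores >= t - 1e-9).mean()
        assert freq <= p + 3 * np.sqrt(p * (1 - p) / 100_000)

    def test_degenerate_pwm_rejected(self):
        # zero pseudocount would leave a forced-base column with probability 0
        mat = np.array([[1.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ValueError):
            PWM("deg", mat, pseudocount=0.0)


class TestScan:
    def test_planted_consensus(self, toy_pwm, rng):
        consensus = toy_pwm.consensus()
        bg = "".join(rng.choice(list("ACGT"), size=300))
        seq = bg[:100] + consensus + bg[104:]
        t = toy_pwm.max_score() - 1e-6
        hits = scan({"chr1": seq}, toy_pwm, t)
        assert any(h.start == 100 and h.strand == "+" for h in hits)

    def test_reverse_complement_reported_on_forward(self, toy_pwm):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        consensus = toy_pwm.consensus()
        rc = "".join(comp[b] for b in reversed(consensus))
        seq = "C" * 100 + rc + "C" * 100
        hits = scan({"chr1": seq}, toy_pwm, toy_pwm.max_score() - 1e-6)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) >= 1
        assert any(h.start == 100 and h.end == 104 for h in minus)

    def test_n_windows_skipped(self, toy_pwm):
        seq = toy_pwm.consensus().replace(toy_pwm.consensus()[1], "N", 1)
        hits = scan({"chr1": seq}, toy_pwm, toy_pwm.min_score())
        assert hits == []

    def test_exhaustive_oracle_2kb(self, toy_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        t = pvalue_threshold(toy_pwm, ScanConfig(pvalue=0.05, score_granularity=1e-4))
        hits = scan({"chr1": seq}, toy_pwm, t)
        got = {(h.chrom, h.start, h.end, h.strand, round(h.pwm_score, 6)) for h in hits}
        assert got == brute_force_scan({"chr1": seq}, toy_pwm, t)


class TestRestrictToOpen:
    peaks = [Peak("chr1", 100, 200), Peak("chr1", 500, 600)]

    def test_inside_kept(self):
        m = MPBS("chr1", 120, 130, "+", 1.0)
        assert restrict_to_open([m], self.peaks) == [m]

    def test_straddling_dropped(self):
        m = MPBS("chr1", 195, 205, "+", 1.0)
        assert restrict_to_open([m], self.peaks) == []

    def test_empty_peaks(self):
        m = MPBS("chr1", 120, 130, "+", 1.0)
        assert restrict_to_open([m], []) == []

    def test_wrong_chrom_dropped(self):
        m = MPBS("chr2", 120, 130, "+", 1.0)
        assert restrict_to_open([m], self.peaks) == []


class TestLabelMpbs:
    def _peak(self, start, end, summit_offset, signal=10.0):
        return Peak("chr1", start, end, "p", 0, signal, summit_offset)

    def test_two_mpbs_nearer_is_bound(self):
        # summit at 1000; MPBS centers at 1010 and 1040
        peak = self._peak(900, 1100, 100)
        ms = [MPBS("chr1", 1005, 1015, "+", 1.0), MPBS("chr1", 1035, 1045, "+", 1.0)]
        out = label_mpbs(ms, [peak])
        assert [m.label for m in out] == [BOUND, UNLABELED]

    def test_beyond_50bp_unlabeled(self):
        peak = self._peak(900, 1100, 100)
        m = MPBS("chr1", 1055, 1065, "+", 1.0)  # center 1060, 60 bp away
        out = label_mpbs([m], [peak])
        assert out[0].label == UNLABELED

    def test_far_from_peaks_unbound(self):
        peak = self._peak(900, 1100, 100)
        m = MPBS("chr1", 6000, 6010, "+", 1.0)
        assert label_mpbs([m], [peak])[0].label == UNBOUND

    def test_tie_broken_to_lower_coordinate(self):
        peak = self._peak(900, 1100, 100)
        ms = [MPBS("chr1", 985, 995, "+", 1.0), MPBS("chr1", 1005, 1015, "+", 1.0)]
        out = label_mpbs(ms, [peak])  # centers 990 and 1010, both 10 bp away
        assert [m.label for m in out] == [BOUND, UNLABELED]

    def test_highest_summit_wins(self):
        # same peak interval listed twice = two summits; higher signal at 1050
        peaks = [self._peak(900, 1100, 100, signal=5.0),
                 self._peak(900, 1100, 150, signal=50.0)]
        ms = [MPBS("chr1", 995, 1005, "+", 1.0), MPBS("chr1", 1045, 1055, "+", 1.0)]
        out = label_mpbs(ms, peaks)
        assert [m.label for m in out] == [UNLABELED, BOUND]

    def test_missing_summit_raises(self):
        with pytest.raises(ValueError):
            label_mpbs([], [Peak("chr1", 0, 100)])

    def test_labeling_is_a_partition(self, rng):
        peaks = [self._peak(1000 * i, 1000 * i + 200, 100) for i in range(5)]
        ms = [
            MPBS("chr1", int(p), int(p) + 10, "+", 1.0)
            for p in rng.integers(0, 6000, size=100)
        ]
        out = label_mpbs(ms, peaks)
        assert len(out) == len(ms)
        assert all(m.label in (BOUND, UNBOUND, UNLABELED) for m in out)

    def test_five_site_hand_built_toy(self):
        """One peak with two summits, plus a far MPBS: hand-derived labels."""
        peaks = [
            Peak("chr1", 1000, 1400, "pk", 0, 8.0, 100),   # summit 1100, weaker
            Peak("chr1", 1000, 1400, "pk", 0, 20.0, 300),  # summit 1300, highest
        ]
        ms = [
            MPBS("chr1", 1095, 1105, "+", 1.0),  # center 1100: near weak summit only
            MPBS("chr1", 1290, 1300, "+", 1.0),  # center 1295: 5 bp from top summit
            MPBS("chr1", 1310, 1320, "+", 1.0),  # center 1315: 15 bp, not closest
            MPBS("chr1", 1380, 1390, "+", 1.0),  # center 1385: inside peak, 85 bp
            MPBS("chr1", 9000, 9010, "+", 1.0),  # far outside any peak
        ]
        out = label_mpbs(ms, peaks)
        assert [m.label for m in out] == [
            UNLABELED, BOUND, UNLABELED, UNLABELED, UNBOUND,
        ]


def _make_labeled(n_bound, n_unbound):
    ms = []
    for i in range(n_bound):
        ms.append(MPBS("chr1", 100 * i, 100 * i + 10, "+", 1.0, BOUND))
    for i in range(n_unbound):
        ms.append(MPBS("chr2", 100 * i, 100 * i + 10, "+", 1.0, UNBOUND))
    return ms


class TestBalanceAndSplit:
    def test_paper_proportions(self):
        splits = balance_and_split(_make_labeled(100, 300), SplitConfig(seed=5))
        counts = {
            k: (
                sum(m.label == BOUND for m in v),
                sum(m.label == UNBOUND for m in v),
            )
            for k, v in splits.items()
        }
        assert counts == {"train": (70, 70), "val": (20, 20), "test": (10, 10)}

    def test_small_sets_stay_balanced(self):
        splits = balance_and_split(_make_labeled(3, 3), SplitConfig(seed=1))
        for v in splits.values():
            assert sum(m.label == BOUND for m in v) == sum(
                m.label == UNBOUND for m in v
            )

    def test_deterministic_under_seed(self):
        a = balance_and_split(_make_labeled(50, 80), SplitConfig(seed=9))
        b = balance_and_split(_make_labeled(50, 80), SplitConfig(seed=9))
        assert a == b

    def test_zero_class_raises(self):
        with pytest.raises(ClassBalanceError):
            balance_and_split(_make_labeled(5, 0))

    def test_no_example_reused_across_splits(self):
        splits = balance_and_split(_make_labeled(40, 60), SplitConfig(seed=2))
        seen = [(m.chrom, m.start) for v in splits.values() for m in v]
        assert len(seen) == len(set(seen))

    @settings(max_examples=20, deadline=None)
    @given(
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_balance_property(self, n_bound, n_unbound, seed):
        splits = balance_and_split(
            _make_labeled(n_bound, n_unbound), SplitConfig(seed=seed)
        )
        total = 0
        for v in splits.values():
            nb = sum(m.label == BOUND for m in v)
            nu = sum(m.label == UNBOUND for m in v)
            assert nb == nu
            total += nb
        assert total == min(n_bound, n_unbound)
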