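import itertools

import numpy as np
import pytest

from atacbind.evaluation import (
    EvalResult,
    auroc,
    footprint_overlap_scores,
    fps_baseline_scores,
    rank_compare,
)
from atacbind.motifs import MPBS


def brute_force_auroc(scores, labels):
    """Oracle: fraction of (positive, negative) pairs correctly ordered,
    ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_four_pair_enumeration(self):
        # pairs: (.9,.8)+1, (.9,.1)+1, (.3,.8)+0, (.3,.1)+1 -> 3/4
        assert auroc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_brute_force_equality(self, rng, n):
        scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


class TestFpsBaseline:
    def test_uniform_zero_region(self):
        tracks = {"chr1": np.zeros(1000)}
        m = MPBS("chr1", 100, 110, "+", 1.0)
        assert fps_baseline_scores([m], tracks)[0] == 0.0

    def test_single_base_mpbs(self):
        track = np.arange(100, dtype=float)
        m = MPBS("chr1", 42, 43, "+", 1.0)
        assert fps_baseline_scores([m], {"chr1": track})[0] == 42.0

    def test_mean_over_interval(self):
        track = np.arange(100, dtype=float)
        m = MPBS("chr1", 10, 14, "+", 1.0)
        assert fps_baseline_scores([m], {"chr1": track})[0] == pytest.approx(11.5)

    def test_planted_footprints_separate_classes(self, small_sim):
        from atacbind.footprint import footprint_scores
        from atacbind.signal import genome_cut_matrix

        sizes = {c: len(s) for c, s in small_sim.genome.items()}
        tracks = genome_cut_matrix(small_sim.fragments, sizes)
        fp = {c: footprint_scores(m.sum(axis=0).astype(float))
              for c, m in tracks.items()}
        truth = small_sim.truth
        ms = [MPBS(r.chrom, int(r.start), int(r.end), "+", 1.0, r.label)
              for r in truth.itertuples()]
        scores = fps_baseline_scores(ms, fp)
        bound = scores[truth.label.values == "bound"]
        unbound = scores[truth.label.values == "unbound"]
        assert bound.mean() > unbound.mean()


class TestFootprintOverlap:
    def test_no_regions_raw_scores(self):
        ms = [MPBS("chr1", 0, 10, "+", 5.0), MPBS("chr1", 20, 30, "+", 9.0)]
        np.testing.assert_array_equal(footprint_overlap_scores(ms, []), [5.0, 9.0])

    def test_all_overlap_uniform_shift(self):
        ms = [MPBS("chr1", 0, 10, "+", 5.0), MPBS("chr1", 20, 30, "+", 9.0)]
        out = footprint_overlap_scores(ms, [("chr1", 0, 100)])
        np.testing.assert_array_equal(out, [14.0, 18.0])
        labels = [1, 0]
        assert auroc(out, labels) == auroc([5.0, 9.0], labels)

    def test_overlap_outranks_non_overlap(self):
        ms = [MPBS("chr1", 0, 10, "+", 5.0), MPBS("chr1", 20, 30, "+", 9.0)]
        out = footprint_overlap_scores(ms, [("chr1", 5, 8)])
        np.testing.assert_array_equal(out, [14.0, 9.0])

    def test_one_bp_overlap_counts(self):
        m = MPBS("chr1", 10, 20, "+", 2.0)
        out = footprint_overlap_scores([m], [("chr1", 19, 25)])
        assert out[0] == 4.0

    def test_overlappers_outrank_property(self, rng):
        ms = [MPBS("chr1", int(p), int(p) + 10, "+", float(s))
              for p, s in zip(rng.integers(0, 10_000, 50), rng.uniform(0, 10, 50))]
        regions = [("chr1", int(p), int(p) + 15) for p in rng.integers(0, 10_000, 8)]
        out = footprint_overlap_scores(ms, regions)
        raw = np.array([m.pwm_score for m in ms])
        overlaps = out > raw
        if overlaps.any() and (~overlaps).any():
            assert out[overlaps].min() > out[~overlaps].max()


def _toy_results(aurocs_by_method, tfs=5, replicates=1):
    results = []
    for rep in range(replicates):
        for t in range(tfs):
            for method, vals in aurocs_by_method.items():
                results.append(
                    EvalResult(f"TF{t}", method, vals[t], 10, 10, rep)
                )
    return results


class TestRankCompare:
    def test_strict_winner_mean_rank_one(self):
        res = _toy_results({
            "a": [0.9] * 5, "b": [0.8] * 5, "c": [0.7] * 5,
        })
        comp = rank_compare(res)
        assert comp.mean_ranks["a"] == 1.0
        assert comp.mean_ranks["c"] == 3.0

    def test_identical_aurocs_tie(self):
        res = _toy_results({"a": [0.8] * 5, "b": [0.8] * 5, "c": [0.8] * 5})
        comp = rank_compare(res)
        assert (comp.mean_ranks == 2.0).all()

    def test_mean_ranks_average_to_half_k_plus_one(self, rng):
        vals = {m: list(rng.uniform(0.5, 1.0, size=6)) for m in "abc"}
        comp = rank_compare(_toy_results(vals, tfs=6, replicates=3))
        assert comp.mean_ranks.mean() == pytest.approx(2.0)

    def test_friedman_statistic_hand_computed(self):
        """3 methods x 5 TFs with no ties: chi2_F = 12n/(k(k+1)) sum R_j^2 - 3n(k+1)."""
        vals = {
            "a": [0.90, 0.85, 0.70, 0.95, 0.80],
            "b": [0.80, 0.90, 0.60, 0.90, 0.70],
            "c": [0.70, 0.80, 0.65, 0.85, 0.60],
        }
        comp = rank_compare(_toy_results(vals))
        # hand ranks per TF: a=[1,2,1,1,1], b=[2,1,3,2,2], c=[3,3,2,3,3]
        r_a, r_b, r_c = 6 / 5, 10 / 5, 14 / 5
        n, k = 5, 3
        expected = 12 * n / (k * (k + 1)) * (r_a**2 + r_b**2 + r_c**2) - 3 * n * (k + 1)
        assert comp.friedman_statistic == pytest.approx(expected)

    def test_missing_cell_raises(self):
        res = _toy_results({"a": [0.9] * 5, "b": [0.8] * 5})
        with pytest.raises(ValueError):
            rank_compare(res[:-1])

    def test_nemenyi_symmetric_with_unit_diagonal(self):
        vals = {"a": [0.9, 0.85, 0.8, 0.95, 0.9],
                "b": [0.7, 0.65, 0.6, 0.75, 0.7],
                "c": [0.5, 0.45, 0.4, 0.55, 0.5]}
        comp = rank_compare(_toy_results(vals))
        p = comp.nemenyi_pvalues
        assert (p.values == p.values.T).all()
        assert (np.diag(p.values) == 1.0).all()
        assert p.loc["a", "c"] < p.loc["a", "b"]


class TestEvalResult:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            EvalResult("TF", "m", float("nan"), 5, 5)
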