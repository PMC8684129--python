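"""Motif scanning, enrichment, accessibility and profile aggregation."""
import math

import numpy as np
import pandas as pd
import pytest

from chromstrat.motifs import (
    MotifModel,
    MotifOccurrence,
    encode,
    motif_accessibility,
    motif_enrichment,
    profile_matrix,
    revcomp,
    scan_motif,
)
from chromstrat.types import AccessibilityMatrix, CoverageTrack, GenomicInterval, RegionSet


def _regions(*triples):
    return RegionSet([GenomicInterval(*t) for t in triples])


def brute_force_scan(model: MotifModel, seq: str, background=None):
    """All-window log-odds scorer in plain Python (the independent oracle)."""
    bg = [0.25] * 4 if background is None else list(background)
    L = model.length
    lo = [[math.log2(model.pwm[i][b] / bg[b]) for b in range(4)] for i in range(L)]
    max_score = sum(max(row) for row in lo)
    threshold = model.score_fraction * max_score
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L].upper()
            if strand == "-":
                window = revcomp(window)
            if any(b not in code for b in window):
                continue
            score = sum(lo[i][code[window[i]]] for i in range(L))
            if score >= threshold:
                hits.append((off, strand, score))
    return sorted(hits)


class TestScanMotif:
    def test_planted_consensus_found_exactly(self):
        seq = "C" * 5 + "ACGTAA" + "C" * 9  # region length 20; revcomp absent
        model = MotifModel.from_consensus("m", "ACGTAA", score_fraction=1.0)
        hits = scan_motif(model, _regions(("chr1", 0, 20)), {"chr1": seq})
        assert [(h.start, h.strand) for h in hits] == [(5, "+")]

    def test_reverse_complement_hit_on_minus_strand(self):
        planted = revcomp("TGTTTACA")  # TGTAAACA, not a palindrome
        seq = "C" * 6 + planted + "C" * 6
        model = MotifModel.from_consensus("m", "TGTTTACA", score_fraction=1.0)
        hits = scan_motif(model, _regions(("chr1", 0, len(seq))), {"chr1": seq})
        assert [(h.start, h.strand) for h in hits] == [(6, "-")]

    def test_palindrome_hits_both_strands_at_same_interval(self):
        seq = "C" * 6 + "AACCGGTT" + "C" * 6  # AACCGGTT is its own revcomp
        model = MotifModel.from_consensus("m", "AACCGGTT", score_fraction=1.0)
        hits = scan_motif(model, _regions(("chr1", 0, len(seq))), {"chr1": seq})
        assert {(h.start, h.strand) for h in hits} == {(6, "+"), (6, "-")}

    def test_no_match_in_homopolymer(self):
        model = MotifModel.from_consensus("m", "ACGT", score_fraction=1.0)
        hits = scan_motif(model, _regions(("chr1", 0, 30)), {"chr1": "T" * 30})
        assert hits == []

    def test_region_shorter_than_motif_yields_no_hits(self):
        model = MotifModel.from_consensus("m", "ACGTACGT")
        hits = scan_motif(model, _regions(("chr1", 0, 5)), {"chr1": "ACGTA" + "T" * 5})
        assert hits == []

    def test_n_windows_never_hit(self):
        seq = "ACGNA" + "ACGTA"
        model = MotifModel.from_consensus("m", "ACGT", score_fraction=0.5)
        hits = scan_motif(model, _regions(("chr1", 0, 10)), {"chr1": seq})
        assert all("N" not in seq[h.start : h.start + 4] for h in hits)
        assert any(h.start == 5 for h in hits)

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        """100 random 2 kb sequences vs the all-window Python scorer."""
        model = MotifModel.from_consensus("m", "TGTTTACA", score_fraction=0.8)
        bases = np.array(list("ACGT"))
        for trial in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=2000)])
            expected = brute_force_scan(model, seq)
            got = sorted(
                (h.start, h.strand, h.score)
                for h in scan_motif(model, _regions(("chr1", 0, 2000)), {"chr1": seq})
            )
            assert [(s, st) for s, st, _ in got] == [(s, st) for s, st, _ in expected]
            for (_, _, a), (_, _, b) in zip(got, expected):
                assert a == pytest.approx(b, abs=1e-9)

    def test_pwm_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifModel("bad", np.full((6, 4), 0.3))
        with pytest.raises(ValueError, match=">= 4"):
            MotifModel.from_consensus("short", "ACG")


def binomial_tail_oracle(k, n, p):
    """Exact upper-tail binomial sum P(X >= k)."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestMotifEnrichment:
    def _sets(self, n_target, n_background):
        target = _regions(*[("chr1", i * 100, i * 100 + 50) for i in range(n_target)])
        background = _regions(*[("chr2", i * 100, i * 100 + 50) for i in range(n_background)])
        return target, background

    def _occ(self, region_ids):
        return [MotifOccurrence("m", rid, "chr1", 0, "+", 1.0) for rid in region_ids]

    def test_null_rates_give_fold_one(self):
        target, background = self._sets(100, 100)
        occ = self._occ(list(target.region_ids)[:30] + list(background.region_ids)[:30])
        res = motif_enrichment(target, background, occ)
        assert res.fold == pytest.approx(1.0)
        assert 0.4 < res.p_value <= 1.0

    def test_exact_binomial_oracle(self):
        target, background = self._sets(100, 100)
        occ = self._occ(list(target.region_ids)[:30] + list(background.region_ids)[:10])
        res = motif_enrichment(target, background, occ)
        assert res.fold == pytest.approx(3.0)
        assert res.p_value == pytest.approx(binomial_tail_oracle(30, 100, 0.1), rel=1e-9)

    def test_zero_background_hits_uses_rate_floor(self):
        target, background = self._sets(50, 200)
        res = motif_enrichment(target, background, self._occ(list(target.region_ids)[:5]))
        assert math.isinf(res.fold)
        assert res.p_value == pytest.approx(binomial_tail_oracle(5, 50, 1 / 400), rel=1e-9)

    def test_empty_target_rejected(self):
        _, background = self._sets(1, 10)
        with pytest.raises(ValueError):
            motif_enrichment(RegionSet([]), background, [])

    def test_null_calibration_on_shuffled_region_labels(self, rng):
        """Random target/background splits give p<0.05 in <=10% of 200 trials.

        The background is kept several-fold larger than the target, as in
        production use (5000 background regions vs a few hundred signature
        regions), so the plug-in background rate is well estimated.
        """
        all_regions = _regions(*[("chr1", i * 100, i * 100 + 50) for i in range(500)])
        ids = list(all_regions.region_ids)
        hit_ids = set(rng.choice(ids, size=150, replace=False))
        occ = self._occ(sorted(hit_ids))
        false_pos = 0
        for _ in range(200):
            perm = rng.permutation(ids)
            target = all_regions.subset(list(perm[:50]))
            background = all_regions.subset(list(perm[50:]))
            if motif_enrichment(target, background, occ).p_value < 0.05:
                false_pos += 1
        assert false_pos <= 20


class TestMotifAccessibility:
    def _matrix(self):
        df = pd.DataFrame({"S1": [4.2, 2.0, 4.0], "S2": [1.0, 2.0, 4.0]},
                          index=["r1", "r2", "r3"])
        return AccessibilityMatrix(df)

    def test_single_region(self):
        occ = [MotifOccurrence("m", "r1", "chr1", 0, "+", 1.0)]
        assert motif_accessibility(self._matrix(), occ)["S1"] == 4.2

    def test_duplicate_occurrences_counted_once(self):
        occ = [MotifOccurrence("m", "r2", "chr1", 0, "+", 1.0),
               MotifOccurrence("m", "r2", "chr1", 5, "-", 1.0),
               MotifOccurrence("m", "r3", "chr1", 0, "+", 1.0)]
        out = motif_accessibility(self._matrix(), occ)
        assert out["S1"] == pytest.approx(3.0)  # mean of {2, 4}

    def test_missing_region_rejected(self):
        occ = [MotifOccurrence("m", "rX", "chr1", 0, "+", 1.0)]
        with pytest.raises(ValueError, match="absent"):
            motif_accessibility(self._matrix(), occ)

    def test_no_occurrences_rejected(self):
        with pytest.raises(ValueError):
            motif_accessibility(self._matrix(), [])


class TestProfileMatrix:
    def test_uniform_signal(self):
        track = CoverageTrack({"chr1": [(0, 200, 2.0)]})
        res = profile_matrix(track, [("chr1", 100)], half_window=50, n_bins=10)
        assert np.allclose(res.matrix, 2.0)
        assert np.allclose(res.column_means, 2.0)

    def test_zero_window_anchor_excluded_from_means(self):
        track = CoverageTrack({"chr1": [(0, 200, 3.0)]})
        res = profile_matrix(track, [("chr1", 100), ("chr1", 10_000)],
                             half_window=50, n_bins=10)
        assert list(res.informative) == [True, False]
        assert np.allclose(res.column_means, 3.0)

    def test_step_edge_binning_oracle(self):
        # zero left of center, 3.0 right of center
        track = CoverageTrack({"chr1": [(100, 200, 3.0)]})
        res = profile_matrix(track, [("chr1", 100)], half_window=40, n_bins=8)
        assert np.allclose(res.matrix[0][:4], 0.0)
        assert np.allclose(res.matrix[0][4:], 3.0)
        # per-base oracle for a partial bin: shift the anchor off the edge
        res2 = profile_matrix(track, [("chr1", 95)], half_window=40, n_bins=8)
        per_base = track.values_at("chr1", np.arange(55, 135))
        assert np.allclose(res2.matrix[0], per_base.reshape(8, 10).mean(axis=1))

    def test_minus_strand_reversed(self):
        track = CoverageTrack({"chr1": [(100, 200, 3.0)]})
        plus = profile_matrix(track, [("chr1", 100, "+")], half_window=40, n_bins=8)
        minus = profile_matrix(track, [("chr1", 100, "-")], half_window=40, n_bins=8)
        assert np.allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_bin_divisibility_enforced(self):
        track = CoverageTrack({"chr1": [(0, 10, 1.0)]})
        with pytest.raises(ValueError):
            profile_matrix(track, [("chr1", 5)], half_window=50, n_bins=7)


def test_encode_and_revcomp():
    assert list(encode("ACGTN")) == [0, 1, 2, 3, 4]
    assert revcomp("AACCGGTT") == "AACCGGTT"  # palindrome
    assert revcomp("TGTTTACA") == "TGTAAACA"
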