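"""Motif models, scanning, enrichment and accessibility summaries.

Motifs are represented as position weight matrices (probabilities over
A, C, G, T per position), optionally built from a consensus string.
Scanning computes the log-odds score against background base frequencies
at every position of every region, on both strands, and calls a hit
wherever the score reaches ``score_fraction`` of the maximum achievable
score. Windows containing N never hit. Enrichment of a motif in a target
region set versus a background set is assessed with a one-sided binomial
test on per-region hit rates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .types import AccessibilityMatrix, CoverageTrack, RegionSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NEG = -1e9  # effective -inf for N windows, avoids inf arithmetic warnings


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class MotifModel:
    """A named PWM with a hit threshold expressed as a fraction of max score."""

    name: str
    pwm: np.ndarray  # shape (L, 4), rows sum to 1
    score_fraction: float = 0.8
    consensus: str | None = None

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must have shape (L, 4)")
        if self.pwm.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("pwm rows must each sum to 1")
        if not (0 < self.score_fraction <= 1):
            raise ValueError("score_fraction must lie in (0, 1]")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        score_fraction: float = 0.8,
        match_prob: float = 0.91,
    ) -> "MotifModel":
        consensus = consensus.upper()
        if any(b not in BASES for b in consensus):
            raise ValueError(f"consensus may contain only {BASES}, got {consensus!r}")
        off = (1.0 - match_prob) / 3.0
        pwm = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            pwm[i, _CODE[b]] = match_prob
        return cls(name=name, pwm=pwm, score_fraction=score_fraction, consensus=consensus)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """(L, 5) log2-odds matrix; the fifth column (N) is effectively -inf."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg <= 0).any():
            raise ValueError("background base frequencies must be 4 positive values summing to 1")
        with np.errstate(divide="ignore"):
            lo4 = np.log2(self.pwm / bg)
        lo4 = np.where(np.isfinite(lo4), lo4, _NEG)
        return np.hstack([lo4, np.full((self.length, 1), _NEG)])


@dataclass(frozen=True)
class MotifOccurrence:
    """A located motif hit, strand-aware, fully inside its region."""

    motif: str
    region_id: str
    chrom: str
    start: int  # 0-based genomic start of the hit window
    strand: str
    score: float


def scan_motif(
    model: MotifModel,
    regions: RegionSet,
    genome: dict[str, str],
    background: np.ndarray | None = None,
) -> list[MotifOccurrence]:
    """Scan every region of the genome for motif hits on both strands.

    A hit is any window whose log-odds score is >= ``score_fraction`` times
    the maximum achievable score. Regions shorter than the motif yield no
    hits. Occurrences are reported in region order, then position, with the
    plus strand first at equal positions.
    """
    lo = model.log_odds(background)
    L = model.length
    max_score = float(lo[:, :4].max(axis=1).sum())
    threshold = model.score_fraction * max_score
    lo_rc = lo[::-1][:, [3, 2, 1, 0, 4]]  # score of revcomp(window) against lo
    pos_idx = np.arange(L)
    hits: list[MotifOccurrence] = []
    for rid, iv in zip(regions.region_ids, regions):
        if iv.chrom not in genome:
            raise ValueError(f"region {rid}: chromosome {iv.chrom!r} absent from genome")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"region {rid} exceeds chromosome bounds")
        codes = encode(seq[iv.start : iv.end])
        if codes.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        plus = lo[pos_idx, windows].sum(axis=1)
        minus = lo_rc[pos_idx, windows].sum(axis=1)
        for off in range(windows.shape[0]):
            if plus[off] >= threshold:
                hits.append(
                    MotifOccurrence(model.name, rid, iv.chrom, iv.start + off, "+", float(plus[off]))
                )
            if minus[off] >= threshold:
                hits.append(
                    MotifOccurrence(model.name, rid, iv.chrom, iv.start + off, "-", float(minus[off]))
                )
    return hits


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    target_hits: int
    target_n: int
    background_hits: int
    background_n: int


def motif_enrichment(
    target: RegionSet,
    background: RegionSet,
    occurrences: list[MotifOccurrence],
) -> EnrichmentResult:
    """Fold enrichment and one-sided binomial p of per-region motif hit rates.

    ``fold`` is the ratio of the fraction of target regions with >= 1 hit to
    the same fraction in the background. The p-value is the upper binomial
    tail for the target hit count at the background rate. With zero
    background hits the fold is undefined (inf) and the p-value uses the
    rate floor ``1 / (2 * |background|)``.
    """
    if len(target) == 0:
        raise ValueError("target set must be non-empty")
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    hit_ids = {occ.region_id for occ in occurrences}
    k_t = sum(1 for rid in target.region_ids if rid in hit_ids)
    k_b = sum(1 for rid in background.region_ids if rid in hit_ids)
    n_t, n_b = len(target), len(background)
    if k_b == 0:
        rate = 1.0 / (2.0 * n_b)
        fold = float("inf")
    else:
        rate = k_b / n_b
        fold = (k_t / n_t) / rate
    p = float(binom.sf(k_t - 1, n_t, min(rate, 1.0)))
    return EnrichmentResult(fold, p, k_t, n_t, k_b, n_b)


def motif_accessibility(
    matrix: AccessibilityMatrix,
    occurrences: list[MotifOccurrence],
) -> pd.Series:
    """Per-sample mean accessibility over the distinct motif-bearing regions."""
    if not occurrences:
        raise ValueError("no motif occurrences supplied")
    ids = sorted({occ.region_id for occ in occurrences})
    missing = [r for r in ids if r not in matrix.data.index]
    if missing:
        raise ValueError(f"occurrence regions absent from matrix: {missing[:5]}")
    out = matrix.data.loc[ids].mean(axis=0)
    out.name = "motif_accessibility"
    return out


@dataclass
class ProfileResult:
    """Binned signal around anchors plus column means over informative anchors."""

    matrix: np.ndarray  # (n_anchors, n_bins)
    column_means: np.ndarray  # (n_bins,)
    informative: np.ndarray  # bool mask: anchors with any signal in window


def profile_matrix(
    track: CoverageTrack,
    anchors: list[tuple],
    half_window: int,
    n_bins: int,
) -> ProfileResult:
    """Mean signal in ``n_bins`` bins over ``[center - hw, center + hw)`` per anchor.

    Anchors are ``(chrom, center)`` or ``(chrom, center, strand)``; minus-
    strand anchors are reversed so bins read 5'->3'. Anchors whose entire
    window carries zero signal are excluded from the column means.
    ``n_bins`` must divide ``2 * half_window``.
    """
    if half_window <= 0 or n_bins <= 0 or (2 * half_window) % n_bins != 0:
        raise ValueError("n_bins must divide 2 * half_window")
    bw = 2 * half_window // n_bins
    mat = np.zeros((len(anchors), n_bins), dtype=float)
    for i, anchor in enumerate(anchors):
        chrom, center = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "+"
        positions = np.arange(center - half_window, center + half_window)
        per_base = track.values_at(chrom, positions)
        binned = per_base.reshape(n_bins, bw).mean(axis=1)
        mat[i] = binned[::-1] if strand == "-" else binned
    informative = mat.any(axis=1)
    if informative.any():
        col_means = mat[informative].mean(axis=0)
    else:
        logger.warning("all anchor windows carry zero signal; column means are nan")
        col_means = np.full(n_bins, np.nan)
    return ProfileResult(mat, col_means, informative)
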