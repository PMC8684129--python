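"""Union peak construction, per-region track scoring and rank normalization.

The union peak set is the base-pair union of all per-sample peak calls:
overlapping *and* book-ended (abutting) half-open intervals merge, since
fragmented adjacent peak calls describe one accessible region. Accessibility
is then scored per tumor as the length-weighted mean of its read-normalized
track over each union region, and each tumor's scores are converted to
fractional ranks (minimum to maximum accessibility) so that tumors become
comparable regardless of per-sample scale.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import AccessibilityMatrix, CoverageTrack, GenomicInterval, RankMatrix, RegionSet

logger = logging.getLogger(__name__)


def merge_peaks(peak_sets: Sequence[RegionSet]) -> RegionSet:
    """Merge peak sets into their base-pair union.

    Returns the maximal merged intervals covering every input interval,
    sorted by coordinate; book-ended intervals (``end == next start``) are
    merged. Raises ``ValueError`` for an empty input list.
    """
    if not peak_sets:
        raise ValueError("merge_peaks requires at least one peak set")
    all_ivs = sorted(
        (iv for rs in peak_sets for iv in rs),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    if not all_ivs:
        raise ValueError("merge_peaks requires at least one non-empty peak set")
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = all_ivs[0].chrom, all_ivs[0].start, all_ivs[0].end
    for iv in all_ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:  # book-ended counts as contiguous
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return RegionSet(merged)


def score_regions(regions: RegionSet, track: CoverageTrack) -> np.ndarray:
    """Length-weighted mean track signal per region.

    Uncovered bases contribute zero signal (bedGraph omits zero runs), so the
    mean is taken over the full region length. Regions on chromosomes absent
    from the track score 0 with a warning.
    """
    out = np.zeros(len(regions), dtype=float)
    track_chroms = set(track.chroms)
    missing: set[str] = set()
    for chrom, (rstarts, rends, positions) in regions.by_chrom().items():
        if chrom not in track_chroms:
            missing.add(chrom)
            continue
        starts, ends, values = track.steps(chrom)
        # steps overlapping region i: those with end > rstart and start < rend
        lo = np.searchsorted(ends, rstarts, side="right")
        hi = np.searchsorted(starts, rends, side="left")
        for i in range(len(rstarts)):
            if hi[i] <= lo[i]:
                continue
            sl = slice(lo[i], hi[i])
            ov = np.minimum(ends[sl], rends[i]) - np.maximum(starts[sl], rstarts[i])
            total = float(np.sum(ov * values[sl]))
            out[positions[i]] = total / (rends[i] - rstarts[i])
    if missing:
        logger.warning("regions on chromosomes absent from track scored 0: %s", sorted(missing))
    return out


def build_matrix(regions: RegionSet, tracks: Mapping[str, CoverageTrack]) -> AccessibilityMatrix:
    """Score every sample's track over the union regions."""
    if not tracks:
        raise ValueError("build_matrix requires at least one track")
    data = {sample: score_regions(regions, track) for sample, track in tracks.items()}
    df = pd.DataFrame(data, index=list(regions.region_ids))
    return AccessibilityMatrix(df)


def rank_normalize(matrix: AccessibilityMatrix) -> RankMatrix:
    """Column-wise ascending fractional ranks (ties get the mean rank)."""
    values = matrix.data.to_numpy(dtype=float)
    ranks = rankdata(values, axis=0, method="average")
    return RankMatrix(pd.DataFrame(ranks, index=matrix.data.index, columns=matrix.data.columns))
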