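"""Chromatin signature calling and region annotation.

A group's chromatin signature is the set of union-peak regions whose
group-vs-rest log2 fold change of mean accessibility (with a pseudo-count)
strictly exceeds a threshold. Signatures are called on the raw
accessibility matrix, not the rank matrix. Annotation helpers compute
distance to the nearest TSS, CpG dinucleotide density, genes with a TSS
within a window of the region midpoint, and a size-matched random
background sample of accessible regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stratify import GroupAssignment
from .types import AccessibilityMatrix, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Per-group signature regions with their log2FC values."""

    by_group: dict[int, pd.Series] = field(default_factory=dict)
    pseudo_count: float = 1.0
    lfc_threshold: float = 2.5

    def region_ids(self, group: int) -> list[str]:
        return list(self.by_group[group].index)

    def counts(self) -> dict[int, int]:
        return {g: len(s) for g, s in sorted(self.by_group.items())}


def _split_columns(
    matrix: AccessibilityMatrix, groups: GroupAssignment, group: int
) -> tuple[list[str], list[str]]:
    inside = [s for s in matrix.sample_ids if groups.mapping.get(s) == group]
    outside = [s for s in matrix.sample_ids if s in groups.mapping and groups.mapping[s] != group]
    if not inside:
        raise ValueError(f"group {group} has no members among matrix samples")
    if not outside:
        raise ValueError(f"group {group} covers every sample; no 'rest' to compare against")
    return inside, outside


def group_log2fc(
    matrix: AccessibilityMatrix,
    groups: GroupAssignment,
    group: int,
    pseudo_count: float = 1.0,
) -> pd.Series:
    """Per-region log2((mean_in + pc) / (mean_out + pc)) for one group vs rest."""
    inside, outside = _split_columns(matrix, groups, group)
    mean_in = matrix.data[inside].mean(axis=1)
    mean_out = matrix.data[outside].mean(axis=1)
    lfc = np.log2((mean_in + pseudo_count) / (mean_out + pseudo_count))
    lfc.name = f"log2fc_group{group}"
    return lfc


def define_signature(
    matrix: AccessibilityMatrix,
    groups: GroupAssignment,
    group: int,
    pseudo_count: float = 1.0,
    lfc_threshold: float = 2.5,
) -> pd.Series:
    """Regions with group-vs-rest log2FC strictly greater than the threshold."""
    lfc = group_log2fc(matrix, groups, group, pseudo_count=pseudo_count)
    return lfc[lfc > lfc_threshold]


def call_signatures(
    matrix: AccessibilityMatrix,
    groups: GroupAssignment,
    pseudo_count: float = 1.0,
    lfc_threshold: float = 2.5,
) -> SignatureSet:
    """Call signatures for every group present in the assignment."""
    sig = SignatureSet(pseudo_count=pseudo_count, lfc_threshold=lfc_threshold)
    for g in sorted(set(groups.mapping.values())):
        sig.by_group[g] = define_signature(
            matrix, groups, g, pseudo_count=pseudo_count, lfc_threshold=lfc_threshold
        )
    return sig


def distance_to_tss(regions: RegionSet, tss: pd.DataFrame | list[tuple]) -> np.ndarray:
    """Absolute distance (bp) from each region midpoint to the nearest TSS.

    ``tss`` is a DataFrame with columns (gene_id, chrom, pos[, strand]) or a
    list of ``(chrom, pos, strand)`` tuples. Regions on chromosomes without
    any TSS get ``nan`` and a warning.
    """
    if isinstance(tss, pd.DataFrame):
        entries = list(zip(tss["chrom"].astype(str), tss["pos"].astype(int)))
    else:
        entries = [(str(c), int(p)) for c, p, *_ in tss]
    if not entries:
        raise ValueError("TSS list must be non-empty")
    per_chrom: dict[str, list[int]] = {}
    for chrom, pos in entries:
        per_chrom.setdefault(chrom, []).append(pos)
    sorted_tss = {c: np.array(sorted(p), dtype=np.int64) for c, p in per_chrom.items()}
    out = np.full(len(regions), np.nan)
    missing: set[str] = set()
    for i, iv in enumerate(regions):
        positions = sorted_tss.get(iv.chrom)
        if positions is None:
            missing.add(iv.chrom)
            continue
        mid = iv.midpoint
        j = np.searchsorted(positions, mid)
        cands = []
        if j < len(positions):
            cands.append(abs(int(positions[j]) - mid))
        if j > 0:
            cands.append(abs(mid - int(positions[j - 1])))
        out[i] = min(cands)
    if missing:
        logger.warning("no TSS on chromosomes %s; distances flagged nan", sorted(missing))
    return out


def cpg_density(regions: RegionSet, genome: dict[str, str]) -> np.ndarray:
    """Count of CG dinucleotides divided by region length, per region.

    Case-insensitive; windows containing N never match. Regions exceeding
    the chromosome bounds raise ``ValueError``.
    """
    out = np.zeros(len(regions), dtype=float)
    for i, iv in enumerate(regions):
        if iv.chrom not in genome:
            raise ValueError(f"region {iv.coord_id}: chromosome absent from genome")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"region {iv.coord_id} exceeds chromosome length {len(seq)}"
            )
        out[i] = seq[iv.start : iv.end].upper().count("CG") / iv.length
    return out


def nearby_genes(
    regions: RegionSet,
    gene_tss: pd.DataFrame,
    window: int = 1_000_000,
) -> dict[str, list[str]]:
    """Genes whose TSS lies within ``window`` bp of each region midpoint.

    The bound is inclusive and only genes on the region's chromosome are
    considered. Returns ``{region_id: [gene_id, ...]}`` with genes ordered by
    TSS position then id.
    """
    if gene_tss["gene_id"].duplicated().any():
        raise ValueError("gene TSS table must have unique gene ids")
    per_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values(["pos", "gene_id"]).reset_index(drop=True)
        for c, sub in gene_tss.groupby("chrom")
    }
    out: dict[str, list[str]] = {}
    for rid, iv in zip(regions.region_ids, regions):
        sub = per_chrom.get(iv.chrom)
        if sub is None:
            out[rid] = []
            continue
        mid = iv.midpoint
        positions = sub["pos"].to_numpy()
        lo = np.searchsorted(positions, mid - window, side="left")
        hi = np.searchsorted(positions, mid + window, side="right")
        out[rid] = list(sub["gene_id"].iloc[lo:hi])
    return out


def sample_background(
    peaks: RegionSet,
    targets: RegionSet,
    n: int = 5000,
    seed: int = 0,
) -> RegionSet:
    """Randomly sample n accessible regions size-matched to the targets.

    Peaks are stratified into length deciles; the sample draws from each
    stratum in proportion to how many target regions fall into it, without
    replacement, deterministically for a given seed. When a stratum has
    fewer peaks than requested the shortfall is redistributed to the other
    strata with a warning. ``n`` may not exceed the number of peaks.
    """
    n_peaks = len(peaks)
    if n > n_peaks:
        raise ValueError(f"cannot sample n={n} background regions from {n_peaks} peaks")
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    if n == n_peaks:
        return RegionSet(list(peaks), list(peaks.region_ids))
    rng = np.random.default_rng(seed)
    peak_lengths = peaks.lengths()
    edges = np.quantile(peak_lengths, np.linspace(0.1, 0.9, 9))
    peak_bins = np.searchsorted(edges, peak_lengths, side="right")
    target_bins = np.searchsorted(edges, targets.lengths(), side="right")
    n_strata = 10
    target_counts = np.bincount(target_bins, minlength=n_strata).astype(float)
    want = target_counts / target_counts.sum() * n
    alloc = np.floor(want).astype(int)
    # largest-remainder apportionment to hit n exactly
    remainder_order = np.argsort(-(want - alloc), kind="stable")
    for b in remainder_order[: n - alloc.sum()]:
        alloc[b] += 1
    avail = np.bincount(peak_bins, minlength=n_strata)
    overflow = int(np.sum(np.maximum(alloc - avail, 0)))
    if overflow:
        logger.warning("background strata short by %d regions; redistributing", overflow)
        alloc = np.minimum(alloc, avail)
        spare_order = np.argsort(-(avail - alloc), kind="stable")
        i = 0
        while overflow > 0:
            b = spare_order[i % n_strata]
            if alloc[b] < avail[b]:
                alloc[b] += 1
                overflow -= 1
            i += 1
    chosen: list[int] = []
    for b in range(n_strata):
        if alloc[b] == 0:
            continue
        members = np.flatnonzero(peak_bins == b)
        chosen.extend(rng.choice(members, size=alloc[b], replace=False).tolist())
    chosen = sorted(chosen)
    ids = [peaks.region_ids[i] for i in chosen]
    return peaks.subset(ids)
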