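"""Core domain containers shared across the pipeline.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), matching BED/bedGraph semantics. Any function that
converts to 1-based display coordinates says so explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
STAGE_ORDER = ("I", "II", "III", "IV")
STAGES = STAGE_ORDER + ("unknown",)
PAM50_SUBTYPES = ("Basal-L", "Lum-A", "Lum-B", "HER2-enriched", "unknown")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    ``score``, when present, must be a finite non-negative real (peak
    calling scores); ``strand`` defaults to ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= int(self.start) < int(self.end)):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (half-open, empty intervals forbidden)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.score is not None:
            if not np.isfinite(self.score) or self.score < 0:
                raise ValueError(f"score must be a finite non-negative real, got {self.score!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, the anchor for TSS-distance and gene-window rules."""
        return (self.start + self.end) // 2

    @property
    def coord_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """An ordered, identifier-addressed set of genomic intervals.

    Intervals are stored sorted by ``(chrom, start, end)`` and each carries a
    unique stable region id (the interval name when names are unique,
    otherwise the coordinate string).
    """

    __slots__ = ("_intervals", "_ids", "_pos")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        region_ids: Sequence[str] | None = None,
    ) -> None:
        ivs = list(intervals)
        if region_ids is None:
            ids = [iv.coord_id for iv in ivs]
        else:
            ids = [str(r) for r in region_ids]
            if len(ids) != len(ivs):
                raise ValueError("region_ids must match intervals one-to-one")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs[i] for i in order)
        self._ids: tuple[str, ...] = tuple(ids[i] for i in order)
        if len(set(self._ids)) != len(self._ids):
            raise ValueError("region ids must be unique")
        self._pos = {rid: i for i, rid in enumerate(self._ids)}

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    @property
    def region_ids(self) -> tuple[str, ...]:
        return self._ids

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, region_id: str) -> GenomicInterval:
        return self._intervals[self._pos[region_id]]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._pos

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self._intervals], dtype=np.int64)

    def subset(self, region_ids: Sequence[str]) -> "RegionSet":
        idx = [self._pos[r] for r in region_ids]
        return RegionSet([self._intervals[i] for i in idx], [self._ids[i] for i in idx])

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """Per-chromosome ``(starts, ends, positions)`` arrays, sorted."""
        out: dict[str, tuple[list[int], list[int], list[int]]] = {}
        for i, iv in enumerate(self._intervals):
            out.setdefault(iv.chrom, ([], [], []))
            s, e, p = out[iv.chrom]
            s.append(iv.start)
            e.append(iv.end)
            p.append(i)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64), p)
            for c, (s, e, p) in out.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "region_id": list(self._ids),
                "score": [iv.score for iv in self._intervals],
                "strand": [iv.strand for iv in self._intervals],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._intervals == other._intervals and self._ids == other._ids


class CoverageTrack:
    """Step-function signal with bedGraph semantics.

    Holds per-chromosome sorted, non-overlapping ``(start, end, value)``
    steps. Positions not covered by any step have signal 0.
    """

    __slots__ = ("_steps",)

    def __init__(self, steps: Mapping[str, Iterable[tuple[int, int, float]]]) -> None:
        store: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, raw in steps.items():
            triples = sorted((int(s), int(e), float(v)) for s, e, v in raw)
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=float)
            if np.any(starts < 0) or np.any(ends <= starts):
                raise ValueError(f"{chrom}: steps must satisfy 0 <= start < end")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: step values must be finite")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping steps are not allowed")
            store[chrom] = (starts, ends, values)
        self._steps = store

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._steps))

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._steps:
            z = np.array([], dtype=np.int64)
            return z, z, np.array([], dtype=float)
        return self._steps[chrom]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal value at each base position (0 where uncovered)."""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends, values = self.steps(chrom)
        out = np.zeros(positions.shape, dtype=float)
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out


def _check_labeled(data: pd.DataFrame, what: str, non_negative: bool = True) -> pd.DataFrame:
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError(f"{what} must be non-empty")
    if data.index.duplicated().any():
        raise ValueError(f"{what}: duplicate row ids")
    if data.columns.duplicated().any():
        raise ValueError(f"{what}: duplicate sample ids")
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{what}: missing values are not allowed")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: values must be finite")
    if non_negative and (values < 0).any():
        raise ValueError(f"{what}: negative values are not allowed")
    out = data.astype(float)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


class AccessibilityMatrix:
    """Region x sample matrix of non-negative accessibility scores."""

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = _check_labeled(data, "accessibility matrix")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


class ExpressionMatrix:
    """Gene x sample matrix of non-negative normalized expression."""

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = _check_labeled(data, "expression matrix")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


class RankMatrix:
    """Per-sample (column-wise) fractional ranks of an accessibility matrix.

    Within each column values are ranks in ``[1, n_regions]`` with ties
    receiving the mean of the covered ranks, so every column sums to
    ``n (n + 1) / 2``.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = _check_labeled(data, "rank matrix")
        n = self.data.shape[0]
        expected = n * (n + 1) / 2.0
        sums = self.data.to_numpy().sum(axis=0)
        if not np.allclose(sums, expected, rtol=1e-9, atol=1e-6):
            raise ValueError("rank matrix columns must each sum to n(n+1)/2")
        vals = self.data.to_numpy()
        if vals.min() < 1.0 - 1e-9 or vals.max() > n + 1e-9:
            raise ValueError("ranks must lie in [1, n_regions]")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass
class TumorMetadata:
    """Clinical annotations for one tumor sample."""

    sample_id: str
    stage: str = "unknown"
    pam50: str = "unknown"
    ihc: str = "unknown"
    group: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.pam50 not in PAM50_SUBTYPES:
            raise ValueError(f"pam50 must be one of {PAM50_SUBTYPES}, got {self.pam50!r}")
        if self.group is not None and self.group < 1:
            raise ValueError("group, if set, must be a positive integer")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their conventional defaults.

    ``pseudo_count`` and ``lfc_threshold`` control signature calling;
    ``n_neighbors``/``k_groups`` the embedding and grouping; ``background_n``
    the size of the size-matched background sample; ``gene_window`` the
    region-to-gene TSS window in bp; ``decile``/``quartile`` the expression
    cut fractions; ``alpha_stars`` the significance star bands.
    """

    pseudo_count: float = 1.0
    lfc_threshold: float = 2.5
    n_neighbors: int = 10
    k_groups: int = 3
    background_n: int = 5000
    gene_window: int = 1_000_000
    decile: float = 0.10
    quartile: float = 0.25
    alpha_stars: tuple[float, float, float] = (1e-2, 1e-3, 1e-4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pseudo_count", "n_neighbors", "k_groups", "background_n", "gene_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("decile", "quartile"):
            v = getattr(self, name)
            if not (0 < v < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if not all(a > 0 for a in self.alpha_stars):
            raise ValueError("alpha_stars must be positive")
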