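"""Readers and writers for the plain-text formats the pipeline touches.

BED and bedGraph are parsed line by line so that malformed records can be
reported with their line number; FASTA goes through Biopython; matrices and
metadata tables go through pandas. All files are UTF-8, tab-separated where
tabular.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    AccessibilityMatrix,
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    RegionSet,
    TumorMetadata,
)

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")

METADATA_COLUMNS = ("sample_id", "stage", "pam50", "ihc")


class ParseError(ValueError):
    """A malformed record in a text file, reported with its line number."""


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3-BED6 file into a sorted :class:`RegionSet`.

    Coordinates are interpreted 0-based half-open. Comment/track/browser
    lines are skipped; columns beyond the sixth are ignored with a warning.
    Region ids are taken from the name column when names are present and
    unique, otherwise from coordinates.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    warned_extra = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}, line {lineno}: expected >= 3 tab-separated fields")
        if len(fields) > 6 and not warned_extra:
            logger.warning("%s: ignoring columns beyond 6 (first at line %d)", path, lineno)
            warned_extra = True
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: non-integer coordinates") from exc
        name = None
        if len(fields) >= 4 and fields[3] not in ("", "."):
            name = fields[3]
        score = None
        if len(fields) >= 5 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-numeric score") from exc
        strand = "."
        if len(fields) >= 6 and fields[5] not in ("",):
            strand = fields[5]
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    names = [iv.name for iv in intervals]
    ids = None
    if all(n is not None for n in names) and len(set(names)) == len(names) and names:
        ids = names  # type: ignore[assignment]
    return RegionSet(intervals, region_ids=ids)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3, or BED6 when any name/score/strand is set."""
    plain = all(
        iv.name is None and iv.score is None and iv.strand == "." for iv in regions
    )
    with open(path, "w", encoding="utf-8") as fh:
        for iv in regions:
            if plain:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Steps must be non-overlapping within each chromosome (abutting steps are
    fine); overlaps or non-numeric values raise :class:`ParseError`.
    """
    path = Path(path)
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}, line {lineno}: expected 4 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: non-numeric field") from exc
        if not np.isfinite(value):
            raise ParseError(f"{path}, line {lineno}: non-finite value")
        if not (0 <= start < end):
            raise ParseError(f"{path}, line {lineno}: require 0 <= start < end")
        steps.setdefault(chrom, []).append((start, end, value))
    try:
        return CoverageTrack(steps)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged rows ({exc})") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample id in header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell in {what}") from exc
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: missing cell in {what}")
    return df


def read_accessibility_matrix(path: str | Path) -> AccessibilityMatrix:
    """Read a region x sample TSV (header of sample ids, first column region ids)."""
    try:
        return AccessibilityMatrix(_read_table(path, "accessibility matrix"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV of non-negative normalized expression."""
    try:
        return ExpressionMatrix(_read_table(path, "expression matrix"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(matrix: AccessibilityMatrix | ExpressionMatrix | "pd.DataFrame", path: str | Path) -> None:
    df = matrix if isinstance(matrix, pd.DataFrame) else matrix.data
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: uppercased sequence}``."""
    path = Path(path)
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ParseError(f"{path}: duplicate header {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise ParseError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> list[TumorMetadata]:
    """Read a sample metadata TSV with columns sample_id, stage, pam50, ihc."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    out = []
    for _, row in df.iterrows():
        group = None
        if "group" in df.columns and row.get("group", "unknown") not in ("unknown", ""):
            group = int(row["group"])
        try:
            out.append(
                TumorMetadata(
                    sample_id=row["sample_id"],
                    stage=row["stage"],
                    pam50=row["pam50"],
                    ihc=row["ihc"],
                    group=group,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: sample {row['sample_id']!r}: {exc}") from exc
    return out


def write_metadata(metadata: list[TumorMetadata], path: str | Path) -> None:
    rows = []
    any_group = any(m.group is not None for m in metadata)
    for m in metadata:
        row = {"sample_id": m.sample_id, "stage": m.stage, "pam50": m.pam50, "ihc": m.ihc}
        if any_group:
            row["group"] = "" if m.group is None else str(m.group)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table (gene_id, chrom, pos[, strand]) as a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing TSS column {col!r}")
    if "strand" not in df.columns:
        df["strand"] = "."
    df["pos"] = df["pos"].astype(int)
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id in TSS table")
    return df[["gene_id", "chrom", "pos", "strand"]]


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(path, sep="\t", index=False)
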