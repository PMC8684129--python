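"""End-to-end orchestration: simulate -> matrix -> rank -> stratify ->
signatures -> motifs -> associations, with a manifest and summary report.

Every stage writes its artifacts under the configured output directory;
the manifest records input/output SHA-256 hashes, per-stage seeds and wall
times so that a rerun with the same config and seed can be verified
byte-identical for the deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .assoc import basal_filter, decile_tables, pearson, stage_trend
from .config import PipelineConfig
from .motifs import MotifModel, motif_accessibility, motif_enrichment, scan_motif
from .peak_matrix import build_matrix, merge_peaks, rank_normalize
from .signatures import call_signatures, sample_background
from .simulate import generate_cohort, write_cohort
from .stratify import assign_groups, embed
from .types import AccessibilityMatrix, RegionSet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline; returns the summary report (also written as JSON)."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    report: dict = {}

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)
                }
                logger.info("stage %s: done", name)

        return _Timer()

    bundle = None
    genome = None
    motif_models: list[MotifModel] = []
    expression = None
    metadata = []

    with _stage("inputs"):
        if config.simulate is not None:
            bundle = generate_cohort(config.simulate)
            write_cohort(bundle, out / "cohort")
            regions = bundle.regions
            matrix = bundle.accessibility
            expression = bundle.expression
            metadata = bundle.metadata
            genome = bundle.genome
            motif_models = bundle.motif_models
            peak_sets = list(bundle.peaks.values()) if bundle.peaks else []
            tracks = bundle.tracks or {}
        else:
            inp = config.inputs
            if inp.accessibility:
                matrix = cio.read_accessibility_matrix(inp.accessibility)
                regions = _regions_from_ids(matrix.region_ids)
                peak_sets, tracks = [], {}
            else:
                peak_files = sorted(Path(inp.peaks_dir).glob("*.bed"))
                track_files = sorted(Path(inp.tracks_dir).glob("*.bedgraph"))
                peak_sets = [cio.read_bed(p) for p in peak_files]
                tracks = {p.stem: cio.read_bedgraph(p) for p in track_files}
                regions = matrix = None  # built below
            if inp.expression:
                expression = cio.read_expression_matrix(inp.expression)
            if inp.metadata:
                metadata = cio.read_metadata(inp.metadata)
            if inp.genome:
                genome = cio.read_fasta(inp.genome)
            if inp.motifs:
                motif_models = _read_motif_tsv(inp.motifs)

    with _stage("build_matrix"):
        if config.simulate is None and config.inputs.accessibility is None:
            regions = merge_peaks(peak_sets)
            matrix = build_matrix(regions, tracks)
        cio.write_matrix(matrix, out / "accessibility.tsv")
        report["n_regions"] = len(matrix.region_ids)
        report["n_samples"] = len(matrix.sample_ids)

    with _stage("rank"):
        ranks = rank_normalize(matrix)
        cio.write_matrix(ranks.data, out / "ranks.tsv")

    acfg = config.analysis
    with _stage("stratify"):
        embedding = embed(ranks, n_neighbors=acfg.n_neighbors, seed=config.seed)
        groups = assign_groups(embedding, k=acfg.k_groups, seed=config.seed)
        pd.DataFrame(
            {
                "sample_id": embedding.sample_ids,
                "umap1": embedding.coordinates[:, 0],
                "umap2": embedding.coordinates[:, 1],
                "group": [groups.mapping[s] for s in embedding.sample_ids],
            }
        ).to_csv(out / "groups.tsv", sep="\t", index=False, float_format="%.6g")
        report["group_sizes"] = {str(g): n for g, n in groups.sizes().items()}
        manifest["stages"]["stratify"] = {"seed": config.seed}

    with _stage("signatures"):
        sigs = call_signatures(
            matrix, groups, pseudo_count=acfg.pseudo_count, lfc_threshold=acfg.lfc_threshold
        )
        sigdir = out / "signatures"
        sigdir.mkdir(exist_ok=True)
        for g, series in sigs.by_group.items():
            series.rename_axis("region_id").to_csv(
                sigdir / f"signature_{g}.tsv", sep="\t", float_format="%.6g"
            )
            if regions is not None:
                present = [r for r in series.index if r in regions]
                cio.write_bed(regions.subset(present), sigdir / f"signature_{g}.bed")
        report["signature_counts"] = {str(g): int(n) for g, n in sigs.counts().items()}

    occurrences_by_motif: dict[str, list] = {}
    with _stage("motifs"):
        report["motifs"] = {}
        if genome is not None and motif_models:
            all_sig_ids = [r for s in sigs.by_group.values() for r in s.index if r in regions]
            n_bg = min(acfg.background_n, max(1, len(regions) - 1))
            background = sample_background(
                regions,
                regions.subset(all_sig_ids) if all_sig_ids else regions,
                n=n_bg,
                seed=config.seed,
            )
            cio.write_bed(background, out / "background.bed")
            for model in motif_models:
                occ = scan_motif(model, regions, genome)
                occurrences_by_motif[model.name] = occ
                entry: dict = {"n_occurrences": len(occ)}
                for g, series in sigs.by_group.items():
                    ids = [r for r in series.index if r in regions]
                    if not ids:
                        continue
                    enr = motif_enrichment(regions.subset(ids), background, occ)
                    entry[f"group{g}_fold"] = None if np.isinf(enr.fold) else round(enr.fold, 4)
                    entry[f"group{g}_p"] = enr.p_value
                if occ:
                    access = motif_accessibility(matrix, occ)
                    access.rename_axis("sample_id").to_csv(
                        out / f"motif_accessibility_{model.name}.tsv",
                        sep="\t",
                        float_format="%.6g",
                    )
                report["motifs"][model.name] = entry

    with _stage("assoc"):
        assoc_report: dict = {}
        stage_of = {m.sample_id: m.stage for m in metadata}
        if metadata and genome is not None and motif_models:
            # stage trend of accessibility at each motif family's sites
            for model in motif_models:
                occ = occurrences_by_motif.get(model.name, [])
                if not occ:
                    continue
                access = motif_accessibility(matrix, occ)
                by_stage = {
                    s: access[[t for t in access.index if stage_of.get(t) == s]].to_numpy()
                    for s in config.stage_order
                }
                by_stage = {s: v for s, v in by_stage.items() if len(v) >= 2}
                if len(by_stage) >= 2:
                    trend = stage_trend(by_stage, direction="greater", alphas=acfg.alpha_stars)
                    assoc_report[f"stage_trend_{model.name}"] = [
                        {"pair": f"{c.stage_a}->{c.stage_b}", "p": c.p_value, "stars": c.stars}
                        for c in trend.comparisons
                    ]
        if expression is not None:
            candidate = (
                config.simulate.regulator_gene if config.simulate is not None else "ANP32E"
            )
            regulator = candidate if candidate in expression.data.index else None
            if regulator and genome is not None and motif_models:
                for model in motif_models:
                    occ = occurrences_by_motif.get(model.name, [])
                    if not occ:
                        continue
                    access = motif_accessibility(matrix, occ)
                    shared = [s for s in access.index if s in expression.data.columns]
                    if len(shared) >= 3:
                        r, p = pearson(
                            expression.data.loc[regulator, shared], access[shared]
                        )
                        assoc_report[f"{regulator}_vs_{model.name}_accessibility"] = {
                            "r": round(r, 4),
                            "p": p,
                        }
            try:
                kept, removed = basal_filter(expression, quartile=acfg.quartile)
                assoc_report["basal_filter"] = {
                    "kept": len(kept),
                    "removed": len(removed),
                }
            except ValueError:
                logger.info("marker genes absent; basal filter skipped")
            if regulator and len(expression.sample_ids) * acfg.decile >= 1:
                tables = decile_tables(expression, regulator, decile=acfg.decile)
                pd.DataFrame(
                    {"top_decile_mean": tables.top_means, "bottom_decile_mean": tables.bottom_means}
                ).rename_axis("gene_id").to_csv(
                    out / f"decile_tables_{regulator}.tsv", sep="\t", float_format="%.6g"
                )
                assoc_report["decile_table_n"] = len(tables.top_samples)
        report["assoc"] = assoc_report

    with _stage("report"):
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        hashes = {}
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                hashes[str(path.relative_to(out))] = _sha256(path)
        manifest["files"] = hashes
        # timings vary between reruns; hashes and seeds are the identity
        stable = {k: {kk: vv for kk, vv in v.items() if kk != "seconds"}
                  for k, v in manifest["stages"].items()}
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"version": manifest["version"], "seed": manifest["seed"],
                 "stages": stable, "files": hashes},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
    return report


def _regions_from_ids(region_ids) -> RegionSet | None:
    """Recover interval coordinates from 'chrom:start-end' ids when possible."""
    from .types import GenomicInterval

    intervals = []
    for rid in region_ids:
        try:
            chrom, span = rid.rsplit(":", 1)
            start, end = span.split("-")
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
        except (ValueError, IndexError):
            return None
    return RegionSet(intervals, list(region_ids))


def _read_motif_tsv(path) -> list[MotifModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for _, row in df.iterrows():
        frac = float(row["score_fraction"]) if "score_fraction" in df.columns else 0.8
        models.append(MotifModel.from_consensus(str(row["name"]), str(row["consensus"]), frac))
    return models
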