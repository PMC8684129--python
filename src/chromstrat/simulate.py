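"""Synthetic tumor cohort generator with planted statistical structure.

The generator emulates, at desk scale, the structure the stratification
pipeline assumes in a real cohort:

* ``k`` latent tumor groups with group-private high-accessibility
  ("signature") regions lifted ``signature_effect``-fold over a common
  baseline;
* transcription-factor motif consensus strings written into the genome
  sequence, concentrated in each group's signature regions and present at
  a background rate elsewhere in accessible regions;
* a stage-graded additive accessibility increase at one motif family's
  sites (the FOX-like family by default);
* a regulator gene (ANP32E-like) whose expression is coupled to the
  cohort's per-sample accessibility at that motif family through a
  Gaussian copula on ranks, targeting a chosen Pearson correlation;
* luminal marker genes (FOXA1, GATA3) expressed low in the basal-like
  group so that marker-quartile filtering has a planted answer.

Accessibility noise is multiplicative lognormal (scores are non-negative
and right-skewed, mimicking read-normalized tracks), mean-corrected so
that expected values equal the planted means. All randomness derives from
one integer seed through independent named substreams, so the same seed
reproduces every output byte-identically and omitting expensive components
(genome, tracks) does not perturb the rest.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as cio
from .motifs import MotifModel, revcomp
from .types import (
    AccessibilityMatrix,
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    RegionSet,
    STAGE_ORDER,
    TumorMetadata,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifFamily:
    """A motif family: consensus string plus the fraction of its owning
    group's signature regions that carry it."""

    name: str
    consensus: str
    signature_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.signature_fraction <= 1):
            raise ValueError("signature_fraction must lie in [0, 1]")
        if len(self.consensus) < 4:
            raise ValueError("consensus must be at least 4 bases")


DEFAULT_FAMILIES = (
    MotifFamily("SOX", "AACAATAG"),
    MotifFamily("FOX", "TGTTTACA"),
    MotifFamily("CEBP", "TTGCGCAA"),
)


@dataclass
class SyntheticCohortSpec:
    """Parameters of the planted cohort; defaults are the study conditions.

    ``signature_effect`` is a fold lift over ``baseline_mean`` (so planted
    signatures at the default 20-fold clear the 2.5 log2FC calling
    threshold with a pseudo-count of 1). ``stage_effect`` is an additive
    accessibility increment per stage rank (I=0 .. IV=3) at the
    ``stage_family`` motif's regions. ``regulator_coupling`` is the target
    Pearson correlation between the regulator gene's expression and
    per-sample mean accessibility at the stage family's motif regions.
    """

    n_tumors_per_group: tuple[int, ...] = (20, 20, 20)
    n_regions: int = 5000
    n_signature_per_group: int = 200
    baseline_mean: float = 2.0
    signature_effect: float = 20.0
    noise_sd: float = 0.25
    motif_families: tuple[MotifFamily, ...] = DEFAULT_FAMILIES
    motif_background_rate: float = 0.35
    stage_effect: float = 0.5
    stage_family: int = 2  # 1-based index into motif_families
    regulator_coupling: float = -0.5
    regulator_gene: str = "ANP32E"
    n_genes: int = 200
    region_length: int = 400
    genome_length: int = 4_000_000
    chrom_count: int = 3
    seed: int = 0

    @property
    def n_tumors(self) -> int:
        return int(sum(self.n_tumors_per_group))

    @property
    def k(self) -> int:
        return len(self.n_tumors_per_group)

    def validate(self) -> None:
        if self.k < 2 or any(n <= 0 for n in self.n_tumors_per_group):
            raise ValueError("need >= 2 groups with positive tumor counts")
        for name in ("n_regions", "n_signature_per_group", "baseline_mean",
                     "signature_effect", "n_genes", "region_length",
                     "genome_length", "chrom_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.stage_effect < 0:
            raise ValueError("noise_sd and stage_effect must be non-negative")
        if not (0 <= self.motif_background_rate <= 1):
            raise ValueError("motif_background_rate must lie in [0, 1]")
        if abs(self.regulator_coupling) >= 1:
            raise ValueError("|regulator_coupling| must be < 1")
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4 (regulator plus marker genes)")
        if self.k * self.n_signature_per_group > self.n_regions:
            raise ValueError("signature regions exceed total regions: infeasible spec")
        if not (1 <= self.stage_family <= len(self.motif_families)):
            raise ValueError("stage_family must index a motif family (1-based)")
        per_chrom = -(-self.n_regions // self.chrom_count)
        slot = (self.genome_length // self.chrom_count) // per_chrom
        if slot < self.region_length + 100:
            raise ValueError(
                "genome too small: regions cannot be placed with sufficient spacing"
            )


@dataclass
class CohortBundle:
    """Everything :func:`generate_cohort` produces, plus the planted truth."""

    spec: SyntheticCohortSpec
    regions: RegionSet
    accessibility: AccessibilityMatrix
    expression: ExpressionMatrix
    metadata: list[TumorMetadata]
    tss: pd.DataFrame
    motif_models: list[MotifModel]
    truth: dict
    genome: dict[str, str] | None = None
    tracks: dict[str, CoverageTrack] | None = None
    peaks: dict[str, RegionSet] | None = None


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("placement", "stage", "motif", "plant", "matrix",
             "expression", "regulator", "genome", "tss", "peaks")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _lognormal_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; exactly 1 when sd == 0."""
    if sd == 0:
        return np.ones(shape)
    z = rng.standard_normal(shape)
    return np.exp(sd * z - sd * sd / 2.0)


def _place_regions(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Evenly slotted region placement with random in-slot offsets.

    Slotting guarantees a minimum inter-region gap of half the free slot
    space, so small peak-boundary jitter can never make regions book-ended.
    """
    chrom_len = spec.genome_length // spec.chrom_count
    counts = [spec.n_regions // spec.chrom_count] * spec.chrom_count
    for i in range(spec.n_regions % spec.chrom_count):
        counts[i] += 1
    intervals = []
    L = spec.region_length
    for c, count in enumerate(counts):
        chrom = f"chr{c + 1}"
        slot = chrom_len // count
        margin = max(1, (slot - L) // 2)
        offsets = rng.integers(0, margin, size=count)
        for i in range(count):
            start = int(i * slot + offsets[i])
            intervals.append(GenomicInterval(chrom, start, start + L))
    return RegionSet(intervals), chrom_len


def generate_cohort(
    spec: SyntheticCohortSpec,
    with_genome: bool = True,
    with_tracks: bool = True,
) -> CohortBundle:
    """Generate a full synthetic cohort with its planted truth record.

    ``with_genome=False`` / ``with_tracks=False`` skip the genome sequence
    and per-sample track/peak synthesis; because every component draws from
    its own seed substream, the remaining outputs are identical either way.
    """
    spec.validate()
    rng = _streams(spec.seed)
    k = spec.k
    n_samples = spec.n_tumors
    sample_ids = [f"T{i + 1:03d}" for i in range(n_samples)]
    group_of = np.concatenate(
        [np.full(n, g + 1, dtype=int) for g, n in enumerate(spec.n_tumors_per_group)]
    )

    # stages: balanced within each group, shuffled so order carries no signal
    stage_rank = np.zeros(n_samples, dtype=int)
    for g in range(1, k + 1):
        idx = np.flatnonzero(group_of == g)
        ranks = np.array([i % 4 for i in range(len(idx))])
        rng["stage"].shuffle(ranks)
        stage_rank[idx] = ranks
    stages = [STAGE_ORDER[r] for r in stage_rank]

    regions, chrom_len = _place_regions(spec, rng["placement"])
    region_ids = list(regions.region_ids)
    n_regions = spec.n_regions

    # group-private signature regions
    sig_pool = rng["placement"].choice(
        n_regions, size=k * spec.n_signature_per_group, replace=False
    )
    signature_rows = {
        g + 1: np.sort(sig_pool[g * spec.n_signature_per_group : (g + 1) * spec.n_signature_per_group])
        for g in range(k)
    }
    in_any_signature = np.zeros(n_regions, dtype=bool)
    for rows in signature_rows.values():
        in_any_signature[rows] = True
    non_sig_rows = np.flatnonzero(~in_any_signature)

    # motif carriers: a fraction of the owning group's signatures, plus a
    # background rate across non-signature accessible regions
    family_rows: dict[str, np.ndarray] = {}
    for f_idx, fam in enumerate(spec.motif_families):
        carriers = []
        if f_idx < k:
            own = signature_rows[f_idx + 1]
            n_sig_carriers = int(round(fam.signature_fraction * len(own)))
            carriers.append(
                np.sort(rng["motif"].choice(own, size=n_sig_carriers, replace=False))
            )
        n_bg = int(round(spec.motif_background_rate * len(non_sig_rows)))
        if n_bg:
            carriers.append(
                np.sort(rng["motif"].choice(non_sig_rows, size=n_bg, replace=False))
            )
        family_rows[fam.name] = (
            np.unique(np.concatenate(carriers)) if carriers else np.array([], dtype=int)
        )

    stage_fam = spec.motif_families[spec.stage_family - 1]
    stage_rows = family_rows[stage_fam.name]

    # expected accessibility, then mean-one lognormal noise
    mu = np.full((n_regions, n_samples), float(spec.baseline_mean))
    for g, rows in signature_rows.items():
        members = np.flatnonzero(group_of == g)
        mu[np.ix_(rows, members)] = spec.baseline_mean * spec.signature_effect
    mu[stage_rows, :] += spec.stage_effect * stage_rank[None, :]
    values = mu * _lognormal_noise(rng["matrix"], spec.noise_sd, mu.shape)
    accessibility = AccessibilityMatrix(
        pd.DataFrame(values, index=region_ids, columns=sample_ids)
    )

    # per-sample mean accessibility at the stage family's motif regions:
    # the coupling target for the regulator gene
    stage_family_access = values[stage_rows, :].mean(axis=0)

    # regulator expression via a Gaussian copula on ranks
    rho = spec.regulator_coupling
    order_stat = stage_family_access.argsort().argsort()  # 0-based ranks, ties impossible a.s.
    z_a = norm.ppf((order_stat + 0.5) / n_samples)
    eps = rng["regulator"].standard_normal(n_samples)
    z_e = rho * z_a + np.sqrt(1.0 - rho * rho) * eps
    regulator_expr = 10.0 * np.exp(0.3 * z_e)

    # marker genes: luminal markers low in group 1 (basal-like), the
    # proliferation marker high in group 1
    marker_means = {
        "FOXA1": {1: 2.0, "rest": 18.0},
        "GATA3": {1: 2.0, "rest": 15.0},
        "KI67": {1: 20.0, "rest": 5.0},
    }
    gene_ids = [spec.regulator_gene] + list(marker_means) + [
        f"GENE{i + 1:04d}" for i in range(spec.n_genes - 1 - len(marker_means))
    ]
    expr = np.empty((len(gene_ids), n_samples))
    expr[0] = regulator_expr
    for row, gene in enumerate(gene_ids[1:], start=1):
        if gene in marker_means:
            base = np.where(group_of == 1, marker_means[gene][1], marker_means[gene]["rest"])
        else:
            base = np.full(n_samples, 5.0)
        expr[row] = base * np.exp(0.3 * rng["expression"].standard_normal(n_samples))
    expression = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))

    # clinical metadata mirroring the group structure
    pam50_by_group = {1: ["Basal-L"], 2: ["Lum-B", "HER2-enriched"], 3: ["Lum-A"]}
    ihc_by_group = {1: ["TNBC"], 2: ["HR+/HER2-", "HR+/HER2+"], 3: ["HR+/HER2-"]}
    metadata = []
    per_group_counter: dict[int, int] = {}
    for i, s in enumerate(sample_ids):
        g = int(group_of[i])
        j = per_group_counter.get(g, 0)
        per_group_counter[g] = j + 1
        pam = pam50_by_group.get(g, ["unknown"])
        ihc = ihc_by_group.get(g, ["unknown"])
        metadata.append(
            TumorMetadata(
                sample_id=s,
                stage=stages[i],
                pam50=pam[j % len(pam)],
                ihc=ihc[j % len(ihc)],
            )
        )

    # TSS table: genes scattered uniformly over the genome
    tss_chroms = rng["tss"].integers(1, spec.chrom_count + 1, size=len(gene_ids))
    tss_pos = rng["tss"].integers(0, chrom_len, size=len(gene_ids))
    tss_strand = np.where(rng["tss"].integers(0, 2, size=len(gene_ids)) == 0, "+", "-")
    tss = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c}" for c in tss_chroms],
            "pos": tss_pos.astype(int),
            "strand": tss_strand,
        }
    )

    motif_models = [
        MotifModel.from_consensus(f.name, f.consensus) for f in spec.motif_families
    ]

    truth: dict = {
        "groups": {s: int(g) for s, g in zip(sample_ids, group_of)},
        "stages": {s: st for s, st in zip(sample_ids, stages)},
        "signature_regions": {
            str(g): [region_ids[r] for r in rows] for g, rows in signature_rows.items()
        },
        "motif_regions": {
            name: [region_ids[r] for r in rows] for name, rows in family_rows.items()
        },
        "stage_family": stage_fam.name,
        "regulator_gene": spec.regulator_gene,
        "params": _spec_to_jsonable(spec),
        "occurrences": [],
    }

    genome = None
    if with_genome:
        genome = _build_genome(spec, regions, family_rows, rng, chrom_len, truth)

    tracks = peaks = None
    if with_tracks:
        tracks, peaks = _build_tracks_and_peaks(spec, regions, values, sample_ids, rng["peaks"], chrom_len)

    return CohortBundle(
        spec=spec,
        regions=regions,
        accessibility=accessibility,
        expression=expression,
        metadata=metadata,
        tss=tss,
        motif_models=motif_models,
        truth=truth,
        genome=genome,
        tracks=tracks,
        peaks=peaks,
    )


def _build_genome(spec, regions, family_rows, rng, chrom_len, truth):
    """Random uniform-base genome with motif consensi written into carriers."""
    region_ids = list(regions.region_ids)
    intervals = list(regions)
    seqs = {}
    for c in range(spec.chrom_count):
        codes = rng["genome"].integers(0, 4, size=chrom_len)
        seqs[f"chr{c + 1}"] = np.array(list("ACGT"))[codes]
    occupied: dict[int, list[tuple[int, int]]] = {}
    occurrences = []
    margin = 20
    for fam in spec.motif_families:
        motif = fam.consensus.upper()
        L = len(motif)
        for row in family_rows[fam.name]:
            iv = intervals[row]
            lo, hi = margin, iv.length - margin - L
            if hi <= lo:
                raise ValueError("region too short to plant motif with margins")
            taken = occupied.setdefault(row, [])
            offset = None
            for _ in range(200):
                cand = int(rng["plant"].integers(lo, hi))
                if all(cand + L <= s or cand >= e for s, e in taken):
                    offset = cand
                    break
            if offset is None:
                raise ValueError("could not place motif without overlap; region too crowded")
            taken.append((offset, offset + L))
            strand = "+" if rng["plant"].integers(0, 2) == 0 else "-"
            written = motif if strand == "+" else revcomp(motif)
            start = iv.start + offset
            seqs[iv.chrom][start : start + L] = list(written)
            occurrences.append(
                {
                    "motif": fam.name,
                    "region_id": region_ids[row],
                    "chrom": iv.chrom,
                    "start": int(start),
                    "strand": strand,
                }
            )
    truth["occurrences"] = occurrences
    return {c: "".join(arr) for c, arr in seqs.items()}


def _build_tracks_and_peaks(spec, regions, values, sample_ids, rng, chrom_len):
    """Per-sample bedGraph-style tracks and jittered peak calls.

    Each sample's track is a step of its accessibility score over each
    region (zero elsewhere); its peak set is every region whose score
    clears half the baseline, with boundaries jittered by up to 10 bp to
    imitate peak-caller variability. Region spacing guarantees jittered
    peaks never merge across regions.
    """
    tracks: dict[str, CoverageTrack] = {}
    peaks: dict[str, RegionSet] = {}
    call_threshold = 0.5 * spec.baseline_mean
    intervals = list(regions)
    for j, sample in enumerate(sample_ids):
        steps: dict[str, list[tuple[int, int, float]]] = {}
        peak_ivs = []
        jit = rng.integers(0, 11, size=(len(intervals), 2))
        for i, iv in enumerate(intervals):
            v = float(values[i, j])
            steps.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
            if v > call_threshold:
                start = max(0, iv.start - int(jit[i, 0]))
                end = min(chrom_len, iv.end + int(jit[i, 1]))
                peak_ivs.append(GenomicInterval(iv.chrom, start, end))
        tracks[sample] = CoverageTrack(steps)
        peaks[sample] = RegionSet(peak_ivs)
    return tracks, peaks


def _spec_to_jsonable(spec: SyntheticCohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["n_tumors_per_group"] = list(spec.n_tumors_per_group)
    d["motif_families"] = [dataclasses.asdict(f) for f in spec.motif_families]
    return d


def spec_from_dict(d: dict) -> SyntheticCohortSpec:
    """Build a spec from a plain mapping (e.g. parsed YAML), rejecting unknown keys."""
    d = dict(d)
    fams = d.pop("motif_families", None)
    known = {f.name for f in dataclasses.fields(SyntheticCohortSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
    if "n_tumors_per_group" in d:
        d["n_tumors_per_group"] = tuple(int(x) for x in d["n_tumors_per_group"])
    spec = SyntheticCohortSpec(**d)
    if fams is not None:
        spec.motif_families = tuple(
            MotifFamily(**f) if isinstance(f, dict) else f for f in fams
        )
    spec.validate()
    return spec


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, str]:
    """Write the cohort to disk as plain-text files; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _reg(key: str, path: Path) -> Path:
        files[key] = str(path)
        return path

    cio.write_matrix(bundle.accessibility, _reg("accessibility", outdir / "accessibility.tsv"))
    cio.write_matrix(bundle.expression, _reg("expression", outdir / "expression.tsv"))
    cio.write_metadata(bundle.metadata, _reg("metadata", outdir / "metadata.tsv"))
    cio.write_tss_table(bundle.tss, _reg("tss", outdir / "tss.tsv"))
    cio.write_bed(bundle.regions, _reg("regions", outdir / "regions.bed"))
    with open(_reg("truth", outdir / "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(_reg("motifs", outdir / "motifs.tsv"), "w", encoding="utf-8") as fh:
        fh.write("name\tconsensus\tscore_fraction\n")
        for m in bundle.motif_models:
            fh.write(f"{m.name}\t{m.consensus}\t{m.score_fraction:g}\n")
    if bundle.genome is not None:
        cio.write_fasta(bundle.genome, _reg("genome", outdir / "genome.fa"))
    if bundle.tracks is not None and bundle.peaks is not None:
        (outdir / "tracks").mkdir(exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
        for sample, track in bundle.tracks.items():
            cio.write_bedgraph(track, outdir / "tracks" / f"{sample}.bedgraph")
        for sample, rs in bundle.peaks.items():
            cio.write_bed(rs, outdir / "peaks" / f"{sample}.bed")
        files["tracks_dir"] = str(outdir / "tracks")
        files["peaks_dir"] = str(outdir / "peaks")
    return files
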