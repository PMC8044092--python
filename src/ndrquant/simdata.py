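"""Synthetic cfDNA generator with full ground truth.

Emulates the statistical structure the NDR degradation method relies on:

* a compact genome of non-overlapping multi-exon transcripts;
* tissue-specific expression tables in which planted tumor-specific and
  blood-specific transcripts clear the shortlisting thresholds with a
  margin of at least 2x (tumor-specific: fpkm > 20 in the tumor tissue,
  < 0.5 in blood; blood-specific: the converse);
* per-tissue fragment intensities that dip inside the promoter and first
  exon-intron junction NDR windows of genes expressed in that tissue, with
  a monotone expression->dip mapping, per-gene accessibility jitter, and
  phased-nucleosome oscillation in the flanks;
* cfDNA fragment lengths from a mono/di-nucleosomal mixture with mode
  166 bp;
* samples as tissue mixtures: healthy plasma is blood-only, cancer plasma a
  tumor/blood mixture of known fraction, with per-fragment provenance
  labels and per-patient random effects on dip depth.

Only NDRs of tissue-specific genes carry burden information; everything is
seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import FragmentSet, HEALTHY_SOURCE, TUMOR_SOURCE, _PROV_CODES
from .regions import NDRRegion, TranscriptModel, WindowSpec, derive_ndr_regions

GENE_CLASSES = ("tumor_specific", "tumor2_specific", "blood_specific", "shared", "unexpressed")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator (defaults are the reference scenario)."""

    # gene-class counts
    n_tumor_genes: int = 50
    n_tumor2_genes: int = 0
    n_blood_genes: int = 50
    n_shared_genes: int = 20
    n_unexpressed_genes: int = 30
    # genome layout (bp)
    chrom: str = "chr1"
    genome_length: int | None = None  # computed from the layout when None
    exon1_length: tuple[int, int] = (600, 1400)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (400, 900)
    n_exons: tuple[int, int] = (2, 4)
    intergenic_gap: tuple[int, int] = (4500, 6500)
    margin: int = 3000
    # expression sampler (median fpkm); specific genes clear thresholds 2x
    fpkm_specific: tuple[float, float] = (20.0, 200.0)  # log-uniform
    fpkm_off_max: float = 0.45
    fpkm_shared: tuple[float, float] = (5.0, 50.0)  # log-uniform, all tissues
    # expression -> NDR relative-coverage dip
    dip_floor: float = 0.3
    dip_slope: float = 0.5 / np.log10(31.0)  # fpkm 30 -> target ~0.5
    dip_jitter_sd: float = 0.25  # per-gene lognormal sd on dip depth
    dip_ndr_jitter_sd: float = 0.12  # extra per-NDR lognormal sd (promoter vs junction)
    dip_shoulder: int = 250  # raised-cosine taper (bp) beyond the core window
    # nucleosome phasing in flanks
    phase_amplitude: float = 0.15
    phase_period: float = 190.0
    # fragment length mixture
    length_mode: int = 166
    length_sd: float = 10.0
    di_fraction: float = 0.1
    di_mode: int = 332
    di_sd: float = 25.0
    min_length: int = 60
    # biological variability of dip depth
    patient_effect_sd: float = 0.1  # tumor tissues, per patient
    donor_effect_sd: float = 0.05  # blood tissue, per donor/sample
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if self.dip_floor <= 0 or self.dip_floor > 1:
            raise ValueError("dip_floor must lie in (0, 1]")
        for count in (self.n_tumor_genes, self.n_tumor2_genes, self.n_blood_genes,
                      self.n_shared_genes, self.n_unexpressed_genes):
            if count < 0:
                raise ValueError("gene counts must be >= 0")

    @property
    def tissues(self) -> tuple[str, ...]:
        return ("tumor", "tumor2", "blood") if self.n_tumor2_genes else ("tumor", "blood")

    @property
    def n_genes(self) -> int:
        return (self.n_tumor_genes + self.n_tumor2_genes + self.n_blood_genes
                + self.n_shared_genes + self.n_unexpressed_genes)

    @property
    def mean_fragment_length(self) -> float:
        return (1 - self.di_fraction) * self.length_mode + self.di_fraction * self.di_mode

    def dip_target(self, fpkm: float) -> float:
        """Monotone decreasing expression -> relative-coverage target, floored."""
        return float(max(self.dip_floor, 1.0 - self.dip_slope * np.log10(fpkm + 1.0)))


@dataclass
class GroundTruth:
    """Everything a test oracle needs about the simulated reference and samples."""

    gene_classes: pd.Series  # transcript_id -> class
    informative_features: list[str]  # NDR feature_ids of tissue-specific genes
    ndr_targets: pd.DataFrame  # feature_id x tissue -> target relative coverage
    samples: list[dict] = field(default_factory=list)


@dataclass
class SimReference:
    config: SimConfig
    transcripts: list[TranscriptModel]
    expression: pd.DataFrame
    truth: GroundTruth
    genome_length: int
    regions: list[NDRRegion]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.config.chrom: self.genome_length}


def _layout_transcript(rng: np.random.Generator, config: SimConfig,
                       tid: str, gid: str, pos: int) -> tuple[TranscriptModel, int]:
    """Place one transcript starting at genomic `pos`; returns (model, end)."""
    n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
    lens = [int(rng.integers(*config.exon1_length))]
    for _ in range(n_ex - 1):
        lens.append(int(rng.integers(*config.intron_length)))  # intron
        lens.append(int(rng.integers(*config.exon_length)))  # exon
    strand = "+" if rng.random() < 0.5 else "-"
    layout = lens if strand == "+" else lens[::-1]
    cursor = pos
    blocks = []
    for i, length in enumerate(layout):
        blocks.append((cursor, cursor + length))
        cursor += length
    genomic_exons = blocks[::2]  # exons alternate with introns
    exons = tuple(genomic_exons) if strand == "+" else tuple(genomic_exons[::-1])
    tx = TranscriptModel(tid, gid, config.chrom, strand, exons)
    return tx, cursor


def _draw_expression(rng: np.random.Generator, config: SimConfig,
                     classes: Sequence[str]) -> pd.DataFrame:
    tissues = config.tissues
    lo, hi = np.log10(config.fpkm_specific[0]), np.log10(config.fpkm_specific[1])
    slo, shi = np.log10(config.fpkm_shared[0]), np.log10(config.fpkm_shared[1])
    rows = []
    for cls in classes:
        row = {}
        for tissue in tissues:
            if cls == "unexpressed":
                row[f"fpkm_{tissue}"] = 0.0
            elif cls == "shared":
                row[f"fpkm_{tissue}"] = 10 ** rng.uniform(slo, shi)
            elif cls == f"{tissue}_specific":
                row[f"fpkm_{tissue}"] = 10 ** rng.uniform(lo, hi)
            else:
                row[f"fpkm_{tissue}"] = rng.uniform(0.0, config.fpkm_off_max)
        row["unexpressed"] = cls == "unexpressed"
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_reference(config: SimConfig = SimConfig(), seed: int | None = None) -> SimReference:
    """Genome, annotation, expression table, NDR windows, and ground truth.

    Gene placement, strand, exon structure and expression levels are seeded;
    two seeds give different coordinates but identical class counts.
    """
    rng = np.random.default_rng(seed)
    classes = (
        ["tumor_specific"] * config.n_tumor_genes
        + ["tumor2_specific"] * config.n_tumor2_genes
        + ["blood_specific"] * config.n_blood_genes
        + ["shared"] * config.n_shared_genes
        + ["unexpressed"] * config.n_unexpressed_genes
    )
    rng.shuffle(classes)
    transcripts: list[TranscriptModel] = []
    pos = config.margin
    for i, cls in enumerate(classes):
        pos += int(rng.integers(*config.intergenic_gap))
        tx, pos = _layout_transcript(rng, config, f"TX{i:04d}", f"G{i:04d}", pos)
        transcripts.append(tx)
    needed = pos + config.margin
    genome_length = config.genome_length or needed
    if genome_length < needed:
        raise ValueError(f"genes need {needed} bp but genome_length={genome_length}")

    expression = _draw_expression(rng, config, classes)
    expression.index = pd.Index([tx.transcript_id for tx in transcripts], name="transcript_id")

    regions = derive_ndr_regions(transcripts, config.window_spec,
                                 {config.chrom: genome_length})

    # accessibility jitter on dip depth: a per-gene component shared by the
    # promoter and junction NDRs plus a smaller per-NDR component, so the
    # two NDRs of a gene correlate strongly but not perfectly
    gene_jitter = np.exp(rng.normal(0.0, config.dip_jitter_sd, size=len(transcripts)))
    targets = {}
    for tx, jit in zip(transcripts, gene_jitter):
        for which in ("promoter", "junction"):
            fid = f"{tx.transcript_id}:{which}"
            ndr_jit = jit * np.exp(rng.normal(0.0, config.dip_ndr_jitter_sd))
            row = {}
            for tissue in config.tissues:
                fpkm = expression.loc[tx.transcript_id, f"fpkm_{tissue}"]
                base = config.dip_target(fpkm)
                row[tissue] = float(np.clip(1.0 - (1.0 - base) * ndr_jit, 0.1, 1.0))
            targets[fid] = row
    ndr_targets = pd.DataFrame(targets).T
    ndr_targets.index.name = "feature_id"

    gene_classes = pd.Series(classes, index=expression.index, name="gene_class")
    informative = [
        f"{tid}:{which}"
        for tid, cls in gene_classes.items()
        if cls in ("tumor_specific", "tumor2_specific", "blood_specific")
        for which in ("promoter", "junction")
    ]
    truth = GroundTruth(gene_classes, informative, ndr_targets)
    return SimReference(config, transcripts, expression, truth, genome_length, regions)


def tissue_intensity(
    reference: SimReference, tissue: str, effect: float | Mapping[str, float] = 1.0
) -> np.ndarray:
    """Per-bp fragment-midpoint intensity for one tissue.

    Baseline 1 everywhere; inside the NDR windows of genes expressed in the
    tissue the intensity equals the (effect-scaled) dip target; phased-
    nucleosome oscillation is superimposed on the +/-2 kb flanks with an
    amplitude proportional to the dip depth.  ``effect`` scales the dip
    depth either globally (scalar, e.g. a tumor-patient effect) or per NDR
    (mapping feature_id -> multiplier, e.g. region-specific donor
    variability).
    """
    config = reference.config
    if tissue not in config.tissues:
        raise ValueError(f"tissue {tissue!r} not in reference tissues {config.tissues}")
    scalar_effect = np.isscalar(effect) or isinstance(effect, float)
    g = np.ones(reference.genome_length, dtype=np.float64)
    spec = config.window_spec
    lo_off, hi_off = spec.span_offsets
    sh = config.dip_shoulder
    G = reference.genome_length

    by_tx: dict[str, list] = {}
    for region in reference.regions:
        by_tx.setdefault(region.transcript_id, []).append(region)

    def footprint(region) -> tuple[int, int, np.ndarray]:
        """Dip weight: 1 inside the core window, raised-cosine shoulders."""
        ws, we = region.ndr_window
        flo, fhi = max(ws - sh, 0), min(we + sh, G)
        pos = np.arange(flo, fhi)
        w = np.ones(fhi - flo)
        if sh > 0:
            left = pos < ws
            right = pos >= we
            w[left] = 0.5 * (1.0 + np.cos(np.pi * (ws - pos[left]) / sh))
            w[right] = 0.5 * (1.0 + np.cos(np.pi * (pos[right] - we + 1) / sh))
        return flo, fhi, w

    for regions in by_tx.values():
        depth_fracs = []
        for region in regions:
            target = reference.truth.ndr_targets.at[region.feature_id, tissue]
            eff = effect if scalar_effect else float(effect.get(region.feature_id, 1.0))
            depth_fracs.append(float(min(max(eff * (1.0 - target), 0.0), 0.95)))
        if not any(df > 0 for df in depth_fracs):
            continue
        prints = [footprint(r) for r in regions]
        # combined dip weight of the gene, for suppressing oscillation
        lo = min(p[0] for p in prints)
        hi = max(p[1] for p in prints)
        combined = np.zeros(hi - lo)
        for flo, fhi, w in prints:
            np.maximum(combined[flo - lo:fhi - lo], w, out=combined[flo - lo:fhi - lo])
        if config.phase_amplitude > 0:
            for region, df in zip(regions, depth_fracs):
                if df <= 0:
                    continue
                if region.strand == "+":
                    glo, ghi = region.anchor + lo_off, region.anchor + hi_off
                else:
                    glo, ghi = region.anchor - hi_off, region.anchor - lo_off
                glo, ghi = max(glo, 0), min(ghi, G)
                span = np.arange(glo, ghi)
                osc = config.phase_amplitude * df * np.cos(
                    2.0 * np.pi * (span - region.anchor) / config.phase_period
                )
                # phased nucleosomes live outside the gene's depleted footprints
                inside = (span >= lo) & (span < hi)
                osc[inside] *= 1.0 - combined[span[inside] - lo]
                g[glo:ghi] *= 1.0 + osc
        for (flo, fhi, w), df in zip(prints, depth_fracs):
            if df > 0:
                g[flo:fhi] *= 1.0 - df * w
    return g


def _sample_lengths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Mono/di-nucleosomal length mixture.

    The mono-nucleosomal component is Laplace-peaked: real cfDNA length
    histograms drop off sharply around the ~166 bp protection mode, and a
    rounded Gaussian of comparable width would leave the integer mode
    ambiguous between neighboring bins.
    """
    is_di = rng.random(n) < config.di_fraction
    if config.length_sd > 0:
        mono = rng.laplace(config.length_mode, config.length_sd / np.sqrt(2.0), size=n)
    else:
        mono = np.full(n, float(config.length_mode))
    di = rng.normal(config.di_mode, config.di_sd, size=n)
    lengths = np.where(is_di, di, mono)
    return np.maximum(np.rint(lengths).astype(np.int64), config.min_length)


def simulate_sample(
    reference: SimReference,
    tissue_fractions: Mapping[str, float],
    depth: float,
    seed: int | None = None,
    sample_id: str = "sample",
    tissue_effects: Mapping[str, float] | None = None,
) -> tuple[FragmentSet, dict]:
    """One cfDNA sample as a seeded tissue mixture.

    Fragment midpoints follow the per-tissue intensity, lengths the
    mono/di-nucleosomal mixture; per-tissue counts are multinomial around
    the requested fractions; fragments carry tissue provenance (blood ->
    healthy_source, tumor tissues -> tumor_source).  ``tissue_effects``
    scales each tissue's dip depth (patient/donor random effects).
    """
    config = reference.config
    fracs = dict(tissue_fractions)
    for tissue in fracs:
        if tissue not in config.tissues:
            raise ValueError(f"tissue {tissue!r} absent from reference")
    total = sum(fracs.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"tissue fractions must sum to 1 (got {total})")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    tissues = [t for t in config.tissues if fracs.get(t, 0.0) > 0]
    probs = np.array([fracs[t] for t in tissues], dtype=float)
    probs = probs / probs.sum()
    n_total = int(round(depth * reference.genome_length / config.mean_fragment_length))
    counts = rng.multinomial(n_total, probs)
    effects = dict(tissue_effects or {})
    parts: list[FragmentSet] = []
    realized = {}
    for tissue, count in zip(tissues, counts):
        realized[tissue] = int(count)
        if count == 0:
            continue
        intensity = tissue_intensity(reference, tissue, effects.get(tissue, 1.0))
        cum = np.cumsum(intensity)
        u = rng.random(count) * cum[-1]
        mids = np.searchsorted(cum, u)
        lengths = _sample_lengths(rng, config, count)
        starts = np.clip(mids - lengths // 2, 0, reference.genome_length - lengths)
        ends = starts + lengths
        code = _PROV_CODES[HEALTHY_SOURCE if tissue == "blood" else TUMOR_SOURCE]
        parts.append(
            FragmentSet(
                sample_id,
                np.full(count, config.chrom, dtype=object),
                starts.astype(np.int64),
                ends.astype(np.int64),
                np.full(count, code, dtype=np.uint8),
            )
        )
    fragments = FragmentSet.concat(parts, sample_id)
    entry = {
        "sample_id": sample_id,
        "tissue_fractions": fracs,
        "depth": depth,
        "seed": seed,
        "realized_counts": realized,
        "tissue_effects": effects,
        "tumor_fraction": sum(v for t, v in fracs.items() if t != "blood"),
    }
    return fragments, entry


def fragment_length_mode(config: SimConfig = SimConfig(), n: int = 100_000,
                         seed: int | None = None) -> int:
    """Histogram mode of n sampled fragment lengths (n >= 10,000)."""
    if n < 10_000:
        raise ValueError("need n >= 10,000 for a stable mode")
    rng = np.random.default_rng(seed)
    lengths = _sample_lengths(rng, config, n)
    return int(np.bincount(lengths).argmax())


# ---------------------------------------------------------------------------
# serialization of the synthetic reference
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Annotation as GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            lo, hi = tx.span()
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            fh.write(
                f"{tx.chrom}\tndrquant_sim\ttranscript\t{lo + 1}\t{hi}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for s, e in sorted(tx.exons):
                fh.write(
                    f"{tx.chrom}\tndrquant_sim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_bed12(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Annotation as BED12 (name = transcript_id, blocks = exons)."""
    rows = []
    for tx in transcripts:
        lo, hi = tx.span()
        exons = sorted(tx.exons)
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        offs = ",".join(str(s - lo) for s, _ in exons) + ","
        rows.append((tx.chrom, lo, hi, tx.transcript_id, 0, tx.strand,
                     lo, hi, "0,0,0", len(exons), sizes, offs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_expression_tsv(expression: pd.DataFrame, path: str) -> None:
    expression.to_csv(path, sep="\t", index_label="transcript_id")
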