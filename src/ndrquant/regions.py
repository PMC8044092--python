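"""Strand-aware nucleosome-depleted-region (NDR) windows from transcript models.

Two NDR classes carry the degradation signal used throughout the package:

* the promoter NDR, -150 to +50 bp relative to the transcription start site
  (TSS), and
* the first exon-intron junction NDR, -300 to -100 bp relative to the 3'
  boundary of the first exon,

both measured in transcript orientation and normalized against +/-1-2 kb
flanks.  A scan over higher-order junctions (k-th exon-intron, k-th
intron-exon, gene end) with identical window geometry supports the
region-class correlation analysis.

Coordinates are 0-based half-open internally; GTF input is converted at the
I/O edge (pyranges does this), BED is written as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with exons ordered 5'->3' in transcript orientation.

    Exons are genomic half-open ``(start, end)`` intervals.  On the minus
    strand exon 1 is the genomically rightmost exon; ``tss`` and
    ``first_exon_end`` are genomic boundary coordinates (the position where
    transcription starts, and the transcript-orientation 3' boundary of
    exon 1).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon interval ({s}, {e})")
        # transcript-orientation ordering: ascending on +, descending on -
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError("exons must be ordered 5'->3' in transcript orientation")

    @property
    def tss(self) -> int:
        s, e = self.exons[0]
        return s if self.strand == "+" else e

    @property
    def first_exon_end(self) -> int:
        """Transcript-orientation 3' boundary of exon 1 (genomic coordinate)."""
        s, e = self.exons[0]
        return e if self.strand == "+" else s

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def gene_end(self) -> int:
        """Transcript-orientation 3' terminus of the transcript."""
        s, e = self.exons[-1]
        return e if self.strand == "+" else s

    def span(self) -> Interval:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and the per-position relative-coverage cap.

    Offsets are transcript-orientation bp relative to the anchor (TSS for
    promoters, first-exon end for junctions); ``cap`` truncates per-position
    relative coverage (values > cap are set to cap) before averaging.
    """

    promoter_offsets: Interval = (-150, 50)
    junction_offsets: Interval = (-300, -100)
    flank_offsets: tuple[Interval, Interval] = ((-2000, -1000), (1000, 2000))
    cap: float = 2.0

    def __post_init__(self) -> None:
        for s, e in (self.promoter_offsets, self.junction_offsets, *self.flank_offsets):
            if s >= e:
                raise ValueError("offset intervals must satisfy start < end")
        if self.cap <= 0:
            raise ValueError("cap must be positive")

    @property
    def span_offsets(self) -> Interval:
        """Smallest offset interval containing the NDR windows and both flanks."""
        lo = min(self.promoter_offsets[0], self.junction_offsets[0], self.flank_offsets[0][0])
        hi = max(self.promoter_offsets[1], self.junction_offsets[1], self.flank_offsets[1][1])
        return lo, hi


@dataclass(frozen=True)
class NDRRegion:
    """One scored genomic window (promoter or junction) with its flanks."""

    feature_id: str
    transcript_id: str
    chrom: str
    region_class: str
    ndr_window: Interval
    upstream_flank: Interval
    downstream_flank: Interval
    anchor: int
    strand: str

    @property
    def width(self) -> int:
        return self.ndr_window[1] - self.ndr_window[0]

    def ndr_offsets(self) -> Interval:
        """Recover the transcript-orientation NDR offsets from the anchor."""
        s, e = self.ndr_window
        if self.strand == "+":
            return s - self.anchor, e - self.anchor
        return self.anchor - e, self.anchor - s


def _oriented(anchor: int, offsets: Interval, strand: str) -> Interval:
    """Map a transcript-orientation offset interval onto the genome.

    On the minus strand the interval endpoints are reflected about the
    anchor: [s, e) -> [anchor - e, anchor - s).
    """
    s, e = offsets
    if strand == "+":
        return anchor + s, anchor + e
    return anchor - e, anchor - s


def _make_region(
    tx: TranscriptModel,
    region_class: str,
    anchor: int,
    ndr_offsets: Interval,
    spec: WindowSpec,
    chrom_size: int | None,
) -> NDRRegion | None:
    ndr = _oriented(anchor, ndr_offsets, tx.strand)
    up = _oriented(anchor, spec.flank_offsets[0], tx.strand)
    down = _oriented(anchor, spec.flank_offsets[1], tx.strand)
    lo = min(ndr[0], up[0], down[0])
    hi = max(ndr[1], up[1], down[1])
    if lo < 0 or (chrom_size is not None and hi > chrom_size):
        return None
    return NDRRegion(
        feature_id=f"{tx.transcript_id}:{region_class}",
        transcript_id=tx.transcript_id,
        chrom=tx.chrom,
        region_class=region_class,
        ndr_window=ndr,
        upstream_flank=up,
        downstream_flank=down,
        anchor=anchor,
        strand=tx.strand,
    )


def derive_ndr_regions(
    annotation: Iterable[TranscriptModel],
    spec: WindowSpec = WindowSpec(),
    chrom_sizes: dict[str, int] | None = None,
) -> list[NDRRegion]:
    """Promoter and first exon-intron junction NDRs for each transcript.

    Single-exon transcripts contribute no junction region (logged).  Regions
    whose window or flanks run past the chromosome bounds are dropped and
    counted in a log message.
    """
    regions: list[NDRRegion] = []
    dropped = 0
    single_exon = 0
    for tx in annotation:
        size = chrom_sizes.get(tx.chrom) if chrom_sizes else None
        prom = _make_region(tx, "promoter", tx.tss, spec.promoter_offsets, spec, size)
        if prom is None:
            dropped += 1
        else:
            regions.append(prom)
        if tx.n_exons < 2:
            single_exon += 1
            continue
        junc = _make_region(tx, "junction", tx.first_exon_end, spec.junction_offsets, spec, size)
        if junc is None:
            dropped += 1
        else:
            regions.append(junc)
    if single_exon:
        logger.warning("%d single-exon transcripts contribute no junction NDR", single_exon)
    if dropped:
        logger.warning("%d NDR regions dropped (window or flank outside chromosome bounds)", dropped)
    return regions


def derive_ordered_junctions(
    annotation: Iterable[TranscriptModel],
    spec: WindowSpec = WindowSpec(),
    max_k: int = 3,
    chrom_sizes: dict[str, int] | None = None,
) -> list[NDRRegion]:
    """Windows for the region-class scan: k-th junctions and gene ends.

    Emits ``junction_k`` (3' boundary of exon k), ``intron_exon_k`` (5'
    boundary of exon k+1) for k = 1..max_k, and ``gene_end``, all with the
    first-junction offset geometry.  Transcripts with fewer than k+1 exons
    contribute no k-th junction.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    regions: list[NDRRegion] = []
    dropped = 0
    for tx in annotation:
        size = chrom_sizes.get(tx.chrom) if chrom_sizes else None
        for k in range(1, min(max_k, tx.n_exons - 1) + 1):
            es, ee = tx.exons[k - 1]
            donor = ee if tx.strand == "+" else es  # 3' boundary of exon k
            ns, ne = tx.exons[k]
            acceptor = ns if tx.strand == "+" else ne  # 5' boundary of exon k+1
            for cls, anchor in ((f"junction_{k}", donor), (f"intron_exon_{k}", acceptor)):
                reg = _make_region(tx, cls, anchor, spec.junction_offsets, spec, size)
                if reg is None:
                    dropped += 1
                else:
                    regions.append(reg)
        reg = _make_region(tx, "gene_end", tx.gene_end, spec.junction_offsets, spec, size)
        if reg is None:
            dropped += 1
        else:
            regions.append(reg)
    if dropped:
        logger.warning("%d scan regions dropped (outside chromosome bounds)", dropped)
    return regions


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse transcript models from a GTF with transcript_id/gene_id attributes."""
    import pyranges

    df = pyranges.read_gtf(path).df
    exons = df[df["Feature"] == "exon"]
    models: list[TranscriptModel] = []
    for tid, grp in exons.groupby("transcript_id", sort=True):
        strand = grp["Strand"].iloc[0]
        ivals = sorted(zip(grp["Start"], grp["End"]), reverse=(strand == "-"))
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                chrom=str(grp["Chromosome"].iloc[0]),
                strand=strand,
                exons=tuple((int(s), int(e)) for s, e in ivals),
            )
        )
    return models


def read_bed12(path: str) -> list[TranscriptModel]:
    """Parse transcript models from BED12 (name column = transcript_id)."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    models = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(row.start + o, row.start + o + s) for o, s in zip(offs, sizes)]
        if row.strand == "-":
            exons = exons[::-1]
        models.append(
            TranscriptModel(
                transcript_id=str(row.name),
                gene_id=str(row.name).split(".")[0],
                chrom=str(row.chrom),
                strand=str(row.strand),
                exons=tuple(exons),
            )
        )
    return models


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def regions_to_frame(regions: Sequence[NDRRegion]) -> pd.DataFrame:
    """Tabular view: BED6 columns for the NDR window plus flank columns."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.ndr_window[0] for r in regions],
            "end": [r.ndr_window[1] for r in regions],
            "feature_id": [r.feature_id for r in regions],
            "score": 0,
            "strand": [r.strand for r in regions],
            "transcript_id": [r.transcript_id for r in regions],
            "region_class": [r.region_class for r in regions],
            "anchor": [r.anchor for r in regions],
            "up_start": [r.upstream_flank[0] for r in regions],
            "up_end": [r.upstream_flank[1] for r in regions],
            "down_start": [r.downstream_flank[0] for r in regions],
            "down_end": [r.downstream_flank[1] for r in regions],
        }
    )


def write_regions(regions: Sequence[NDRRegion], bed_path: str, flank_tsv_path: str | None = None) -> None:
    """Write NDR windows as 6-column BED; flanks go to a companion TSV."""
    df = regions_to_frame(regions)
    df[["chrom", "start", "end", "feature_id", "score", "strand"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    if flank_tsv_path is not None:
        df.drop(columns=["score"]).to_csv(flank_tsv_path, sep="\t", index=False)


def read_regions(bed_path: str, flank_tsv_path: str) -> list[NDRRegion]:
    """Re-read regions written by :func:`write_regions` (round-trip safe)."""
    df = pd.read_csv(flank_tsv_path, sep="\t")
    return [
        NDRRegion(
            feature_id=str(r.feature_id),
            transcript_id=str(r.transcript_id),
            chrom=str(r.chrom),
            region_class=str(r.region_class),
            ndr_window=(int(r.start), int(r.end)),
            upstream_flank=(int(r.up_start), int(r.up_end)),
            downstream_flank=(int(r.down_start), int(r.down_end)),
            anchor=int(r.anchor),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
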