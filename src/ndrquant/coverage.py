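"""Fragment sets, per-position depth, and flank-normalized relative coverage.

The chain here is: trim fragments/reads to their central 61 bp (amplifying
the nucleosome-protection signal), count per-position depth across each NDR
span, divide by the mean depth of the +/-1-2 kb flanks ("relative
coverage"), truncate per-position values above the cap, and average over the
NDR window.  A feature matrix stacks these per-NDR means across samples.

A flank mean of zero yields a *missing* value, never 0 or infinity; the
missingness propagates into the feature matrix as NaN plus a report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import NDRRegion, WindowSpec

TUMOR_SOURCE = "tumor_source"
HEALTHY_SOURCE = "healthy_source"
UNKNOWN_SOURCE = "unknown"
_PROV_CODES = {TUMOR_SOURCE: 0, HEALTHY_SOURCE: 1, UNKNOWN_SOURCE: 2}
_PROV_NAMES = {v: k for k, v in _PROV_CODES.items()}


@dataclass
class FragmentSet:
    """A sample's cfDNA fragments as parallel numpy arrays.

    ``provenance`` stores small integer codes (see :data:`_PROV_CODES`);
    provenance labels support dilution bookkeeping (realized tumor-tissue
    fraction of an in silico mixture).
    """

    sample_id: str
    chroms: np.ndarray  # object/str array, one per record
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    provenance: np.ndarray  # uint8 codes

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.chroms) == len(self.provenance) == n):
            raise ValueError("parallel arrays must have equal length")
        if n and np.any(self.starts >= self.ends):
            raise ValueError("fragments must satisfy start < end")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        records: Iterable[tuple[str, int, int] | tuple[str, int, int, str]],
    ) -> "FragmentSet":
        recs = list(records)
        chroms = np.array([r[0] for r in recs], dtype=object)
        starts = np.array([r[1] for r in recs], dtype=np.int64)
        ends = np.array([r[2] for r in recs], dtype=np.int64)
        prov = np.array(
            [_PROV_CODES[r[3]] if len(r) > 3 else _PROV_CODES[UNKNOWN_SOURCE] for r in recs],
            dtype=np.uint8,
        )
        return cls(sample_id, chroms, starts, ends, prov)

    def provenance_labels(self) -> np.ndarray:
        return np.array([_PROV_NAMES[int(c)] for c in self.provenance], dtype=object)

    def tumor_source_fraction(self) -> float:
        """Fraction of records labeled as tumor-derived (dilution bookkeeping)."""
        if len(self) == 0:
            return float("nan")
        return float(np.mean(self.provenance == _PROV_CODES[TUMOR_SOURCE]))

    def mean_depth(self, genome_length: int) -> float:
        """Haploid-equivalent x-fold coverage over a genome of given length."""
        return float(np.sum(self.ends - self.starts) / genome_length)

    def subset(self, idx: np.ndarray, sample_id: str | None = None) -> "FragmentSet":
        return FragmentSet(
            sample_id if sample_id is not None else self.sample_id,
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            self.provenance[idx],
        )

    def sorted_copy(self) -> "FragmentSet":
        """Canonical ordering (chrom, start, end) for determinism checks."""
        order = np.lexsort((self.ends, self.starts, self.chroms.astype(str)))
        return self.subset(order)

    @classmethod
    def concat(cls, sets: Sequence["FragmentSet"], sample_id: str) -> "FragmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(
            sample_id,
            np.concatenate([s.chroms for s in sets]),
            np.concatenate([s.starts for s in sets]),
            np.concatenate([s.ends for s in sets]),
            np.concatenate([s.provenance for s in sets]),
        )


def read_fragment_bed(path: str, sample_id: str | None = None) -> FragmentSet:
    """BED3+ fragment intervals; optional 4th column = provenance label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if sample_id is None:
        sample_id = str(path)
    if df.shape[1] >= 4 and df[3].astype(str).isin(_PROV_CODES).all():
        prov = df[3].astype(str).map(_PROV_CODES).to_numpy(dtype=np.uint8)
    else:
        prov = np.full(len(df), _PROV_CODES[UNKNOWN_SOURCE], dtype=np.uint8)
    return FragmentSet(
        sample_id,
        df[0].astype(str).to_numpy(dtype=object),
        df[1].to_numpy(dtype=np.int64),
        df[2].to_numpy(dtype=np.int64),
        prov,
    )


def write_fragment_bed(fragments: FragmentSet, path: str) -> None:
    labels = fragments.provenance_labels()
    pd.DataFrame(
        {"chrom": fragments.chroms, "start": fragments.starts, "end": fragments.ends, "name": labels}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bam(path: str, sample_id: str | None = None, min_mapq: int = 0,
             exclude_duplicates: bool = True) -> FragmentSet:
    """Each aligned read (mate) becomes one record; duplicates excluded.

    Reads flagged unmapped/secondary/supplementary are skipped.  In BAM mode
    both mates are counted independently, matching read-level trimming.
    """
    import pysam

    chroms, starts, ends = [], [], []
    with pysam.AlignmentFile(path) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_end)
    n = len(starts)
    return FragmentSet(
        sample_id or str(path),
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.full(n, _PROV_CODES[UNKNOWN_SOURCE], dtype=np.uint8),
    )


def trim_reads(fragments: FragmentSet, keep: int = 61) -> FragmentSet:
    """Keep the central ``keep`` bp of each record (floor-centered).

    Records shorter than ``keep`` are kept whole; the record count is
    conserved.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    lengths = fragments.ends - fragments.starts
    shift = np.maximum(lengths - keep, 0) // 2
    starts = fragments.starts + shift
    ends = starts + np.minimum(lengths, keep)
    return FragmentSet(fragments.sample_id, fragments.chroms, starts, ends, fragments.provenance)


# ---------------------------------------------------------------------------
# depth and relative coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-position depth over anchor-relative offsets (transcript orientation)."""

    region_ref: str
    positions: np.ndarray  # offsets, e.g. -2000..1999
    depth: np.ndarray  # int64, same length


@dataclass
class RelativeCoverageProfile:
    """Depth divided by the flank mean, truncated at the cap; missing if flank mean is 0."""

    region_ref: str
    positions: np.ndarray
    relcov: np.ndarray | None  # None when missing
    flank_mean: float

    @property
    def missing(self) -> bool:
        return self.relcov is None


def _span_depth(fragments: FragmentSet, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Genomic depth over [lo, hi) via a clipped difference array."""
    mask = fragments.chroms == chrom
    starts = np.clip(fragments.starts[mask], lo, hi) - lo
    ends = np.clip(fragments.ends[mask], lo, hi) - lo
    keep = ends > starts
    n = hi - lo
    diff = np.bincount(starts[keep], minlength=n + 1) - np.bincount(ends[keep], minlength=n + 1)
    return np.cumsum(diff[:n]).astype(np.int64)


def _orient(depth_genomic: np.ndarray, strand: str) -> np.ndarray:
    """Genomic depth over [anchor+lo, anchor+hi) -> transcript-orientation offsets.

    On the minus strand offset o maps to genomic position anchor - o - 1, so
    the oriented profile is the reversed genomic slice.
    """
    return depth_genomic if strand == "+" else depth_genomic[::-1]


def region_depth(fragments: FragmentSet, region: NDRRegion,
                 spec: WindowSpec = WindowSpec()) -> CoverageProfile:
    """Per-position overlap counts over the full span (NDR plus flanks)."""
    lo_off, hi_off = spec.span_offsets
    positions = np.arange(lo_off, hi_off)
    if region.strand == "+":
        glo, ghi = region.anchor + lo_off, region.anchor + hi_off
    else:
        glo, ghi = region.anchor - hi_off, region.anchor - lo_off
    depth = _orient(_span_depth(fragments, region.chrom, glo, ghi), region.strand)
    return CoverageProfile(region.feature_id, positions, depth)


def _offset_slice(positions: np.ndarray, interval: tuple[int, int]) -> slice:
    lo = int(interval[0] - positions[0])
    hi = int(interval[1] - positions[0])
    return slice(lo, hi)


def relative_profile(profile: CoverageProfile, region: NDRRegion,
                     spec: WindowSpec = WindowSpec()) -> RelativeCoverageProfile:
    """Normalize depth by the mean over the union of the two 1 kb flanks.

    Per-position values above ``spec.cap`` are truncated.  A zero flank mean
    flags the profile as missing.
    """
    flank = np.concatenate(
        [profile.depth[_offset_slice(profile.positions, f)] for f in spec.flank_offsets]
    )
    factor = float(flank.mean()) if len(flank) else 0.0
    if factor == 0.0:
        return RelativeCoverageProfile(profile.region_ref, profile.positions, None, 0.0)
    relcov = np.minimum(profile.depth / factor, spec.cap)
    return RelativeCoverageProfile(profile.region_ref, profile.positions, relcov, factor)


def ndr_mean_relcov(relprofile: RelativeCoverageProfile, region: NDRRegion) -> float:
    """Mean truncated relative coverage over the NDR window (NaN if missing)."""
    if relprofile.missing:
        return float("nan")
    window = relprofile.relcov[_offset_slice(relprofile.positions, region.ndr_offsets())]
    return float(window.mean())


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples x NDR features of mean relative coverage, plus optional response.

    ``values`` is a DataFrame (rows = sample_ids, columns = feature_ids;
    NaN = missing).  ``response`` holds the known/expected ctDNA fraction
    per sample when available.
    """

    values: pd.DataFrame
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample_id in feature matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature_id in feature matrix")
        if self.response is not None:
            self.response = self.response.reindex(self.values.index)
            resp = self.response.dropna()
            if ((resp < 0) | (resp > 1)).any():
                raise ValueError("response must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def missingness_report(self) -> pd.Series:
        """Per-feature count of missing cells."""
        return self.values.isna().sum()

    def restrict(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(feature_ids)].copy(), self.response)

    def to_tsv(self, path: str) -> None:
        out = self.values.copy()
        if self.response is not None:
            out.insert(0, "expected_fraction", self.response)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        response = None
        if "expected_fraction" in df.columns:
            response = df.pop("expected_fraction")
        return cls(df, response)


def sample_features(
    fragments: FragmentSet,
    regions: Sequence[NDRRegion],
    spec: WindowSpec = WindowSpec(),
    trim: int | None = 61,
) -> pd.Series:
    """Mean NDR relative coverage for one sample over many regions.

    Computes one whole-chromosome depth array per chromosome and slices each
    region out of it, which is equivalent to per-region :func:`region_depth`
    but far cheaper for hundreds of regions.
    """
    frs = trim_reads(fragments, trim) if trim else fragments
    lo_off, hi_off = spec.span_offsets
    out = pd.Series(np.nan, index=[r.feature_id for r in regions], dtype=float)
    by_chrom: dict[str, list[NDRRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, regs in by_chrom.items():
        mask = frs.chroms == chrom
        if not mask.any():
            continue
        starts, ends = frs.starts[mask], frs.ends[mask]
        lo = min((r.anchor - hi_off if r.strand == "-" else r.anchor + lo_off) for r in regs)
        lo = max(0, lo)
        hi = max((r.anchor - lo_off if r.strand == "-" else r.anchor + hi_off) for r in regs)
        n = hi - lo
        cs = np.clip(starts, lo, hi) - lo
        ce = np.clip(ends, lo, hi) - lo
        diff = np.bincount(cs, minlength=n + 1).astype(np.int64)
        diff -= np.bincount(ce, minlength=n + 1)
        depth_chrom = np.cumsum(diff[:n])
        for r in regs:
            if r.strand == "+":
                glo, ghi = r.anchor + lo_off, r.anchor + hi_off
            else:
                glo, ghi = r.anchor - hi_off, r.anchor - lo_off
            if glo < lo or ghi > hi:
                continue
            d = _orient(depth_chrom[glo - lo:ghi - lo], r.strand)
            prof = CoverageProfile(r.feature_id, np.arange(lo_off, hi_off), d)
            rel = relative_profile(prof, r, spec)
            out[r.feature_id] = ndr_mean_relcov(rel, r)
    return out


def build_feature_matrix(
    samples: Sequence[FragmentSet],
    regions: Sequence[NDRRegion],
    spec: WindowSpec = WindowSpec(),
    response: Mapping[str, float] | None = None,
    trim: int | None = 61,
) -> FeatureMatrix:
    """Stack per-sample NDR means into a samples x features matrix.

    Duplicate sample ids raise; missing cells (zero flank coverage) stay NaN
    and are summarized by :meth:`FeatureMatrix.missingness_report`.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among samples")
    rows = {s.sample_id: sample_features(s, regions, spec, trim=trim) for s in samples}
    values = pd.DataFrame(rows).T.reindex(index=ids, columns=[r.feature_id for r in regions])
    resp = None
    if response is not None:
        resp = pd.Series({sid: response[sid] for sid in ids}, dtype=float)
    return FeatureMatrix(values, resp)
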