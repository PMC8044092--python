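import numpy as np
import pandas as pd
import pytest

from ndrquant.coverage import (
    CoverageProfile,
    FeatureMatrix,
    FragmentSet,
    build_feature_matrix,
    ndr_mean_relcov,
    read_bam,
    read_fragment_bed,
    region_depth,
    relative_profile,
    sample_features,
    trim_reads,
    write_fragment_bed,
)
from ndrquant.regions import NDRRegion, TranscriptModel, WindowSpec, derive_ndr_regions

from _oracles import chain_mean_relcov, depth_by_position

SPEC = WindowSpec()


def region_at(anchor=20_000, strand="+", region_class="promoter", chrom="chr1"):
    offsets = SPEC.promoter_offsets if region_class == "promoter" else SPEC.junction_offsets
    tx = TranscriptModel(
        "tx", "g", chrom, strand,
        exons=((anchor, anchor + 1000), (anchor + 1500, anchor + 1800))
        if strand == "+"
        else ((anchor - 1000, anchor), (anchor - 1800, anchor - 1500)),
    )
    regs = {r.region_class: r for r in derive_ndr_regions([tx], SPEC)}
    return regs[region_class]


class TestTrim:
    @pytest.mark.parametrize(
        "record,keep,expected",
        [
            ((100, 251), 61, (145, 206)),  # 151 bp -> central 61
            ((100, 150), 61, (100, 150)),  # shorter than keep: unchanged
            ((100, 161), 61, (100, 161)),  # keep equals length: identity
            ((0, 100), 50, (25, 75)),
            ((0, 101), 50, (25, 75)),  # parity mismatch floor-centers
        ],
    )
    def test_central_trim(self, record, keep, expected):
        fs = FragmentSet.from_records("s", [("chr1", *record)])
        out = trim_reads(fs, keep)
        assert (out.starts[0], out.ends[0]) == expected

    def test_record_count_conserved_and_keep_validated(self, random_fragments):
        assert len(trim_reads(random_fragments, 61)) == len(random_fragments)
        with pytest.raises(ValueError):
            trim_reads(random_fragments, 0)

    def test_trimming_never_increases_depth(self, random_fragments):
        region = region_at()
        full = region_depth(random_fragments, region, SPEC).depth
        trimmed = region_depth(trim_reads(random_fragments, 61), region, SPEC).depth
        assert np.all(trimmed <= full)


class TestRegionDepth:
    def test_single_spanning_record(self):
        region = region_at()
        fs = FragmentSet.from_records("s", [("chr1", 15_000, 25_000)])
        prof = region_depth(fs, region, SPEC)
        assert np.all(prof.depth == 1)

    def test_two_identical_records_are_additive(self):
        region = region_at()
        fs = FragmentSet.from_records("s", [("chr1", 15_000, 25_000)] * 2)
        assert np.all(region_depth(fs, region, SPEC).depth == 2)

    def test_matches_bruteforce_overlap_count(self, random_fragments):
        region = region_at()
        prof = region_depth(random_fragments, region, SPEC)
        check = np.arange(0, len(prof.positions), 97)  # spot-check a lattice
        genomic = [
            region.anchor + int(prof.positions[i]) for i in check
        ]
        oracle = depth_by_position(random_fragments, "chr1", genomic)
        assert prof.depth[check].tolist() == oracle

    def test_minus_strand_orientation(self):
        region = region_at(strand="-")
        # one record only on the genomic left of the anchor = transcript downstream
        fs = FragmentSet.from_records("s", [("chr1", region.anchor - 500, region.anchor - 400)])
        prof = region_depth(fs, region, SPEC)
        covered = prof.positions[prof.depth > 0]
        assert covered.min() >= 399 and covered.max() <= 499

    def test_depth_conservation_identity(self, random_fragments):
        region = region_at()
        prof = region_depth(random_fragments, region, SPEC)
        lo = region.anchor + int(prof.positions[0])
        hi = region.anchor + int(prof.positions[-1]) + 1
        overlaps = np.minimum(random_fragments.ends, hi) - np.maximum(random_fragments.starts, lo)
        assert prof.depth.sum() == overlaps[overlaps > 0].sum()


class TestRelativeProfile:
    def _profile(self, depth_fn):
        region = region_at()
        positions = np.arange(*SPEC.span_offsets)
        depth = np.array([depth_fn(p) for p in positions], dtype=np.int64)
        return region, CoverageProfile(region.feature_id, positions, depth)

    def test_uniform_depth_normalizes_to_one(self):
        region, prof = self._profile(lambda p: 10)
        rel = relative_profile(prof, region, SPEC)
        assert np.allclose(rel.relcov, 1.0)
        assert ndr_mean_relcov(rel, region) == pytest.approx(1.0)

    def test_half_depth_window(self):
        ws, we = -150, 50
        region, prof = self._profile(lambda p: 5 if ws <= p < we else 10)
        rel = relative_profile(prof, region, SPEC)
        assert ndr_mean_relcov(rel, region) == pytest.approx(0.5)

    def test_cap_truncates_outliers(self):
        region, prof = self._profile(lambda p: 30 if p == 0 else 10)
        rel = relative_profile(prof, region, SPEC)
        assert rel.relcov.max() == pytest.approx(SPEC.cap)

    def test_zero_flank_marks_missing(self):
        ws, we = -150, 50
        region, prof = self._profile(lambda p: 3 if ws <= p < we else 0)
        rel = relative_profile(prof, region, SPEC)
        assert rel.missing
        assert np.isnan(ndr_mean_relcov(rel, region))

    def test_scale_invariance(self, random_fragments):
        region = region_at()
        rel1 = relative_profile(region_depth(random_fragments, region, SPEC), region, SPEC)
        tripled = FragmentSet.concat([random_fragments] * 3, "x3")
        rel3 = relative_profile(region_depth(tripled, region, SPEC), region, SPEC)
        ok = rel1.relcov < SPEC.cap  # capped positions may differ after scaling
        assert np.allclose(rel1.relcov[ok], rel3.relcov[ok])

    def test_split_mean_over_half_window(self):
        ws, we = -150, 50
        mid = (ws + we) // 2
        region, prof = self._profile(lambda p: (0 if p < mid else 10) if ws <= p < we else 10)
        rel = relative_profile(prof, region, SPEC)
        assert ndr_mean_relcov(rel, region) == pytest.approx(0.5)


class TestChainOracle:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("region_class", ["promoter", "junction"])
    def test_full_chain_equals_nested_loop_oracle(self, strand, region_class):
        rng = np.random.default_rng(7)
        n = 300
        starts = rng.integers(16_000, 24_000, size=n)
        lengths = rng.integers(60, 240, size=n)
        fs = FragmentSet(
            "s",
            np.full(n, "chr1", dtype=object),
            starts.astype(np.int64),
            (starts + lengths).astype(np.int64),
            np.full(n, 2, dtype=np.uint8),
        )
        region = region_at(strand=strand, region_class=region_class)
        fast = sample_features(fs, [region], SPEC, trim=61)[region.feature_id]
        slow = chain_mean_relcov(fs, region, SPEC, keep=61)
        assert fast == pytest.approx(slow, abs=1e-12)


class TestFeatureMatrix:
    def _setup(self):
        regions = [
            region_at(20_000, region_class="promoter"),
            region_at(20_000, region_class="junction"),
            region_at(60_000, strand="-", region_class="promoter"),
        ]
        # distinct feature ids required
        regions = [
            NDRRegion(f"r{i}", r.transcript_id, r.chrom, r.region_class,
                      r.ndr_window, r.upstream_flank, r.downstream_flank,
                      r.anchor, r.strand)
            for i, r in enumerate(regions)
        ]
        rng = np.random.default_rng(3)
        samples = []
        for sid in ("a", "b"):
            starts = rng.integers(15_000, 65_000, size=3000)
            lengths = rng.integers(100, 200, size=3000)
            samples.append(
                FragmentSet(sid, np.full(3000, "chr1", dtype=object),
                            starts.astype(np.int64), (starts + lengths).astype(np.int64),
                            np.full(3000, 2, dtype=np.uint8))
            )
        return regions, samples

    def test_matrix_matches_per_region_chain(self):
        regions, samples = self._setup()
        matrix = build_feature_matrix(samples, regions, SPEC, trim=61)
        assert matrix.values.shape == (2, 3)
        for s in samples:
            row = sample_features(s, regions, SPEC, trim=61)
            assert np.allclose(matrix.values.loc[s.sample_id], row, equal_nan=True)

    def test_region_permutation_permutes_columns_only(self):
        regions, samples = self._setup()
        m1 = build_feature_matrix(samples, regions, SPEC)
        m2 = build_feature_matrix(samples, regions[::-1], SPEC)
        assert list(m2.values.columns) == [r.feature_id for r in regions[::-1]]
        assert m1.values.equals(m2.values[m1.values.columns])

    def test_empty_region_is_missing_cell_only(self):
        regions, samples = self._setup()
        far = NDRRegion("far", "tx", "chr1", "promoter", (499_850, 500_050),
                        (498_000, 499_000), (501_000, 502_000), 500_000, "+")
        matrix = build_feature_matrix(samples, regions + [far], SPEC)
        assert matrix.values["far"].isna().all()
        assert matrix.values[[r.feature_id for r in regions]].notna().all().all()
        assert matrix.missingness_report()["far"] == 2

    def test_duplicate_sample_id_rejected(self):
        regions, samples = self._setup()
        dup = samples[0]
        with pytest.raises(ValueError, match="duplicate sample_id"):
            build_feature_matrix([dup, dup], regions, SPEC)

    def test_response_bounds_checked(self):
        with pytest.raises(ValueError, match="response"):
            FeatureMatrix(
                pd.DataFrame({"f": [1.0]}, index=["s"]),
                pd.Series({"s": 1.5}),
            )


class TestIO:
    def test_fragment_bed_round_trip(self, tmp_path, random_fragments):
        path = tmp_path / "frags.bed"
        write_fragment_bed(random_fragments, str(path))
        back = read_fragment_bed(str(path), sample_id="rand")
        assert np.array_equal(back.starts, random_fragments.starts)
        assert np.array_equal(back.ends, random_fragments.ends)
        assert np.array_equal(back.provenance, random_fragments.provenance)

    def test_bam_reads_match_bed_records(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        sam = tmp_path / "toy.sam"
        header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"
        reads = [
            ("r1", 0, 1000, 60, "100M"),
            ("r2", 0, 1500, 60, "50M"),
            ("r3", 1024, 2000, 60, "100M"),  # duplicate flag
            ("r4", 4, 0, 0, "*"),  # unmapped
        ]
        with open(sam, "w") as fh:
            fh.write(header)
            for name, flag, pos, mapq, cigar in reads:
                seq = "A" * (100 if cigar == "100M" else 50) if cigar != "*" else "*"
                fh.write(
                    f"{name}\t{flag}\t{'chr1' if cigar != '*' else '*'}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
        fs = read_bam(str(sam), sample_id="toy")
        assert len(fs) == 2  # duplicate and unmapped excluded
        assert fs.starts.tolist() == [1000, 1500]
        assert fs.ends.tolist() == [1100, 1550]
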