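"""Independent brute-force oracles used by the test suite.

Everything here is written position-by-position / record-by-record with
plain Python loops, deliberately independent of the vectorized
implementations it checks.
"""

from __future__ import annotations

import numpy as np

from ndrquant.coverage import FragmentSet
from ndrquant.regions import NDRRegion, WindowSpec


def trim_record(start: int, end: int, keep: int) -> tuple[int, int]:
    length = end - start
    if length <= keep:
        return start, end
    off = (length - keep) // 2
    return start + off, start + off + keep


def depth_by_position(fragments: FragmentSet, chrom: str, positions) -> list[int]:
    """O(n_records * n_positions) overlap counting."""
    out = []
    recs = list(zip(fragments.chroms, fragments.starts, fragments.ends))
    for p in positions:
        c = 0
        for rchrom, s, e in recs:
            if rchrom == chrom and s <= p < e:
                c += 1
        out.append(c)
    return out


def chain_mean_relcov(
    fragments: FragmentSet,
    region: NDRRegion,
    spec: WindowSpec,
    keep: int | None = 61,
) -> float:
    """trim -> depth -> flank normalization -> cap -> NDR mean, all by loops."""
    recs = []
    for c, s, e in zip(fragments.chroms, fragments.starts, fragments.ends):
        if keep is not None:
            s, e = trim_record(int(s), int(e), keep)
        recs.append((c, s, e))
    trimmed = FragmentSet.from_records(fragments.sample_id, recs)

    a, strand = region.anchor, region.strand

    def genomic(offset: int) -> int:
        # offset o in transcript orientation -> genomic position
        return a + offset if strand == "+" else a - offset - 1

    lo, hi = spec.span_offsets
    offsets = list(range(lo, hi))
    depth = {o: 0 for o in offsets}
    for o in offsets:
        g = genomic(o)
        for rchrom, s, e in zip(trimmed.chroms, trimmed.starts, trimmed.ends):
            if rchrom == region.chrom and s <= g < e:
                depth[o] += 1

    flank_offsets = [
        o for (fs, fe) in spec.flank_offsets for o in range(fs, fe)
    ]
    flank_mean = sum(depth[o] for o in flank_offsets) / len(flank_offsets)
    if flank_mean == 0:
        return float("nan")
    ws, we = region.ndr_offsets()
    vals = []
    for o in range(ws, we):
        vals.append(min(depth[o] / flank_mean, spec.cap))
    return sum(vals) / len(vals)
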