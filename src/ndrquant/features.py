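"""Shortlisting of tissue-specific candidate NDR features.

Candidate transcripts combine tissue-specific expression with a directional
degradation score at both NDRs:

* tumor candidates: fpkm_tumor > 10, fpkm_blood < 1, score < -0.2 at both
  promoter and junction NDRs (more degraded in cancer plasma);
* blood candidates: fpkm_tumor < 1, fpkm_blood > 10, score > +0.2 at both;
* pan-cancer blood-only candidates: fpkm_blood > 5 and fpkm < 1 in every
  listed tumor type (no score filter by default).

Transcripts sharing an identical NDR window, or with overlapping windows of
the same class, are collapsed to one model feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import NDRRegion

MODE_CRC_TUMOR = "crc_tumor"
MODE_CRC_BLOOD = "crc_blood"
MODE_PAN_BLOOD = "pan_blood"


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for one shortlisting mode.

    ``fpkm_high``/``fpkm_low`` bound the specifically-expressed and the
    lowly-expressed tissue respectively; ``score_cut`` is the magnitude of
    the degradation-score threshold (sign fixed by mode).  For pan_blood the
    score filter is off unless ``require_score`` is set.
    """

    mode: str = MODE_CRC_TUMOR
    fpkm_high: float = 10.0
    fpkm_low: float = 1.0
    score_cut: float = 0.2
    require_both_regions: bool = True
    pan_fpkm_blood: float = 5.0
    require_score: bool | None = None  # default: on except pan_blood

    def __post_init__(self) -> None:
        if self.mode not in (MODE_CRC_TUMOR, MODE_CRC_BLOOD, MODE_PAN_BLOOD):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.fpkm_high > self.fpkm_low >= 0:
            raise ValueError("need fpkm_high > fpkm_low >= 0")

    @property
    def score_required(self) -> bool:
        if self.require_score is None:
            return self.mode != MODE_PAN_BLOOD
        return self.require_score


def shortlist_transcripts(
    expression: pd.DataFrame,
    scores: pd.DataFrame | None,
    config: SelectionConfig,
    blood_col: str = "fpkm_blood",
    tumor_col: str = "fpkm_tumor",
) -> tuple[list[str], pd.DataFrame]:
    """Select candidate transcripts; returns (kept ids, per-transcript report).

    ``expression`` is indexed by transcript_id with per-tissue median fpkm
    columns (all columns starting with ``fpkm_`` other than the blood column
    count as tumor types in pan_blood mode).  ``scores`` is indexed by
    transcript_id with 'promoter' and 'junction' score columns; transcripts
    with a missing required score are rejected and counted in the report.
    """
    report = pd.DataFrame(index=expression.index)
    blood = expression[blood_col]
    if config.mode == MODE_CRC_TUMOR:
        expr_ok = (expression[tumor_col] > config.fpkm_high) & (blood < config.fpkm_low)
    elif config.mode == MODE_CRC_BLOOD:
        expr_ok = (expression[tumor_col] < config.fpkm_low) & (blood > config.fpkm_high)
    else:  # pan_blood
        tumor_cols = [c for c in expression.columns if c.startswith("fpkm_") and c != blood_col]
        expr_ok = blood > config.pan_fpkm_blood
        for c in tumor_cols:
            expr_ok &= expression[c] < config.fpkm_low
    report["expression_ok"] = expr_ok

    if config.score_required:
        if scores is None:
            raise ValueError("this mode requires degradation scores")
        regions = ["promoter", "junction"] if config.require_both_regions else ["promoter"]
        sc = scores.reindex(expression.index)[regions]
        report["score_missing"] = sc.isna().any(axis=1)
        if config.mode == MODE_CRC_BLOOD or config.mode == MODE_PAN_BLOOD:
            score_ok = (sc > config.score_cut).all(axis=1)
        else:
            score_ok = (sc < -config.score_cut).all(axis=1)
        score_ok &= ~report["score_missing"]
        report["score_ok"] = score_ok
        keep = expr_ok & score_ok
    else:
        keep = expr_ok
    report["kept"] = keep
    report["reason"] = np.where(
        keep, "kept",
        np.where(~expr_ok, "expression", np.where(report.get("score_missing", False), "score_missing", "score")),
    )
    return list(expression.index[keep]), report


def dedup_features(
    regions: Sequence[NDRRegion],
    scores: Mapping[str, float] | pd.Series | None = None,
) -> list[NDRRegion]:
    """Collapse shared and overlapping NDR windows to single model features.

    Regions with identical (chrom, ndr_window, region_class) collapse to
    one; within a class, mutually overlapping windows collapse to the region
    whose transcript has the most extreme |score| (ties broken by the
    lexicographically smallest transcript_id).  Without scores, the tie rule
    alone applies.  Idempotent.
    """
    if scores is None:
        score_of = {}
    elif isinstance(scores, pd.Series):
        score_of = scores.to_dict()
    else:
        score_of = dict(scores)

    def sort_key(r: NDRRegion):
        return (r.chrom, r.region_class, r.ndr_window[0], r.ndr_window[1], r.transcript_id)

    def extremeness(r: NDRRegion) -> float:
        v = score_of.get(r.feature_id, score_of.get(r.transcript_id, np.nan))
        return abs(v) if np.isfinite(v) else -np.inf

    kept: list[NDRRegion] = []
    cluster: list[NDRRegion] = []
    cluster_end = -1

    def flush() -> None:
        if not cluster:
            return
        best = max(cluster, key=lambda r: (extremeness(r), _neg_id(r)))
        kept.append(best)

    def _neg_id(r: NDRRegion):
        # ties: lexicographically smallest transcript_id wins under max()
        return tuple(-ord(c) for c in r.transcript_id)

    prev_group = None
    for r in sorted(regions, key=sort_key):
        group = (r.chrom, r.region_class)
        if group != prev_group or r.ndr_window[0] >= cluster_end:
            flush()
            cluster = [r]
            cluster_end = r.ndr_window[1]
            prev_group = group
        else:
            # identical windows or overlap with the running cluster
            if not any(
                c.ndr_window == r.ndr_window and c.transcript_id == r.transcript_id for c in cluster
            ):
                cluster.append(r)
            cluster_end = max(cluster_end, r.ndr_window[1])
    flush()
    kept.sort(key=sort_key)
    return kept


def load_expression_tsv(path: str) -> pd.DataFrame:
    """Expression table: transcript_id index, fpkm_* columns, optional unexpressed flag."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm_")]
    if not fpkm_cols:
        raise ValueError("expression table needs fpkm_* columns")
    if (df[fpkm_cols] < 0).any().any():
        raise ValueError("fpkm values must be >= 0")
    return df
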