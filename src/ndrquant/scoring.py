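"""Differential-degradation scoring and the expression-coverage region scan.

The relative coverage score standardizes the difference in NDR mean relative
coverage between cancer and healthy plasma:

    score = (mean(cancer) - mean(healthy)) / sd(cancer)

with sd(cancer) the sample standard deviation (n-1) over cancer samples.
Tumor-specific NDRs (preferentially degraded in cancer plasma) score
negative; blood-specific NDRs score positive.  When healthy samples are
individually shallow, a single merged-healthy value may stand in for
mean(healthy); a bootstrap over merged healthy subsets provides a healthy-
side variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import FragmentSet, sample_features
from .regions import NDRRegion, WindowSpec


@dataclass
class CoverageScore:
    feature_id: str
    mean_cancer: float
    mean_healthy: float
    sd_cancer: float
    score: float  # NaN when sd_cancer == 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.score)


def relative_coverage_score(
    cancer_values: Sequence[float],
    healthy_values: Sequence[float] | float,
    feature_id: str = "",
) -> CoverageScore:
    """Standardized cancer-vs-healthy difference in NDR mean relative coverage.

    ``healthy_values`` may be per-sample values or a single merged-healthy
    scalar.  Requires >=2 cancer values with no missing entries; a zero
    cancer standard deviation leaves the score undefined (NaN).
    """
    cancer = np.asarray(cancer_values, dtype=float)
    if cancer.size < 2:
        raise ValueError("need >=2 cancer values")
    if np.isnan(cancer).any():
        raise ValueError("missing cancer values")
    if np.isscalar(healthy_values):
        mean_healthy = float(healthy_values)
    else:
        healthy = np.asarray(healthy_values, dtype=float)
        if healthy.size < 1:
            raise ValueError("need >=1 healthy value")
        if np.isnan(healthy).any():
            raise ValueError("missing healthy values")
        mean_healthy = float(healthy.mean())
    mean_cancer = float(cancer.mean())
    sd_cancer = float(cancer.std(ddof=1))
    score = (mean_cancer - mean_healthy) / sd_cancer if sd_cancer > 0 else float("nan")
    return CoverageScore(feature_id, mean_cancer, mean_healthy, sd_cancer, score)


def score_features(
    cancer_matrix: pd.DataFrame,
    healthy: pd.DataFrame | pd.Series,
) -> pd.DataFrame:
    """Vectorized scores for a cancer samples x features matrix.

    ``healthy`` is either a samples x features matrix (per-sample mode) or a
    single merged-healthy feature Series (merged mode).  Returns a DataFrame
    indexed by feature_id with mean_cancer/mean_healthy/sd_cancer/score.
    """
    mean_cancer = cancer_matrix.mean(axis=0)
    sd_cancer = cancer_matrix.std(axis=0, ddof=1)
    if isinstance(healthy, pd.Series):
        mean_healthy = healthy.reindex(cancer_matrix.columns)
    else:
        mean_healthy = healthy.mean(axis=0).reindex(cancer_matrix.columns)
    score = (mean_cancer - mean_healthy) / sd_cancer.where(sd_cancer > 0)
    return pd.DataFrame(
        {
            "mean_cancer": mean_cancer,
            "mean_healthy": mean_healthy,
            "sd_cancer": sd_cancer,
            "score": score,
        }
    )


def bootstrap_healthy_sd(
    healthy_samples: Sequence[FragmentSet],
    regions: Sequence[NDRRegion],
    spec: WindowSpec = WindowSpec(),
    n_subsets: int = 20,
    subset_size: int = 10,
    seed: int | None = None,
    trim: int | None = 61,
) -> pd.Series:
    """Healthy-side sd via merged bootstrap subsets.

    Each subset draws ``subset_size`` healthy samples with replacement,
    merges their fragments, and records the per-NDR mean relative coverage;
    the per-feature sd over the ``n_subsets`` merged values approximates the
    healthy between-sample variance despite shallow individual samples.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if len(healthy_samples) < 2:
        raise ValueError("need >=2 healthy samples")
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_subsets):
        idx = rng.integers(0, len(healthy_samples), size=subset_size)
        merged = FragmentSet.concat([healthy_samples[i] for i in idx], f"boot_{b}")
        rows.append(sample_features(merged, regions, spec, trim=trim))
    mat = pd.DataFrame(rows)
    return mat.std(axis=0, ddof=1)


@dataclass
class RegionScanResult:
    region_class: str
    pearson_r: float
    spearman_rho: float
    n_transcripts: int


EXPRESSION_BINS = (
    ("unexpressed", 0.0, 0.0),
    ("0.01<fpkm<=0.1", 0.01, 0.1),
    ("0.1<fpkm<=1", 0.1, 1.0),
    ("1<fpkm<=5", 1.0, 5.0),
    ("5<fpkm<=30", 5.0, 30.0),
    ("fpkm>30", 30.0, float("inf")),
)


def bin_expression(fpkm: pd.Series, unexpressed: pd.Series | None = None) -> pd.Series:
    """Six-level expression grouping used for binned scan summaries."""
    out = pd.Series("", index=fpkm.index, dtype=object)
    for name, lo, hi in EXPRESSION_BINS[1:]:
        out[(fpkm > lo) & (fpkm <= hi)] = name
    if unexpressed is not None:
        out[unexpressed.astype(bool)] = "unexpressed"
    else:
        out[fpkm <= 0.01] = "unexpressed"
    return out


def expression_coverage_scan(
    relcov_by_class: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series,
    expressed_cut: float = 30.0,
    max_per_bin: int | None = None,
    seed: int | None = None,
) -> tuple[list[RegionScanResult], dict]:
    """Correlation between expression and NDR relative coverage per region class.

    ``relcov_by_class`` is transcripts x region_class mean relative coverage.
    Correlations use log10(fpkm + 0.1).  Also reports the promoter-vs-
    junction cross-feature correlation within the expressed
    (fpkm >= expressed_cut) and unexpressed groups, and pooled over both.
    Classes with zero variance in either variable return NaN correlations.
    ``max_per_bin`` randomly (seeded) subsamples each expression bin to at
    most that many transcripts, useful when bins are very unbalanced.
    """
    expr = pd.Series(expression, dtype=float).reindex(relcov_by_class.index)
    if max_per_bin is not None:
        rng = np.random.default_rng(seed)
        keep: list = []
        for _, members in expr.groupby(bin_expression(expr)):
            ids = list(members.index)
            if len(ids) > max_per_bin:
                ids = list(rng.choice(ids, size=max_per_bin, replace=False))
            keep.extend(ids)
        relcov_by_class = relcov_by_class.loc[keep]
        expr = expr.loc[keep]
    x = np.log10(expr + 0.1)
    results: list[RegionScanResult] = []
    for cls in relcov_by_class.columns:
        y = relcov_by_class[cls]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 10:
            raise ValueError(f"region class {cls!r} has <10 transcripts")
        if x[ok].std() == 0 or y[ok].std() == 0:
            results.append(RegionScanResult(cls, float("nan"), float("nan"), n))
            continue
        r = stats.pearsonr(x[ok], y[ok]).statistic
        rho = stats.spearmanr(x[ok], y[ok]).statistic
        results.append(RegionScanResult(cls, float(r), float(rho), n))
    cross: dict = {}
    prom_col = "promoter" if "promoter" in relcov_by_class.columns else None
    junc_col = next((c for c in ("junction", "junction_1") if c in relcov_by_class.columns), None)
    if prom_col and junc_col:
        expressed = expr >= expressed_cut
        unexpr = expr <= 0.01
        both = expressed | unexpr
        for name, mask in (("expressed", expressed), ("unexpressed", unexpr), ("pooled", both)):
            p = relcov_by_class.loc[mask, prom_col]
            j = relcov_by_class.loc[mask, junc_col]
            ok = p.notna() & j.notna()
            if ok.sum() >= 3 and p[ok].std() > 0 and j[ok].std() > 0:
                cross[name] = {
                    "pearson_r": float(stats.pearsonr(p[ok], j[ok]).statistic),
                    "spearman_rho": float(stats.spearmanr(p[ok], j[ok]).statistic),
                    "n": int(ok.sum()),
                }
    return results, cross


def scan_to_frame(results: Sequence[RegionScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_class": [r.region_class for r in results],
            "pearson_r": [r.pearson_r for r in results],
            "spearman_rho": [r.spearman_rho for r in results],
            "n_transcripts": [r.n_transcripts for r in results],
        }
    )
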