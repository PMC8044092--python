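"""In silico dilution: mixtures of tumor-patient and healthy cfDNA fragments.

A diluted sample at expected ctDNA fraction f is built from an undiluted
tumor-patient sample of known purity by drawing a proportion
p = f / purity of the output from the tumor sample and the remainder from a
concatenated healthy pool, keeping the total record count (and hence depth)
equal to the undiluted sample.  Provenance labels are retained so the
realized tumor-tissue fraction of every mixture can be audited.  Dilution
grids follow the study layout: dense fractions at and below 0.05, coarser
steps up to and including the source purity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import FragmentSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionSpec:
    tumor_sample_id: str
    healthy_pool_ids: tuple[str, ...]
    target_fraction: float
    source_purity: float
    seed: int
    preserve_depth: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.source_purity <= 1:
            raise ValueError("source_purity must lie in (0, 1]")
        if not 0 <= self.target_fraction <= self.source_purity:
            raise ValueError("target_fraction must lie in [0, source_purity]")


@dataclass(frozen=True)
class DilutionGrid:
    fractions: tuple[float, ...]
    replicates: int
    seeds: tuple[tuple[int, ...], ...]  # per fraction, one seed per replicate

    def __post_init__(self) -> None:
        if list(self.fractions) != sorted(self.fractions):
            raise ValueError("fractions must be sorted ascending")
        if len(self.seeds) != len(self.fractions):
            raise ValueError("need one seed tuple per fraction")

    @property
    def n_samples(self) -> int:
        return len(self.fractions) * self.replicates


def dilute(
    tumor: FragmentSet,
    healthy_pool: Sequence[FragmentSet],
    spec: DilutionSpec,
    sample_id: str | None = None,
) -> FragmentSet:
    """Sample a mixture of tumor and healthy fragments at the target fraction.

    Mixing proportion p = target_fraction / source_purity.  The output holds
    round(p*N) records drawn without replacement from the tumor sample and
    N - round(p*N) from the concatenated healthy pool, N being the tumor
    record count (depth preservation).  Seeded and reproducible.
    """
    if not healthy_pool:
        raise ValueError("healthy pool must be non-empty")
    p = spec.target_fraction / spec.source_purity
    n_total = len(tumor)
    n_tumor = int(round(p * n_total))
    n_healthy = n_total - n_tumor
    pool = FragmentSet.concat(list(healthy_pool), "pool")
    if n_healthy > len(pool):
        raise ValueError(
            f"healthy pool ({len(pool)} records) smaller than required ({n_healthy})"
        )
    rng = np.random.default_rng(spec.seed)
    sid = sample_id or f"{spec.tumor_sample_id}_f{spec.target_fraction:g}_s{spec.seed}"
    parts = []
    if n_tumor:
        idx_t = rng.choice(n_total, size=n_tumor, replace=False)
        parts.append(tumor.subset(np.sort(idx_t)))
    if n_healthy:
        idx_h = rng.choice(len(pool), size=n_healthy, replace=False)
        parts.append(pool.subset(np.sort(idx_h)))
    return FragmentSet.concat(parts, sid)


def make_grid(
    source_purity: float,
    low_step: float = 0.0025,
    high_step: float = 0.05,
    low_max: float = 0.05,
    low_min: float = 0.005,
    replicates: int = 1,
    seed: int | None = None,
) -> DilutionGrid:
    """Dilution fractions from ``low_min`` up to and including the source purity.

    Dense spacing (``low_step``) at fractions <= ``low_max``; coarser
    (``high_step``) spacing above, always ending at the source purity.
    """
    if not 0 < low_step <= high_step:
        raise ValueError("need 0 < low_step <= high_step")
    if source_purity < low_min:
        logger.warning("source purity %.4f below minimum fraction %.4f: empty grid",
                       source_purity, low_min)
        return DilutionGrid((), replicates, ())
    decimals = 6
    low = np.arange(low_min, min(low_max, source_purity) + low_step / 2, low_step)
    low = low[low <= low_max + 1e-12]
    high = np.arange(low_max + high_step, source_purity + high_step / 2, high_step)
    fractions = np.round(np.concatenate([low, high]), decimals)
    fractions = fractions[fractions <= round(source_purity, decimals)]
    fractions = np.unique(np.append(fractions, round(source_purity, decimals)))
    rng = np.random.default_rng(seed)
    seeds = tuple(
        tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=replicates))
        for _ in fractions
    )
    return DilutionGrid(tuple(float(f) for f in fractions), replicates, seeds)


def dilution_series(
    tumor: FragmentSet,
    healthy_pool: Sequence[FragmentSet],
    source_purity: float,
    grid: DilutionGrid,
    preserve_depth: bool = True,
) -> tuple[list[FragmentSet], pd.DataFrame]:
    """Materialize a grid for one source sample; returns samples + manifest."""
    samples: list[FragmentSet] = []
    rows = []
    pool_ids = tuple(h.sample_id for h in healthy_pool)
    for frac, seeds in zip(grid.fractions, grid.seeds):
        for rep, s in enumerate(seeds):
            spec = DilutionSpec(tumor.sample_id, pool_ids, frac, source_purity, s, preserve_depth)
            sid = f"{tumor.sample_id}_f{frac:g}_r{rep}"
            mixed = dilute(tumor, healthy_pool, spec, sample_id=sid)
            samples.append(mixed)
            rows.append(
                {
                    "sample_id": sid,
                    "tumor_sample_id": tumor.sample_id,
                    "target_fraction": frac,
                    "seed": s,
                    "n_records": len(mixed),
                    "realized_tumor_source_fraction": mixed.tumor_source_fraction(),
                }
            )
    return samples, pd.DataFrame(rows)


def downsample(
    sample: FragmentSet,
    fraction: float | None = None,
    depth: float | None = None,
    genome_length: int | None = None,
    seed: int | None = None,
    sample_id: str | None = None,
) -> FragmentSet:
    """Uniform without-replacement subsample of records.

    Either ``fraction`` in (0, 1] or a target ``depth`` (requires
    ``genome_length``); a requested depth above the available coverage
    raises.
    """
    if (fraction is None) == (depth is None):
        raise ValueError("give exactly one of fraction or depth")
    if depth is not None:
        if genome_length is None:
            raise ValueError("depth-based downsampling needs genome_length")
        available = sample.mean_depth(genome_length)
        if depth > available:
            raise ValueError(f"requested depth {depth} above available {available:.2f}")
        fraction = depth / available
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(round(fraction * len(sample)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sample), size=n, replace=False)
    return sample.subset(np.sort(idx), sample_id or f"{sample.sample_id}_ds{fraction:g}")
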