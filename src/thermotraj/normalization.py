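"""Median-of-ratios size-factor normalization and the low-data gene filter.

Size factors follow the standard median-of-ratios construction: each gene's
geometric mean across the samples of the analysis subset serves as a
pseudo-reference, and a sample's factor is the median over reference genes of
the count-to-reference ratio. Reference genes are those with strictly
positive counts in every sample (geometric mean > 0). Factors are computed
independently for every analysis subset, because each analysis involves a
different set of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_core import CountMatrix, logger


@dataclass(frozen=True)
class SizeFactorSet:
    """Per-sample positive scale factors for one analysis subset."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for sample, f in self.factors.items():
            if not (np.isfinite(f) and f > 0):
                raise ValueError(f"size factor for {sample!r} must be finite and > 0, got {f}")

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def as_array(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors]
        if missing:
            raise ValueError(f"no size factor for sample(s): {missing}")
        return np.array([self.factors[s] for s in sample_ids], dtype=float)


def compute_size_factors(counts: CountMatrix) -> SizeFactorSet:
    """Median-of-ratios size factors.

    For sample j, factor_j = median over reference genes g of
    counts[g, j] / geomean_g, where geomean_g is gene g's geometric mean
    across all samples and the reference set is the genes with all counts
    strictly positive.
    """
    mat = counts.counts
    reference = np.all(mat > 0, axis=1)
    if not reference.any():
        raise ValueError(
            "no reference genes: every gene has a zero count in some sample; "
            "relax filtering or supply a subset with jointly expressed genes"
        )
    logmat = np.log(mat[reference, :])
    log_geomean = logmat.mean(axis=1, keepdims=True)
    log_factors = np.median(logmat - log_geomean, axis=0)
    # only depth ratios are meaningful: anchor the factors at geometric mean
    # 1 so normalization is idempotent (a renormalized matrix has unit
    # factors); this differs from the raw medians by a dataset-wide constant
    # that cancels in every downstream ratio and model term except the
    # intercept
    log_factors -= log_factors.mean()
    factors = np.exp(log_factors)
    return SizeFactorSet(dict(zip(counts.sample_ids, factors)))


def normalize_counts(counts: CountMatrix, factors: SizeFactorSet) -> CountMatrix:
    """Divide each sample's column by its size factor."""
    f = factors.as_array(counts.sample_ids)
    return CountMatrix(counts.gene_ids, counts.sample_ids, counts.counts / f)


def filter_low_data_genes(counts: CountMatrix, min_samples: int = 3) -> CountMatrix:
    """Retain genes with non-zero counts in at least ``min_samples`` samples.

    "Has data" means a non-zero count: count tables carry no missingness
    distinct from zero. Applied per analysis subset, before normalization.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (counts.counts > 0).sum(axis=1) >= min_samples
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_low_data_genes: dropped %d of %d genes with data in fewer "
            "than %d samples",
            n_dropped,
            counts.n_genes,
            min_samples,
        )
    kept_genes = [g for g, k in zip(counts.gene_ids, keep) if k]
    return CountMatrix(kept_genes, counts.sample_ids, counts.counts[keep, :])
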