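"""Per-study ranking, the rank-product statistic, and MAF binning.

Each study column is ranked by ascending p-value (rank 1 = strongest
association).  Ranks are ordinal with a deterministic (p, snp_id)
tie-break, so every column is exactly a permutation of 1..N — the
permutation null sampler relies on this.  The rank product is kept in log
space, log RP = sum_k ln(rank_k), which is monotone-equivalent to the
integer product and cannot overflow at genome scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import MergedDataset
from .errors import SchemaError

DEFAULT_MAF_BOUNDARIES = (0.10, 0.25, 0.5)


@dataclass
class RankMatrix:
    """N x K integer ranks; each column is a permutation of 1..N."""

    ranks: np.ndarray
    snp_ids: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_studies(self) -> int:
        return self.ranks.shape[1]


@dataclass
class RpVector:
    """Per-SNP log rank product and the SNP ordering it induces.

    ``order`` lists SNP row indices by ascending log_rp, ties broken by
    snp_id so the ordering is deterministic.
    """

    log_rp: np.ndarray
    order: np.ndarray


@dataclass
class MafBinning:
    """Partition of (0, 0.5] into MAF bins.

    ``boundaries`` are the upper bin edges, strictly increasing and ending
    at 0.5; bins are half-open [lo, hi) except the final bin, which is
    closed at 0.5.  Defaults follow the conventional low / medium / high
    split at 10% and 25%.
    """

    boundaries: tuple
    bin_of: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.boundaries)

    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_of, minlength=self.n_bins)


def assign_ranks(dataset: MergedDataset) -> RankMatrix:
    """Rank every study column by ascending p-value.

    Ties are broken by snp_id (stable), keeping each column a permutation
    of 1..N.
    """
    n, k = dataset.pmatrix.shape
    if n == 0:
        raise SchemaError("cannot rank an empty dataset")
    ids = dataset.snp_ids.astype(str)
    ranks = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        order = np.lexsort((ids, dataset.pmatrix[:, j]))
        ranks[order, j] = np.arange(1, n + 1)
    return RankMatrix(ranks=ranks, snp_ids=dataset.snp_ids)


def rank_product(ranks: RankMatrix) -> RpVector:
    """Compute log RP per SNP: sum over studies of ln(rank)."""
    log_rp = np.log(ranks.ranks.astype(float)).sum(axis=1)
    order = np.lexsort((ranks.snp_ids.astype(str), log_rp))
    return RpVector(log_rp=log_rp, order=order)


def assign_maf_bins(mafs, boundaries=DEFAULT_MAF_BOUNDARIES) -> MafBinning:
    """Assign each SNP to a MAF bin.

    ``boundaries`` are strictly increasing upper edges, the last exactly
    0.5.  A MAF equal to an interior edge belongs to the upper bin; 0.5
    belongs to the top bin.
    """
    boundaries = tuple(float(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise SchemaError(f"bin boundaries must be strictly increasing, got {boundaries}")
    if not boundaries or boundaries[-1] != 0.5:
        raise SchemaError(f"final bin boundary must be 0.5, got {boundaries}")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size and not ((mafs > 0) & (mafs <= 0.5)).all():
        bad = mafs[~((mafs > 0) & (mafs <= 0.5))][0]
        raise SchemaError(f"MAF outside (0, 0.5]: {bad}")
    # interior edges only: maf == 0.5 falls in the final (closed) bin
    bin_of = np.searchsorted(np.asarray(boundaries[:-1]), mafs, side="right")
    return MafBinning(boundaries=boundaries, bin_of=bin_of.astype(np.int64))
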