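"""Shared test helpers: direct dataset construction and brute-force oracles.

The enumeration oracles are independent of the package's sampler: they walk
every rank tuple with itertools and Python arithmetic.
"""
import itertools

import numpy as np

from modrp import MergedDataset


def make_dataset(
    pmatrix,
    chromosomes=None,
    positions=None,
    mafs=None,
    snp_ids=None,
    study_ids=None,
) -> MergedDataset:
    """Build a MergedDataset directly, defaulting to LD-free geometry.

    By default every SNP sits on its own chromosome, so the LD constraint
    never rejects anything unless the test supplies clustered positions.
    """
    pmatrix = np.asarray(pmatrix, dtype=float)
    n, k = pmatrix.shape
    if snp_ids is None:
        snp_ids = [f"rs{i:04d}" for i in range(n)]
    if chromosomes is None:
        chromosomes = [str(i + 1) for i in range(n)]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n)]
    if mafs is None:
        mafs = [0.3] * n
    if study_ids is None:
        study_ids = [f"s{j + 1}" for j in range(k)]
    return MergedDataset(
        snp_ids=np.array(snp_ids, dtype=object),
        chromosomes=np.array([str(c) for c in chromosomes], dtype=object),
        positions=np.array(positions, dtype=np.int64),
        mafs=np.array(mafs, dtype=float),
        pmatrix=pmatrix,
        study_ids=list(study_ids),
    )


def pairwise_outside_ld(tup, chromosomes, positions, ld_distance):
    """Validity predicate used by the enumeration oracles."""
    for a, b in itertools.combinations(tup, 2):
        if chromosomes[a] == chromosomes[b] and abs(positions[a] - positions[b]) <= ld_distance:
            return False
    return True


def enumerate_null_values(contrib, pool, valid=None):
    """All valid-tuple statistics by exhaustive enumeration.

    ``contrib`` is the N x K per-column contribution matrix; a tuple draws
    one pool member per column and sums its contributions.  Returns the
    (unsorted) array of statistics of every valid tuple.
    """
    k = contrib.shape[1]
    values = []
    for tup in itertools.product(pool, repeat=k):
        if valid is not None and not valid(tup):
            continue
        s = 0.0
        for col, i in enumerate(tup):
            s += contrib[i, col]
        values.append(s)
    return np.array(values)


def exact_rp_pvalues(ranks):
    """Exact unconstrained rank-product p-values by full enumeration.

    For each SNP, the fraction of all N^K rank tuples whose log product is
    <= the SNP's observed log product.
    """
    contrib = np.log(ranks.astype(float))
    null = np.sort(enumerate_null_values(contrib, np.arange(ranks.shape[0])))
    observed = contrib.sum(axis=1)
    counts = np.searchsorted(null, observed, side="right")
    return counts / null.size
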