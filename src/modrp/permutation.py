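"""Constrained permutation null for the rank product (the modRP core).

The null distribution of the statistic is built by resampling the observed
ranks: each iteration draws one SNP per study column, uniformly and
independently, from the target MAF bin, and is kept only if every pair of
sampled SNPs lies outside the configured linkage-disequilibrium (LD)
range — on different chromosomes, or further apart than ``ld_distance``
base pairs.  Rejection sampling makes the accepted draws exactly uniform
over the valid tuples.  One null distribution is built per MAF bin and
shared by all SNPs of that bin: sampling within the bin is what transmits
bin-level power differences into the null, and the LD rejection removes
the dependence that physically clustered SNPs would otherwise inject.

Empirical p-values use the (r + 1) / (B + 1) permutation estimator and
never return zero.  The full analysis runs the null construction twice
with a pair of seeds; if any near-significant SNP's two p-values disagree
by more than a relative tolerance, the iteration count is doubled and both
runs are redrawn, and the reported p-value is the higher of the final
pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import MergedDataset
from .errors import ConstraintError, ModrpError
from .ranking import MafBinning, RankMatrix, RpVector

_BATCH = 1 << 16


@dataclass(frozen=True)
class ConstraintConfig:
    """Switches and parameters of the MAF / LD sampling constraints.

    ``ld_distance`` is in base pairs; two SNPs on the same chromosome
    within that distance (inclusive) are considered potentially in LD, and
    a SNP paired with itself trivially violates the constraint.
    """

    ld_distance: int = 1_000_000
    maf_constrained: bool = True
    ld_constrained: bool = True
    max_rejections_per_draw: int = 10_000

    def __post_init__(self) -> None:
        if self.ld_distance <= 0:
            raise ModrpError(f"ld_distance must be > 0, got {self.ld_distance}")


UNCONSTRAINED = ConstraintConfig(maf_constrained=False, ld_constrained=False)


@dataclass
class NullDistribution:
    """Sorted multiset of B valid-iteration null statistics for one bin."""

    bin_index: int
    values: np.ndarray
    B: int
    seed: object
    constraints: ConstraintConfig
    n_proposed: int = 0
    n_valid: int = 0

    @property
    def rejection_rate(self) -> float:
        if self.n_proposed == 0:
            return 0.0
        return 1.0 - self.n_valid / self.n_proposed


@dataclass(frozen=True)
class ConvergenceConfig:
    """Paired-run protocol parameters.

    Two independent runs (``seed_pair``) each build the per-bin nulls with
    ``B_initial`` valid iterations.  SNPs with min(p1, p2) <= 100 / B are
    screened: if any such pair differs by more than ``rel_tolerance``
    relative, B is doubled (both runs redrawn with fresh derived seeds), up
    to ``max_doublings`` times.
    """

    B_initial: int = 100_000
    rel_tolerance: float = 0.2
    max_doublings: int = 6
    seed_pair: tuple = (0, 1)

    def __post_init__(self) -> None:
        if not (0 < self.rel_tolerance < 1):
            raise ModrpError(f"rel_tolerance must be in (0, 1), got {self.rel_tolerance}")
        if self.B_initial < 1_000:
            raise ModrpError(f"B_initial must be >= 1000, got {self.B_initial}")


def seed_pair_from(seed: int) -> tuple:
    """Derive the two paired-run seeds from one user seed.

    Uses SeedSequence's expansion so a single integer reproduces the whole
    analysis; results are masked to 31 bits.
    """
    s1, s2 = np.random.SeedSequence(int(seed)).generate_state(2)
    return (int(s1) & 0x7FFFFFFF, int(s2) & 0x7FFFFFFF)


@dataclass
class PairedRunResult:
    """Per-SNP p-values and bookkeeping from a paired constrained run.

    ``p`` is the reported (higher-of-pair) p-value; ``not_converged``
    flags SNPs whose seed pair still disagreed after the final doubling.
    """

    p: np.ndarray
    p_run1: np.ndarray
    p_run2: np.ndarray
    statistic: np.ndarray
    B: int
    doublings: int
    not_converged: np.ndarray
    report: dict = field(default_factory=dict)


def _chrom_codes(chromosomes: np.ndarray) -> np.ndarray:
    _, codes = np.unique(chromosomes.astype(str), return_inverse=True)
    return codes.astype(np.int64)


def _ld_valid(snps, chrom_codes, positions, ld_distance):
    """Boolean mask: every pair of sampled SNPs is outside LD range."""
    n, k = snps.shape
    valid = np.ones(n, dtype=bool)
    for a in range(k - 1):
        ca = chrom_codes[snps[:, a]]
        pa = positions[snps[:, a]]
        for b in range(a + 1, k):
            conflict = (ca == chrom_codes[snps[:, b]]) & (
                np.abs(pa - positions[snps[:, b]]) <= ld_distance
            )
            valid &= ~conflict
    return valid


def _sample_null_values(contrib, pool, chrom_codes, positions, constraints, B, rng):
    """Collect B valid-iteration statistics for one bin's pool.

    ``contrib`` is the N x K per-column statistic contribution (ln rank for
    RP, -2 ln p for Fisher); a draw's statistic is the sum of its K sampled
    contributions.  Returns (sorted values, proposed draw count, valid
    draw count).
    """
    k = contrib.shape[1]
    check_ld = constraints.ld_constrained and k > 1
    out = np.empty(B, dtype=np.float64)
    filled = 0
    proposed = 0
    n_valid = 0
    rejected_since_accept = 0
    while filled < B:
        n = int(min(_BATCH, max(1024, B - filled)))
        snps = pool[rng.integers(0, pool.size, size=(n, k))]
        proposed += n
        if check_ld:
            good = snps[_ld_valid(snps, chrom_codes, positions, constraints.ld_distance)]
        else:
            good = snps
        if good.shape[0] == 0:
            rejected_since_accept += n
            if rejected_since_accept >= constraints.max_rejections_per_draw:
                raise ConstraintError(
                    f"no valid iteration after {rejected_since_accept} rejections in a bin "
                    f"of {pool.size} SNPs; the bin is too small or clustered for "
                    f"ld_distance={constraints.ld_distance}"
                )
            continue
        rejected_since_accept = 0
        n_valid += good.shape[0]
        take = min(good.shape[0], B - filled)
        sel = good[:take]
        vals = contrib[sel[:, 0], 0].astype(np.float64, copy=True)
        for j in range(1, k):
            vals += contrib[sel[:, j], j]
        out[filled : filled + take] = vals
        filled += take
    out.sort()
    return out, proposed, n_valid


def draw_null_tuple(
    bin_index: int,
    dataset: MergedDataset,
    ranks: RankMatrix,
    constraints: ConstraintConfig,
    rng: np.random.Generator,
    binning: MafBinning | None = None,
) -> float:
    """Draw one valid iteration and return its log rank product.

    Samples one SNP per study column uniformly from the bin (from all SNPs
    when the MAF constraint is off), rejecting tuples with any pair of
    sampled SNPs within LD range.
    """
    contrib = np.log(ranks.ranks.astype(float))
    if constraints.maf_constrained:
        if binning is None:
            raise ModrpError("MAF-constrained sampling requires a MafBinning")
        pool = np.flatnonzero(binning.bin_of == bin_index)
    else:
        pool = np.arange(dataset.n_snps)
    if pool.size == 0:
        raise ConstraintError(f"MAF bin {bin_index} is empty")
    codes = _chrom_codes(dataset.chromosomes)
    k = contrib.shape[1]
    check_ld = constraints.ld_constrained and k > 1
    for rejections in range(constraints.max_rejections_per_draw):
        snps = pool[rng.integers(0, pool.size, size=(1, k))]
        if not check_ld or _ld_valid(snps, codes, dataset.positions, constraints.ld_distance)[0]:
            return float(contrib[snps[0], np.arange(k)].sum())
    raise ConstraintError(
        f"no valid iteration after {constraints.max_rejections_per_draw} rejections in "
        f"bin {bin_index} of {pool.size} SNPs (ld_distance={constraints.ld_distance})"
    )


def build_null_distribution(
    bin_index: int,
    dataset: MergedDataset,
    ranks: RankMatrix,
    constraints: ConstraintConfig,
    B: int,
    rng,
    binning: MafBinning | None = None,
) -> NullDistribution:
    """Build one bin's null distribution of log RP from B valid iterations.

    ``rng`` may be a numpy Generator or an integer seed; given a seed the
    result is fully deterministic.
    """
    if B < 1:
        raise ModrpError(f"B must be >= 1 (empirical p undefined at B=0), got {B}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    contrib = np.log(ranks.ranks.astype(float))
    if constraints.maf_constrained:
        if binning is None:
            raise ModrpError("MAF-constrained sampling requires a MafBinning")
        pool = np.flatnonzero(binning.bin_of == bin_index)
    else:
        pool = np.arange(dataset.n_snps)
    if pool.size == 0:
        raise ConstraintError(f"MAF bin {bin_index} is empty")
    codes = _chrom_codes(dataset.chromosomes)
    values, proposed, n_valid = _sample_null_values(
        contrib, pool, codes, dataset.positions, constraints, B, rng
    )
    return NullDistribution(
        bin_index=bin_index,
        values=values,
        B=B,
        seed=seed,
        constraints=constraints,
        n_proposed=proposed,
        n_valid=n_valid,
    )


def empirical_pvalue(observed_log_rp: float, null: NullDistribution) -> float:
    """Lower-tail permutation p-value with the plus-one correction.

    p = (#{null values <= observed} + 1) / (B + 1); ties with the observed
    value count as <= (conservative).
    """
    if null.B < 1:
        raise ModrpError("null distribution is empty")
    count = int(np.searchsorted(null.values, observed_log_rp, side="right"))
    return (count + 1) / (null.B + 1)


def _paired_run(
    contrib: np.ndarray,
    tail: str,
    dataset: MergedDataset,
    binning: MafBinning | None,
    constraints: ConstraintConfig,
    convergence: ConvergenceConfig,
) -> PairedRunResult:
    """Shared engine behind modRP and the empirical-Fisher comparator.

    ``tail`` is 'lower' for rank products (small = significant) and
    'upper' for Fisher statistics (large = significant).
    """
    n, k = contrib.shape
    observed = contrib.sum(axis=1)
    if constraints.maf_constrained:
        if binning is None:
            raise ModrpError("MAF-constrained sampling requires a MafBinning")
        bin_of = binning.bin_of
        n_bins = binning.n_bins
    else:
        bin_of = np.zeros(n, dtype=np.int64)
        n_bins = 1
    pools = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    codes = _chrom_codes(dataset.chromosomes)
    positions = dataset.positions

    B = int(convergence.B_initial)
    p1 = p2 = None
    bad = np.zeros(n, dtype=bool)
    bin_stats: dict[int, dict] = {}
    attempt = 0
    for attempt in range(convergence.max_doublings + 1):
        run_ps = []
        bin_stats = {b: {"n_snps": int(pool.size)} for b, pool in enumerate(pools) if pool.size}
        for run_idx, run_seed in enumerate(convergence.seed_pair):
            p = np.empty(n, dtype=np.float64)
            for b, pool in enumerate(pools):
                if pool.size == 0:
                    continue
                ss = np.random.SeedSequence([int(run_seed) & 0x7FFFFFFF, attempt, b])
                rng = np.random.default_rng(ss)
                null, proposed, n_valid = _sample_null_values(
                    contrib, pool, codes, positions, constraints, B, rng
                )
                obs = observed[pool]
                if tail == "lower":
                    count = np.searchsorted(null, obs, side="right")
                elif tail == "upper":
                    count = null.size - np.searchsorted(null, obs, side="left")
                else:  # pragma: no cover
                    raise ValueError(tail)
                p[pool] = (count + 1) / (B + 1)
                bin_stats[b][f"rejection_rate_run{run_idx + 1}"] = 1.0 - n_valid / proposed
            run_ps.append(p)
        p1, p2 = run_ps
        near = np.minimum(p1, p2) <= 100.0 / B
        rel = np.abs(p1 - p2) / np.maximum(p1, p2)
        bad = near & (rel > convergence.rel_tolerance)
        if not bad.any() or attempt == convergence.max_doublings:
            break
        B *= 2
    return PairedRunResult(
        p=np.maximum(p1, p2),
        p_run1=p1,
        p_run2=p2,
        statistic=observed,
        B=B,
        doublings=attempt,
        not_converged=bad,
        report={
            "B": B,
            "doublings": attempt,
            "n_not_converged": int(bad.sum()),
            "bins": bin_stats,
            "seed_pair": tuple(convergence.seed_pair),
            "constraints": {
                "ld_distance": constraints.ld_distance,
                "maf_constrained": constraints.maf_constrained,
                "ld_constrained": constraints.ld_constrained,
            },
        },
    )


def run_modrp(
    dataset: MergedDataset,
    ranks: RankMatrix,
    rp: RpVector | None = None,
    binning: MafBinning | None = None,
    constraints: ConstraintConfig | None = None,
    convergence: ConvergenceConfig | None = None,
) -> PairedRunResult:
    """Run the full modRP protocol: paired constrained nulls per MAF bin.

    Each SNP gets two empirical p-values (one per seeded run); near-
    significant disagreement beyond the tolerance doubles B for both runs;
    the reported p-value is the higher of the final pair.  ``rp`` is
    accepted for interface symmetry; the statistic is recomputed from the
    ranks in log space.
    """
    constraints = constraints if constraints is not None else ConstraintConfig()
    convergence = convergence if convergence is not None else ConvergenceConfig()
    contrib = np.log(ranks.ranks.astype(float))
    return _paired_run(contrib, "lower", dataset, binning, constraints, convergence)
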