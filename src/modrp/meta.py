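"""Comparator meta-analysis methods: Fisher, empirical Fisher, standard RP.

Fisher's method combines K independent p-values via X^2 = -2 sum ln p_k,
chi-square with 2K degrees of freedom under the null.  The "modified
Fisher" comparator replaces the chi-square reference with the same
constrained permutation null used by modRP, so the four-way comparison
isolates the statistic rather than the null construction.  Standard RP is
the rank product with an unconstrained global null (no MAF stratification,
no LD rejection).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .dataio import MergedDataset
from .errors import ModrpError
from .permutation import (
    ConstraintConfig,
    ConvergenceConfig,
    PairedRunResult,
    UNCONSTRAINED,
    _paired_run,
)
from .ranking import MafBinning, RankMatrix, RpVector

METHODS = ("fisher", "mod_fisher", "rp", "modrp")


@dataclass(frozen=True)
class MethodResult:
    """One SNP's outcome under one method."""

    snp_id: str
    method: str
    statistic: float
    p: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ModrpError(f"{self.snp_id}/{self.method}: p outside (0, 1]: {self.p}")


def fisher_statistic(pvalues) -> float:
    """Fisher combination statistic X^2 = -2 sum_k ln p_k."""
    p = np.asarray(pvalues, dtype=float)
    if (p <= 0).any():
        raise ModrpError("Fisher statistic is infinite at p = 0")
    if (p > 1).any():
        raise ModrpError(f"p-value above 1: {p[p > 1][0]}")
    return float(-2.0 * np.log(p).sum())


def fisher_pvalue(statistic: float, k: int) -> float:
    """Upper-tail chi-square probability with 2K degrees of freedom."""
    if statistic < 0:
        raise ModrpError(f"Fisher statistic must be >= 0, got {statistic}")
    return float(stats.chi2.sf(statistic, df=2 * k))


def run_fisher(dataset: MergedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Traditional Fisher meta-analysis on every SNP.

    Returns (statistics, analytic p-values), vectorised over the merged
    p-value matrix.
    """
    if (dataset.pmatrix <= 0).any():
        raise ModrpError("Fisher statistic is infinite at p = 0")
    x2 = -2.0 * np.log(dataset.pmatrix).sum(axis=1)
    return x2, stats.chi2.sf(x2, df=2 * dataset.n_studies)


def run_mod_fisher(
    dataset: MergedDataset,
    binning: MafBinning | None = None,
    constraints: ConstraintConfig | None = None,
    convergence: ConvergenceConfig | None = None,
) -> PairedRunResult:
    """Empirical-Fisher comparator: Fisher X^2 against the constrained null.

    Identical machinery to modRP (per-bin nulls, paired runs, higher-of-
    pair reporting) but each iteration's statistic is the Fisher X^2 of
    the sampled SNPs' observed p-values, and significance is upper-tail.
    """
    constraints = constraints if constraints is not None else ConstraintConfig()
    convergence = convergence if convergence is not None else ConvergenceConfig()
    contrib = -2.0 * np.log(dataset.pmatrix)
    return _paired_run(contrib, "upper", dataset, binning, constraints, convergence)


def run_standard_rp(
    dataset: MergedDataset,
    ranks: RankMatrix,
    rp: RpVector | None = None,
    convergence: ConvergenceConfig | None = None,
) -> PairedRunResult:
    """Standard rank product: one global unconstrained null of observed ranks.

    Definitionally modRP with both the MAF and LD constraints disabled;
    the same seeds give bit-identical results to that configuration.
    """
    from .permutation import run_modrp

    convergence = convergence if convergence is not None else ConvergenceConfig()
    return run_modrp(
        dataset,
        ranks,
        rp,
        binning=None,
        constraints=UNCONSTRAINED,
        convergence=convergence,
    )
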