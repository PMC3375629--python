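"""Cross-study correlation diagnostics and Bonferroni control.

The correlation report contrasts the dependence between study p-value
columns over the whole dataset with the dependence over the top fraction
of SNPs ranked by RP: strong correlation concentrated in the top set is
the signature of shared (pleiotropic or LD-driven) signal.  Spearman
(rank) correlation is used since the method itself operates on ranks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import MergedDataset
from .errors import ModrpError
from .ranking import RpVector


@dataclass
class CorrelationReport:
    """K x K Spearman correlations over the RP top set and over all SNPs."""

    top_fraction: float
    matrix_top: np.ndarray
    matrix_all: np.ndarray
    n_top: int
    study_ids: list


def _spearman_matrix(pmatrix: np.ndarray) -> np.ndarray:
    k = pmatrix.shape[1]
    if k == 1:
        return np.ones((1, 1))
    rho = np.asarray(stats.spearmanr(pmatrix).statistic, dtype=float)
    if rho.ndim == 0:  # scipy collapses the K=2 case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return rho


def correlation_report(
    dataset: MergedDataset, rp: RpVector, top_fraction: float = 0.001
) -> CorrelationReport:
    """Spearman correlation between study columns, top-RP set vs all SNPs.

    The top set holds the first ceil(top_fraction * N) SNPs by ascending
    log RP (ties by snp_id); it must contain at least 3 SNPs.
    """
    if not (0 < top_fraction <= 1):
        raise ModrpError(f"top_fraction must be in (0, 1], got {top_fraction}")
    n = dataset.n_snps
    n_top = math.ceil(top_fraction * n)
    if n_top < 3:
        raise ModrpError(
            f"top set has only {n_top} SNPs; use a top_fraction of at least {3 / n:.3g}"
        )
    top_idx = rp.order[:n_top]
    return CorrelationReport(
        top_fraction=top_fraction,
        matrix_top=_spearman_matrix(dataset.pmatrix[top_idx]),
        matrix_all=_spearman_matrix(dataset.pmatrix),
        n_top=n_top,
        study_ids=list(dataset.study_ids),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests; significance is p <= threshold."""
    if not (0 < alpha < 1):
        raise ModrpError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ModrpError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def min_attainable_p(B: int) -> float:
    """Smallest Monte-Carlo p at B iterations: 1 / (B + 1).

    When this exceeds the Bonferroni threshold no SNP can be declared
    significant at the configured B; callers should warn.
    """
    return 1.0 / (B + 1)
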