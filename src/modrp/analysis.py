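"""End-to-end orchestration: merge -> rank -> bin -> nulls -> methods -> Bonferroni.

This is the library face of the command-line ``run`` subcommand; it is
also what scripts drive directly.
"""
from __future__ import annotations

import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dataio import MergedDataset, merge_studies
from .diagnostics import bonferroni_threshold, correlation_report, min_attainable_p
from .errors import ModrpError
from .meta import METHODS, MethodResult, run_fisher, run_mod_fisher, run_standard_rp
from .permutation import (
    ConstraintConfig,
    ConvergenceConfig,
    run_modrp,
    seed_pair_from,
)
from .ranking import (
    DEFAULT_MAF_BOUNDARIES,
    assign_maf_bins,
    assign_ranks,
    rank_product,
)


@dataclass
class AnalysisResult:
    """Everything one analysis produces, ready to write or inspect."""

    dataset: MergedDataset
    binning: object
    results: list
    per_method: dict
    threshold: float
    correlation: object
    manifest: dict = field(default_factory=dict)

    def results_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "method": r.method,
                "statistic": r.statistic,
                "p": r.p,
                "significant": r.significant,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def run_analysis(
    studies,
    annotation,
    *,
    methods=METHODS,
    maf_boundaries=DEFAULT_MAF_BOUNDARIES,
    constraints: ConstraintConfig | None = None,
    iterations: int = 100_000,
    rel_tolerance: float = 0.2,
    max_doublings: int = 6,
    seed: int = 0,
    alpha: float = 0.05,
    top_fraction: float = 0.001,
) -> AnalysisResult:
    """Run the selected methods on merged studies and flag significance.

    All selected methods share one merged dataset, one MAF binning and one
    seed-derived pair of run seeds, so their p-values are directly
    comparable.  The Bonferroni threshold is alpha divided by the number
    of merged SNPs.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ModrpError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    if not methods:
        raise ModrpError("select at least one method")
    constraints = constraints if constraints is not None else ConstraintConfig()
    convergence = ConvergenceConfig(
        B_initial=iterations,
        rel_tolerance=rel_tolerance,
        max_doublings=max_doublings,
        seed_pair=seed_pair_from(seed),
    )

    dataset = merge_studies(list(studies), list(annotation))
    ranks = assign_ranks(dataset)
    rp = rank_product(ranks)
    binning = assign_maf_bins(dataset.mafs, maf_boundaries)
    threshold = bonferroni_threshold(alpha, dataset.n_snps)

    per_method: dict[str, dict] = {}
    if "fisher" in methods:
        stat, p = run_fisher(dataset)
        per_method["fisher"] = {"statistic": stat, "p": p}
    if "mod_fisher" in methods:
        res = run_mod_fisher(dataset, binning, constraints, convergence)
        per_method["mod_fisher"] = {"statistic": res.statistic, "p": res.p, "run": res}
    if "rp" in methods:
        res = run_standard_rp(dataset, ranks, rp, convergence)
        per_method["rp"] = {"statistic": res.statistic, "p": res.p, "run": res}
    if "modrp" in methods:
        res = run_modrp(dataset, ranks, rp, binning, constraints, convergence)
        per_method["modrp"] = {"statistic": res.statistic, "p": res.p, "run": res}

    results: list[MethodResult] = []
    for m in METHODS:
        if m not in per_method:
            continue
        stat = per_method[m]["statistic"]
        p = per_method[m]["p"]
        for i in range(dataset.n_snps):
            results.append(
                MethodResult(
                    snp_id=str(dataset.snp_ids[i]),
                    method=m,
                    statistic=float(stat[i]),
                    p=float(p[i]),
                    significant=bool(p[i] <= threshold),
                )
            )

    corr = correlation_report(dataset, rp, top_fraction) if dataset.n_snps * top_fraction >= 3 else None

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "seed_pair": list(seed_pair_from(seed)),
        "alpha": alpha,
        "bonferroni_threshold": threshold,
        "n_snps": dataset.n_snps,
        "study_ids": dataset.study_ids,
        "drop_counts": dataset.drop_counts,
        "maf_boundaries": list(maf_boundaries),
        "bin_counts": binning.counts().tolist(),
        "methods": list(methods),
        "iterations_initial": iterations,
        "constraints": {
            "ld_distance": constraints.ld_distance,
            "maf_constrained": constraints.maf_constrained,
            "ld_constrained": constraints.ld_constrained,
        },
        "runs": {
            m: per_method[m]["run"].report
            for m in per_method
            if "run" in per_method[m]
        },
    }
    for m, info in per_method.items():
        if "run" in info and min_attainable_p(info["run"].B) > threshold:
            manifest.setdefault("warnings", []).append(
                f"{m}: minimum attainable Monte-Carlo p {min_attainable_p(info['run'].B):.3g} "
                f"exceeds the Bonferroni threshold {threshold:.3g}; no SNP can reach significance "
                f"at B={info['run'].B}"
            )
    return AnalysisResult(
        dataset=dataset,
        binning=binning,
        results=results,
        per_method=per_method,
        threshold=threshold,
        correlation=corr,
        manifest=manifest,
    )
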