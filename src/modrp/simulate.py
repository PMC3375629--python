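"""Synthetic multi-study GWAS summary statistics with controllable structure.

The generator emulates the three features of real summary data that the
constrained permutation null exists to handle:

* **Positional LD blocks** — SNPs are laid out in consecutive blocks; the
  p-values of SNPs inside one block share an equicorrelated Gaussian
  copula (correlation ``rho``), while blocks are spaced far enough apart
  to be independent and outside any plausible LD distance.
* **MAF-dependent power** — a per-MAF-bin exponent ``gamma`` transforms
  p -> p^gamma, which is monotone (ranks within a column are preserved
  inside each bin) and breaks marginal uniformity per bin exactly the way
  unequal power does: gamma < 1 deflates significance, gamma > 1 inflates
  it.
* **Pleiotropic signals** — chosen SNPs are overwritten with a small
  p-value of a target magnitude in each affected study, and every
  injection is recorded in a truth table.

With rho = 0 and gamma = 1 everywhere, all null p-values are i.i.d.
uniform on (0, 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SnpAnnotation, StudySummary
from .errors import ModrpError
from .ranking import DEFAULT_MAF_BOUNDARIES, assign_maf_bins


@dataclass(frozen=True)
class SignalSpec:
    """One injected pleiotropic signal.

    ``snp`` is a SNP row index or "random"; ``studies`` are 0-based study
    indices the signal affects; ``magnitude`` is the target p-value.
    ``jitter_decades`` > 0 spreads the injected p uniformly over
    +/- that many decades around the target.
    """

    snp: object = "random"
    studies: tuple = (0,)
    magnitude: float = 1e-6
    jitter_decades: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-study dataset.

    Defaults give 5000 SNPs over three studies — the scale at which the
    per-bin calibration properties are assessed — in blocks of 10 SNPs
    spanning 50 kb, with 2 Mb between block starts so distinct blocks are
    always outside the default 1 Mb LD distance.  MAF is uniform on
    (0.01, 0.5); ``maf_beta`` switches to a Beta(a, b) shape rescaled to
    that interval for a more realistic low-frequency-heavy spectrum.
    """

    n_snps: int = 5_000
    n_studies: int = 3
    n_chromosomes: int = 22
    block_size: int = 10
    block_span: int = 50_000
    block_gap: int = 2_000_000
    maf_low: float = 0.01
    maf_high: float = 0.5
    maf_beta: tuple | None = None
    rho: float = 0.0
    gamma: tuple = (1.0, 1.0, 1.0)
    maf_boundaries: tuple = DEFAULT_MAF_BOUNDARIES
    signals: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < self.n_studies:
            raise ModrpError("n_snps must be >= n_studies")
        if self.block_size < 1:
            raise ModrpError("block_size must be >= 1")
        if not (0 <= self.rho < 1):
            raise ModrpError(f"rho must be in [0, 1), got {self.rho}")
        if len(self.gamma) != len(self.maf_boundaries):
            raise ModrpError(
                f"gamma needs one exponent per MAF bin: "
                f"{len(self.gamma)} given for {len(self.maf_boundaries)} bins"
            )
        if len(self.signals) > self.n_snps:
            raise ModrpError("more signals than SNPs")


@dataclass
class SimulatedSet:
    """A simulated dataset plus the ground truth of injected signals."""

    studies: list
    annotation: list
    truth: pd.DataFrame
    config: SimulationConfig


def _layout_positions(cfg: SimulationConfig):
    """Assign block/chromosome/position per SNP.

    Blocks are dealt round-robin across chromosomes; successive blocks on
    one chromosome start ``block_gap`` bp apart, and SNPs within a block
    are evenly spread over ``block_span`` bp.
    """
    n = cfg.n_snps
    block_of = np.arange(n) // cfg.block_size
    idx_in_block = np.arange(n) % cfg.block_size
    chrom_idx = block_of % cfg.n_chromosomes
    block_on_chrom = block_of // cfg.n_chromosomes
    step = cfg.block_span // max(cfg.block_size - 1, 1)
    positions = 1 + block_on_chrom * cfg.block_gap + idx_in_block * max(step, 1)
    chromosomes = np.array([str(c + 1) for c in chrom_idx], dtype=object)
    return block_of, chromosomes, positions.astype(np.int64)


def simulate(config: SimulationConfig) -> SimulatedSet:
    """Generate studies, annotation and a truth table from one seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_snps, cfg.n_studies
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object)
    block_of, chromosomes, positions = _layout_positions(cfg)

    if cfg.maf_beta is not None:
        a, b = cfg.maf_beta
        mafs = cfg.maf_low + (cfg.maf_high - cfg.maf_low) * rng.beta(a, b, size=n)
    else:
        mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=n)
    binning = assign_maf_bins(mafs, cfg.maf_boundaries)

    n_blocks = int(block_of.max()) + 1
    pmat = np.empty((n, k))
    for j in range(k):
        shared = rng.standard_normal(n_blocks)
        z = np.sqrt(cfg.rho) * shared[block_of] + np.sqrt(1.0 - cfg.rho) * rng.standard_normal(n)
        pmat[:, j] = stats.norm.sf(z)  # marginally uniform on (0, 1)
    gamma = np.asarray(cfg.gamma, dtype=float)[binning.bin_of]
    pmat = pmat ** gamma[:, None]

    truth_rows = []
    taken: set[int] = set()
    for sig in cfg.signals:
        if sig.snp == "random":
            free = np.setdiff1d(np.arange(n), np.fromiter(taken, dtype=int, count=len(taken)))
            s = int(rng.choice(free))
        else:
            s = int(sig.snp)
            if not (0 <= s < n):
                raise ModrpError(f"signal SNP index {s} out of range")
        taken.add(s)
        for j in sig.studies:
            if not (0 <= j < k):
                raise ModrpError(f"signal study index {j} out of range")
            p = sig.magnitude
            if sig.jitter_decades > 0:
                p *= 10.0 ** rng.uniform(-sig.jitter_decades, sig.jitter_decades)
            pmat[s, j] = min(p, 1.0)
        truth_rows.append(
            {
                "snp_id": snp_ids[s],
                "snp_index": s,
                "studies": ",".join(str(j) for j in sig.studies),
                "target_p": sig.magnitude,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["snp_id", "snp_index", "studies", "target_p"])

    np.clip(pmat, np.nextafter(0.0, 1.0), 1.0, out=pmat)
    studies = [
        StudySummary(study_id=f"study{j + 1}", snp_ids=snp_ids.tolist(), pvalues=pmat[:, j])
        for j in range(k)
    ]
    annotation = [
        SnpAnnotation(snp_ids[i], chromosomes[i], int(positions[i]), float(mafs[i]))
        for i in range(n)
    ]
    return SimulatedSet(studies=studies, annotation=annotation, truth=truth, config=cfg)


def write_fixture(simulated: SimulatedSet, directory) -> dict:
    """Write the TSV fixture a run consumes; returns the paths written.

    Emits one summary table per study (minimal dialect), the annotation
    table, and the signal truth table.  Byte-identical for equal inputs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s in simulated.studies:
        path = directory / f"{s.study_id}.tsv"
        pd.DataFrame({"snp_id": s.snp_ids, "p": s.pvalues}).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
        paths[s.study_id] = path
    ann = simulated.annotation
    ann_path = directory / "annotation.tsv"
    pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in ann],
            "chromosome": [a.chromosome for a in ann],
            "position": [a.position for a in ann],
            "maf": [a.maf for a in ann],
        }
    ).to_csv(ann_path, sep="\t", index=False, float_format="%.12g")
    paths["annotation"] = ann_path
    truth_path = directory / "truth.tsv"
    simulated.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.12g")
    paths["truth"] = truth_path
    return paths
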