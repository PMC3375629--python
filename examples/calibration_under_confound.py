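"""Why the constrained null exists: per-MAF-bin calibration under a power confound.

Simulates a pure null in which low-MAF SNPs are underpowered (p -> p^0.5)
and high-MAF SNPs overpowered (p -> p^1.5), then compares the fraction of
SNPs with p <= 0.05 per MAF bin for the standard rank product (one global
null) and modRP (one null per MAF bin).  A calibrated method reports
about 5% in every bin.
"""
import numpy as np

from modrp import (
    ConvergenceConfig,
    SimulationConfig,
    assign_maf_bins,
    assign_ranks,
    merge_studies,
    rank_product,
    run_modrp,
    run_standard_rp,
    seed_pair_from,
    simulate,
)

sim = simulate(SimulationConfig(n_snps=5_000, n_studies=3, gamma=(0.5, 1.0, 1.5), seed=8))
ds = merge_studies(sim.studies, sim.annotation)
ranks = assign_ranks(ds)
rp = rank_product(ranks)
binning = assign_maf_bins(ds.mafs)
conv = ConvergenceConfig(B_initial=100_000, seed_pair=seed_pair_from(8))

rp_res = run_standard_rp(ds, ranks, rp, conv)
modrp_res = run_modrp(ds, ranks, rp, binning, convergence=conv)

labels = ["low (MAF<0.10)", "medium (0.10-0.25)", "high (0.25-0.50)"]
print("fraction of SNPs with p <= 0.05 per MAF bin (nominal 0.05):\n")
print(f"{'bin':<22}{'n SNPs':>8}{'standard RP':>14}{'modRP':>10}")
for b, label in enumerate(labels):
    members = np.flatnonzero(binning.bin_of == b)
    print(
        f"{label:<22}{members.size:>8}"
        f"{(rp_res.p[members] <= 0.05).mean():>14.4f}"
        f"{(modrp_res.p[members] <= 0.05).mean():>10.4f}"
    )
print(
    "\nStandard RP starves the underpowered low-MAF bin of significance and "
    "inflates the high-MAF bin; modRP stays near 0.05 everywhere because each "
    "bin is judged against resamples of its own ranks."
)
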