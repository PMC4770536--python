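"""Simulate a small gilt cohort and run genotype/sample QC.

Builds a pedigreed population with injected missingness and Mendelian
errors, writes/reads PLINK text PED/MAP, and applies the four SNP
filters and two animal filters used before association analysis.
"""

import numpy as np

from giltgwas import (
    SimConfig,
    filter_animals,
    filter_snps,
    inject_missingness,
    mendel_check,
    simulate_pedigree_genotypes,
)

cfg = SimConfig(
    n_animals=200,
    chromosome_plan=[("1", 60, 50_000_000), ("2", 60, 50_000_000), ("X", 30, 40_000_000)],
    missing_rate=0.03,
    mendel_error_rate=0.01,
    seed=1,
)
ped, geno = simulate_pedigree_genotypes(cfg, n_sires=10, n_dams=50)
geno = inject_missingness(geno, cfg)
print(f"simulated {geno.n_animals} animals x {geno.n_markers} SNPs "
      f"({np.mean(geno.codes == -1):.1%} missing calls)")

geno, snp_report = filter_snps(geno, min_call_rate=0.95, min_maf=0.05)
print("SNP filter removed:", snp_report.removed, "->", geno.n_markers, "SNPs kept")

geno, animal_report = filter_animals(geno, max_missing=0.05)
print("animal filter removed:", animal_report.removed, "->", geno.n_animals, "kept")

failing, mendel_report = mendel_check(geno, ped, max_error_rate=0.01)
print(f"Mendelian (parentage) test: {len(failing)} of {mendel_report.n_input} "
      "tested offspring fail — these carry the injected genotyping errors")
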