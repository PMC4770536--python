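"""Synthetic genotypes, pedigrees and phenotypes with the study's structure.

The generator emulates a SNP-array GWAS design for age at puberty in
gilts: a few hundred phenotyped females genotyped at tens of thousands
of autosomal + X SNPs (MAF >= 0.05 after QC), age at first estrus in
days around a 200-day mean, year-season of birth as the contemporary
group, a sparse genetic architecture in which a SNP carries a nonzero
effect with probability (1 - pi_true) drawn from a common normal, and a
sire/dam pedigree for the animal model.  Missing calls and Mendelian
errors can be injected to exercise the QC filters.

Linkage disequilibrium between adjacent SNPs follows a first-order
Markov haplotype model: each haplotype's allele indicators are generated
from a latent Gaussian AR(1) process with per-step correlation
``ld_rho``, thresholded to match each SNP's allele frequency.  rho = 0
gives independent loci; rho -> 1 makes neighbouring SNPs near copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedigree import Pedigree
from .qc import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults describe the emulated study scaled to desk size: 759 gilts,
    19 chromosomes (18 autosomes + X), MAF in [0.05, 0.5], sparse
    architecture pi_true = 0.9935, residual variance giving a moderate
    heritability, 8 year-season classes (4 birth years x 2 seasons).
    """

    n_animals: int = 759
    chromosome_plan: list = field(
        default_factory=lambda: [(str(c), 100, 150_000_000) for c in range(1, 19)]
        + [("X", 100, 140_000_000)]
    )
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    pi_true: float = 0.9935
    sigma2_u_true: float = 1.0
    sigma2_e_true: float = 134.8
    n_season_classes: int = 8
    season_effect_sd: float = 5.0
    baseline_age: float = 200.0
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if not self.chromosome_plan:
            raise ValueError("chromosome_plan must not be empty")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0 < self.pi_true < 1:
            raise ValueError("pi_true must lie in (0, 1)")
        if min(self.sigma2_u_true, self.sigma2_e_true) < 0:
            raise ValueError("variances must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.mendel_error_rate < 1:
            raise ValueError("mendel_error_rate must lie in [0, 1)")
        for chrom, n_snps, length in self.chromosome_plan:
            if n_snps < 5:
                raise ValueError(
                    f"chromosome {chrom}: need >= 5 SNPs to form windows"
                )
            if length < n_snps:
                raise ValueError(f"chromosome {chrom}: length too short")

    @property
    def n_markers(self) -> int:
        return sum(n for _, n, _ in self.chromosome_plan)


@dataclass
class TruthSet:
    """Ground truth recorded by the phenotype simulator for recovery tests."""

    true_effects: np.ndarray  # days per counted-allele copy; 0 where excluded
    true_included: np.ndarray  # bool per SNP
    true_class_effects: dict  # year_season label -> effect (days)
    true_h2_marker: float  # realized var(Zu) / var(y)
    true_window_gv: pd.DataFrame  # non-overlapping 5-SNP window variances

    def __post_init__(self):
        if (self.true_effects[~self.true_included] != 0).any():
            raise ValueError("true_effects must be zero where not included")


def _marker_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n_snps, length in config.chromosome_plan:
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
        for i, p in enumerate(pos):
            rows.append(
                {
                    "name": f"SIM{chrom}_{i + 1:05d}",
                    "chrom": str(chrom),
                    "pos_bp": int(p),
                    "allele1": "B",
                    "allele2": "A",
                }
            )
    return pd.DataFrame(rows)


def _haplotypes(
    n_hap: int, freqs: np.ndarray, plan_sizes: list, rho: float, rng
) -> np.ndarray:
    """Binary haplotypes with latent Gaussian AR(1) dependence per chromosome."""
    m = freqs.size
    z = np.empty((n_hap, m))
    start = 0
    for size in plan_sizes:
        z[:, start] = rng.standard_normal(n_hap)
        for j in range(start + 1, start + size):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * rng.standard_normal(
                n_hap
            )
        start += size
    thresh = norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Unrelated-animal genotypes: each animal is the sum of two haplotypes."""
    rng = np.random.default_rng(config.seed)
    markers = _marker_table(config, rng)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_markers)
    sizes = [n for _, n, _ in config.chromosome_plan]
    h1 = _haplotypes(config.n_animals, freqs, sizes, config.ld_rho, rng)
    h2 = _haplotypes(config.n_animals, freqs, sizes, config.ld_rho, rng)
    codes = (h1 + h2).astype(np.int8)
    ids = [f"G{i + 1:05d}" for i in range(config.n_animals)]
    return GenotypeMatrix(codes=codes, animal_ids=ids, markers=markers)


def simulate_pedigree_genotypes(
    config: SimConfig, n_sires: int = 37, n_dams: int = 380
) -> tuple[Pedigree, GenotypeMatrix]:
    """Founder parents plus offspring genotypes by per-locus Mendelian transmission.

    Founders are drawn from the allele frequencies; each of
    ``config.n_animals`` offspring gets a random sire and dam (dams may
    repeat, so full- and half-sib families arise).  With
    ``mendel_error_rate > 0`` that fraction of offspring calls is flipped
    to a different genotype code, creating detectable opposing-homozygote
    conflicts for the parentage test.  Loci are transmitted independently
    (no linkage within gametes).
    """
    if n_sires < 1 or n_dams < 1:
        raise ValueError("need at least one sire and one dam")
    rng = np.random.default_rng(config.seed)
    markers = _marker_table(config, rng)
    m = config.n_markers
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)

    sire_ids = [f"S{i + 1:04d}" for i in range(n_sires)]
    dam_ids = [f"D{i + 1:04d}" for i in range(n_dams)]
    off_ids = [f"G{i + 1:05d}" for i in range(config.n_animals)]

    founders = (rng.random((n_sires + n_dams, m)) < freqs).astype(np.int8) + (
        rng.random((n_sires + n_dams, m)) < freqs
    ).astype(np.int8)
    sire_g = founders[:n_sires]
    dam_g = founders[n_sires:]

    sire_pick = rng.integers(0, n_sires, size=config.n_animals)
    dam_pick = rng.integers(0, n_dams, size=config.n_animals)

    def gamete(par_codes):
        # transmit the counted allele w.p. 0 / 0.5 / 1 for codes 0 / 1 / 2
        return (rng.random(par_codes.shape) < par_codes / 2.0).astype(np.int8)

    off = gamete(sire_g[sire_pick]) + gamete(dam_g[dam_pick])

    if config.mendel_error_rate > 0:
        corrupt = rng.random(off.shape) < config.mendel_error_rate
        shift = rng.integers(1, 3, size=off.shape).astype(np.int8)
        off = np.where(corrupt, (off + shift) % 3, off).astype(np.int8)

    codes = np.vstack([sire_g, dam_g, off])
    geno = GenotypeMatrix(
        codes=codes, animal_ids=sire_ids + dam_ids + off_ids, markers=markers
    )
    ped = Pedigree(
        ids=sire_ids + dam_ids + off_ids,
        sires=[None] * (n_sires + n_dams)
        + [sire_ids[i] for i in sire_pick],
        dams=[None] * (n_sires + n_dams) + [dam_ids[i] for i in dam_pick],
    )
    return ped, geno


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Age-at-puberty phenotypes from the sparse-architecture linear model.

    y_i = baseline + class effect + sum_j z_ij u_j + e_i, with u_j nonzero
    with probability (1 - pi_true) ~ N(0, sigma2_u_true) and
    e_i ~ N(0, sigma2_e_true); z is the centred dosage.  Requires a
    complete (no missing) genotype matrix — simulate phenotypes before
    injecting missingness.
    """
    if (geno.codes == MISSING).any():
        raise ValueError("genotypes contain missing codes; simulate phenotypes first")
    rng = np.random.default_rng(config.seed + 1)
    n, m = geno.codes.shape

    included = rng.random(m) < (1.0 - config.pi_true)
    effects = np.where(
        included, rng.normal(0.0, np.sqrt(config.sigma2_u_true), size=m), 0.0
    )
    Zc = geno.codes.astype(float)
    Zc = Zc - Zc.mean(axis=0, keepdims=True)
    g = Zc @ effects

    classes = [f"YS{c + 1}" for c in range(config.n_season_classes)]
    class_effects = dict(
        zip(classes, rng.normal(0.0, config.season_effect_sd, config.n_season_classes))
    )
    assign = rng.integers(0, config.n_season_classes, size=n)
    season = np.array([classes[a] for a in assign])
    b = np.array([class_effects[s] for s in season])

    e = rng.normal(0.0, np.sqrt(config.sigma2_e_true), size=n)
    y = config.baseline_age + b + g + e

    var_y = float(np.var(y, ddof=1))
    h2_marker = float(np.var(g, ddof=1) / var_y) if var_y > 0 else 0.0

    window_rows = []
    start = 0
    widx = 0
    for chrom, n_snps, _ in config.chromosome_plan:
        for w0 in range(start, start + n_snps - 4, 5):
            gw = Zc[:, w0 : w0 + 5] @ effects[w0 : w0 + 5]
            window_rows.append(
                {
                    "window_id": widx,
                    "chrom": str(chrom),
                    "first_index": w0,
                    "gv": float(np.var(gw, ddof=1)),
                }
            )
            widx += 1
        start += n_snps

    phen = pd.DataFrame(
        {"animal_id": geno.animal_ids, "age_days": y, "year_season": season}
    )
    truth = TruthSet(
        true_effects=effects,
        true_included=included,
        true_class_effects=class_effects,
        true_h2_marker=h2_marker,
        true_window_gv=pd.DataFrame(window_rows),
    )
    return phen, truth


def inject_missingness(geno: GenotypeMatrix, config: SimConfig) -> GenotypeMatrix:
    """Set calls to the missing sentinel uniformly at random at ``missing_rate``."""
    if config.missing_rate == 0:
        return GenotypeMatrix(
            codes=geno.codes.copy(),
            animal_ids=list(geno.animal_ids),
            markers=geno.markers.copy(),
        )
    rng = np.random.default_rng(config.seed + 2)
    mask = rng.random(geno.codes.shape) < config.missing_rate
    codes = np.where(mask, np.int8(MISSING), geno.codes).astype(np.int8)
    return GenotypeMatrix(
        codes=codes, animal_ids=list(geno.animal_ids), markers=geno.markers.copy()
    )


def truncate_phenotypes(phen: pd.DataFrame, cutoff: float = 240.0) -> pd.DataFrame:
    """Drop records with age_days above the cutoff (right-censoring emulation).

    The emulated study only analysed gilts observed in estrus by the end
    of the detection window; this optional switch probes the selection
    effect of that design on variance components.
    """
    return phen[phen["age_days"] <= cutoff].reset_index(drop=True)
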