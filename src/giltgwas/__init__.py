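"""GWAS for age at puberty in pigs by Bayesian whole-genome regression.

Pipeline: genotype/sample QC -> pedigree REML variance components (as
priors) -> BayesC-pi (estimate the zero-effect probability pi) -> BayesC
with pi fixed -> 5-SNP window genetic-variance scan -> parametric
bootstrap significance with proportion-of-false-positives control ->
LD and candidate intervals.  A synthetic-data module emulates the study
design so every stage is testable without real genotypes.
"""

from importlib import resources

import pandas as pd

from .bayesc import (
    McmcConfig,
    PosteriorSummary,
    estimate_pi,
    marker_h2,
    run_mcmc,
    year_season_design,
)
from .bootstrap import (
    BootstrapResult,
    bootstrap_window_test,
    pfp_adjust,
    simulate_null_dataset,
)
from .ld import pairwise_r2
from .pedigree import (
    Pedigree,
    PriorSpec,
    RelationshipMatrix,
    VarianceComponents,
    build_amatrix,
    reml_fit,
    variance_priors,
)
from .qc import (
    MISSING,
    GenotypeMatrix,
    QcReport,
    encode_center_impute,
    filter_animals,
    filter_snps,
    genotype_pca,
    mendel_check,
    validate_phenotypes,
)
from .report import candidate_intervals, merge_adjacent, run_pipeline
from .simulate import (
    SimConfig,
    TruthSet,
    inject_missingness,
    simulate_genotypes,
    simulate_pedigree_genotypes,
    simulate_phenotypes,
)
from .windows import (
    WindowDef,
    build_windows,
    expected_qtl_count,
    select_putative_qtl,
    window_variance,
)

__version__ = "0.1.0"


def load_reported_qtl_windows() -> pd.DataFrame:
    """Significant 5-SNP QTL windows reported for age at puberty in a
    white-composite pig population (Sus scrofa build 10.2 coordinates),
    with each window's share of genetic variance, rank and bootstrap
    p-value.  Used for interval arithmetic and reporting examples."""
    with resources.files("giltgwas.data").joinpath("qtl_windows.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})
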