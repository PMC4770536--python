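"""Genotype data model and pre-association quality control.

The central container is :class:`GenotypeMatrix`: an ``n x m`` matrix of
counted-allele dosages (0/1/2, ``MISSING`` = -1) plus ordered marker
metadata.  QC follows the usual SNP-array workflow for a pedigreed pig
population: drop SNPs with unknown map position, Y-linked SNPs, low call
rate or low minor allele frequency; drop animals with excessive
missingness or failing a Mendelian (parentage) consistency test; then
mean-impute and column-centre the dosages to form the regression design.

Boundary semantics are strict inequalities: a SNP is removed when its
call rate is *below* the threshold or its MAF is *below* the threshold;
an animal is removed when its missing fraction is *above* the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

AUTOSOMES = tuple(str(i) for i in range(1, 19))
#: labels accepted in marker metadata; "0" means unknown position
VALID_CHROMS = AUTOSOMES + ("X", "Y", "0")
UNKNOWN_CHROMS = frozenset({"0", "", "NA", "unknown"})

MARKER_COLUMNS = ["name", "chrom", "pos_bp", "allele1", "allele2"]


class QcError(ValueError):
    """Raised when a QC step would leave an empty data set or gets bad input."""


@dataclass
class MarkerMeta:
    """Metadata for one SNP; ``allele1`` is the counted allele."""

    name: str
    chrom: str
    pos_bp: int
    allele1: str = "A"
    allele2: str = "B"


@dataclass
class GenotypeMatrix:
    """Coded SNP genotypes with marker metadata.

    Parameters
    ----------
    codes : ndarray of shape (n_animals, n_markers), int8
        Copies of the counted allele: 0, 1, 2, or ``MISSING`` (-1).
    animal_ids : list of str
    markers : DataFrame with columns name, chrom, pos_bp, allele1, allele2,
        one row per column of ``codes``, positions strictly increasing
        within each chromosome and chromosomes contiguous.
    """

    codes: np.ndarray
    animal_ids: list
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise QcError("codes must be a 2-D array")
        if self.codes.shape[0] != len(self.animal_ids):
            raise QcError("animal_ids length does not match codes rows")
        if self.codes.shape[1] != len(self.markers):
            raise QcError("markers length does not match codes columns")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise QcError("genotype codes must be 0, 1, 2 or the missing sentinel")
        self.markers = self.markers.reset_index(drop=True)
        self._check_marker_order()

    def _check_marker_order(self) -> None:
        mk = self.markers
        if list(mk.columns[:3]) != MARKER_COLUMNS[:3] and not set(
            MARKER_COLUMNS[:3]
        ).issubset(mk.columns):
            raise QcError(f"markers must have columns {MARKER_COLUMNS[:3]}")
        seen = []
        for chrom, grp in mk.groupby("chrom", sort=False):
            if chrom not in VALID_CHROMS:
                raise QcError(f"invalid chromosome label {chrom!r}")
            pos = grp["pos_bp"].to_numpy()
            if (pos < 1).any():
                raise QcError("marker positions must be >= 1")
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise QcError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
            seen.append(chrom)
        if len(seen) != len(set(seen)):
            raise QcError("chromosomes must each form a single contiguous block")

    # -- basic dimensions ------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    # -- per-marker summaries --------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP from non-missing calls (NaN if none)."""
        obs = self.codes != MISSING
        cnt = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.codes == MISSING, 0, self.codes).sum(axis=0) / (
                2.0 * cnt
            )
        return np.where(cnt > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        """Minor (folded) allele frequency per SNP; invariant to the counted allele."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def animal_missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column index arrays."""
        rows = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        cols = np.arange(self.n_markers) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            codes=self.codes[np.ix_(rows, cols)],
            animal_ids=[self.animal_ids[i] for i in rows],
            markers=self.markers.iloc[cols].reset_index(drop=True),
        )


@dataclass
class QcReport:
    """Accounting for one filter pass: removed + retained = input, per axis."""

    axis: str  # "snp" or "animal"
    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)  # filter name -> count
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": self.axis, "filter": k, "removed": v}
            for k, v in self.removed.items()
        ]
        rows.append(
            {"axis": self.axis, "filter": "retained", "removed": self.n_retained}
        )
        return pd.DataFrame(rows)


def filter_snps(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    drop_unknown_chrom: bool = True,
    drop_y: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with unknown position, on Y, call rate < threshold or MAF < threshold.

    Each removed SNP is attributed to the first rule it fails, in the order
    unknown-chromosome, Y-chromosome, call-rate, MAF.  Thresholds are strict:
    a SNP at exactly ``min_call_rate`` or ``min_maf`` is retained.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise QcError("thresholds must lie in [0, 1]")
    chrom = geno.markers["chrom"].astype(str).to_numpy()
    unknown = np.isin(chrom, list(UNKNOWN_CHROMS)) & drop_unknown_chrom
    ylinked = (chrom == "Y") & drop_y & ~unknown
    cr = geno.call_rate()
    low_cr = (cr < min_call_rate) & ~unknown & ~ylinked
    maf = geno.maf()
    low_maf = (np.nan_to_num(maf, nan=0.0) < min_maf) & ~unknown & ~ylinked & ~low_cr
    drop = unknown | ylinked | low_cr | low_maf
    keep = np.flatnonzero(~drop)
    if keep.size == 0:
        raise QcError("SNP filtering removed every marker")
    report = QcReport(
        axis="snp",
        n_input=geno.n_markers,
        n_retained=keep.size,
        removed={
            "unknown_chromosome": int(unknown.sum()),
            "y_chromosome": int(ylinked.sum()),
            "call_rate": int(low_cr.sum()),
            "maf": int(low_maf.sum()),
        },
        thresholds={"min_call_rate": min_call_rate, "min_maf": min_maf},
    )
    return geno.subset(snps=keep), report


def filter_animals(
    geno: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove animals whose missing-genotype fraction strictly exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise QcError("max_missing must lie in [0, 1]")
    miss = geno.animal_missing_rate()
    keep = np.flatnonzero(~(miss > max_missing))
    if keep.size == 0:
        raise QcError("animal filtering removed every animal")
    report = QcReport(
        axis="animal",
        n_input=geno.n_animals,
        n_retained=keep.size,
        removed={"missing_rate": int(geno.n_animals - keep.size)},
        thresholds={"max_missing": max_missing},
    )
    return geno.subset(animals=keep), report


def mendel_check(
    geno: GenotypeMatrix, ped, max_error_rate: float = 0.01
) -> tuple[list, QcReport]:
    """Mendelian (parentage) consistency test by opposing homozygotes.

    For every genotyped offspring with at least one genotyped parent, count
    loci where offspring and a parent are opposing homozygotes (0 vs 2) over
    loci where both calls are observed; the offspring fails when
    conflicts / compared > ``max_error_rate``.  Heterozygous calls never
    conflict with any parent.

    Returns the list of failing animal ids and a report.  Raises on a
    pedigree cycle (delegated to ``ped.topological_order()``).
    """
    ped.topological_order()  # raises PedigreeCycleError if cyclic
    idx = {a: i for i, a in enumerate(geno.animal_ids)}
    failing = []
    tested = 0
    for child, sire, dam in ped.records():
        if child not in idx:
            continue
        parents = [p for p in (sire, dam) if p is not None and p in idx]
        if not parents:
            continue
        tested += 1
        g_off = geno.codes[idx[child]]
        conflicts = 0
        compared = 0
        for p in parents:
            g_par = geno.codes[idx[p]]
            both = (g_off != MISSING) & (g_par != MISSING)
            compared += int(both.sum())
            conflicts += int(
                (((g_off == 0) & (g_par == 2)) | ((g_off == 2) & (g_par == 0)))[
                    both
                ].sum()
            )
        if compared > 0 and conflicts / compared > max_error_rate:
            failing.append(child)
    report = QcReport(
        axis="animal",
        n_input=tested,
        n_retained=tested - len(failing),
        removed={"mendel_fail": len(failing)},
        thresholds={"max_error_rate": max_error_rate},
    )
    return failing, report


def encode_center_impute(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls then centre each SNP column to mean zero.

    Returns ``(Z, col_means)`` where ``Z`` is the n x m float design matrix
    used by the whole-genome regression and ``col_means`` are the observed
    per-column dosage means (needed to reconstruct genomic values on new
    animals).
    """
    codes = geno.codes.astype(float)
    obs = geno.codes != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise QcError("column with zero observed calls; run SNP QC first")
    means = np.where(obs, codes, 0.0).sum(axis=0) / n_obs
    Z = np.where(obs, codes, means[None, :]) - means[None, :]
    return Z, means


def genotype_pca(geno: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` principal component scores of the centred genotype matrix.

    Returns ``(scores, explained_variance)``; components are ordered by
    decreasing explained variance.  Used to inspect population
    stratification before association analysis.
    """
    if k < 1 or k > min(geno.n_animals, geno.n_markers):
        raise QcError(f"k must be in [1, min(n, m)]; got {k}")
    Z, _ = encode_center_impute(geno)
    # PCA of animals: SVD of the centred matrix
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    explained = s[:k] ** 2 / max(geno.n_animals - 1, 1)
    return scores, explained


def validate_phenotypes(
    phen: pd.DataFrame, age_range: tuple[float, float] = (120.0, 260.0)
) -> pd.DataFrame:
    """Validate a phenotype table (animal_id, age_days, year_season).

    ``age_days`` must fall in a plausible window (default 120-260 d around
    the 140-240 d estrus-detection period) and ``year_season`` must be
    non-empty.  Returns the table with canonical column order.
    """
    required = ["animal_id", "age_days", "year_season"]
    missing_cols = [c for c in required if c not in phen.columns]
    if missing_cols:
        raise QcError(f"phenotype table missing columns {missing_cols}")
    age = phen["age_days"].astype(float)
    lo, hi = age_range
    if ((age < lo) | (age > hi)).any():
        raise QcError(f"age_days outside plausible range [{lo}, {hi}]")
    ys = phen["year_season"].astype(str)
    if (ys.str.len() == 0).any():
        raise QcError("year_season labels must be non-empty")
    return phen[required].reset_index(drop=True)
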