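"""Pairwise linkage disequilibrium (r^2) from unphased genotypes.

Two estimators:

``em``
    Two-locus haplotype frequencies by expectation-maximisation over the
    3x3 diplotype table (only the double heterozygote is phase-ambiguous),
    then D = p_AB - p_A p_B and r^2 = D^2 / (p_A q_A p_B q_B).  This is
    the classical gametic r^2 a haplotype-based tool reports.

``genotype_corr``
    Squared Pearson correlation of the dosage columns (composite LD) —
    faster, and close to the EM estimate under Hardy-Weinberg.

Missing calls are dropped pairwise; a monomorphic SNP has undefined r^2
and is reported as missing with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix


@dataclass
class LdResult:
    snp_a: str
    snp_b: str
    D: float | None
    r2: float | None
    n_used: int
    method: str
    reason: str | None = None  # set when r2 is undefined


def em_haplotype_freqs(
    ga: np.ndarray, gb: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """EM estimate of the 4 haplotype frequencies (AB, Ab, aB, ab).

    ``ga``/``gb`` are dosage vectors (0/1/2) of the counted alleles A and
    B with no missing values.  When no double heterozygotes are present
    the estimate equals the closed-form haplotype count in one step.
    """
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    n = counts.sum()
    if n == 0:
        raise ValueError("no complete genotype pairs")
    n_hap = 2.0 * n

    # known haplotype contributions: genotype (i, j) carries i copies of A,
    # j of B; all phase-resolved except the double het (1, 1)
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = counts[i, j]
            # haplotype pair for an unambiguous genotype
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            for k in range(2):
                h = (1 - a_alleles[k]) * 2 + (1 - b_alleles[k])
                base[h] += c
    ndh = counts[1, 1]

    f = np.full(4, 0.25)
    for _ in range(max_iter):
        # double het is AB/ab with prob prop. to f_AB*f_ab, else Ab/aB
        p_cis = f[0] * f[3]
        p_trans = f[1] * f[2]
        tot = p_cis + p_trans
        w = 0.5 if tot == 0 else p_cis / tot
        new = base.copy()
        new[0] += ndh * w
        new[3] += ndh * w
        new[1] += ndh * (1 - w)
        new[2] += ndh * (1 - w)
        new /= n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _r2_from_freqs(f: np.ndarray) -> tuple[float, float]:
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    D = f[0] - pA * pB
    return float(D), float(D * D / denom) if denom > 0 else float("nan")


def _pair_r2(ga, gb, method: str) -> tuple[float | None, float | None, int, str | None]:
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok].astype(float), gb[ok].astype(float)
    n = ga.size
    if n == 0:
        return None, None, 0, "no complete pairs"
    if np.ptp(ga) == 0 or np.ptp(gb) == 0:
        return None, None, n, "monomorphic SNP"
    if method == "em":
        f = em_haplotype_freqs(ga.astype(int), gb.astype(int))
        D, r2 = _r2_from_freqs(f)
        return D, r2, n, None
    if method == "genotype_corr":
        r = np.corrcoef(ga, gb)[0, 1]
        # composite-LD D on the dosage scale: cov/2 approximates gametic D
        D = float(np.cov(ga, gb, ddof=1)[0, 1] / 2.0)
        return D, float(r * r), n, None
    raise ValueError(f"unknown LD method {method!r}")


def pairwise_r2(
    geno: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    region: tuple[str, int, int] | None = None,
    method: str = "em",
) -> pd.DataFrame:
    """LD for explicit marker-name pairs, or all pairs within a region.

    ``region`` is (chromosome, start_bp, end_bp), inclusive.  Returns one
    row per pair with D, r2, n_used and a reason column for undefined
    results.
    """
    names = geno.markers["name"].tolist()
    idx = {nm: i for i, nm in enumerate(names)}
    if pairs is None:
        if region is None:
            raise ValueError("provide either pairs or a region")
        chrom, lo, hi = region
        sel = geno.markers[
            (geno.markers["chrom"].astype(str) == str(chrom))
            & (geno.markers["pos_bp"] >= lo)
            & (geno.markers["pos_bp"] <= hi)
        ]["name"].tolist()
        pairs = [(a, b) for i, a in enumerate(sel) for b in sel[i + 1 :]]
    rows = []
    for a, b in pairs:
        D, r2, n, reason = _pair_r2(
            geno.codes[:, idx[a]], geno.codes[:, idx[b]], method
        )
        rows.append(
            LdResult(snp_a=a, snp_b=b, D=D, r2=r2, n_used=n, method=method, reason=reason)
        )
    return pd.DataFrame([r.__dict__ for r in rows])
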