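"""5-SNP window genetic-variance scan and putative-QTL selection.

Windows of five consecutive SNPs are formed in chromosome-position
order (non-overlapping stride-5 by default; an overlapping stride-1
"sliding" mode is available).  A window's genetic variance is the
empirical variance across animals of the genomic values contributed by
its SNPs' posterior-mean effects, expressed also as a percentage of the
total genetic variance; the K windows with the largest share, with
K = round(m*(1-pi)) — the expected number of effect-bearing SNPs — are
declared putative QTL and passed to the bootstrap test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_SIZE = 5

#: chromosome sort key: autosomes numerically, then X, Y, unknown
def chrom_sort_key(chrom: str) -> tuple:
    c = str(chrom)
    if c.isdigit() and c != "0":
        return (0, int(c))
    return (1, {"X": 1, "Y": 2}.get(c, 3))


@dataclass
class WindowDef:
    """Five consecutive markers on one chromosome."""

    window_id: int
    chrom: str
    first_index: int  # column index of the first SNP in the marker table
    start_bp: int
    end_bp: int
    marker_first: str
    marker_last: str

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.first_index, self.first_index + WINDOW_SIZE)


def build_windows(
    markers: pd.DataFrame, mode: str = "non_overlapping"
) -> list[WindowDef]:
    """Form 5-SNP windows per chromosome; windows never span chromosomes.

    ``non_overlapping`` strides by 5 and discards a trailing partial
    window; ``sliding`` strides by 1.  A chromosome with fewer than 5
    SNPs contributes no windows (warning).
    """
    if mode not in ("non_overlapping", "sliding"):
        raise ValueError(f"unknown window mode {mode!r}")
    stride = WINDOW_SIZE if mode == "non_overlapping" else 1
    out: list[WindowDef] = []
    offset = 0
    wid = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        k = len(grp)
        if k < WINDOW_SIZE:
            warnings.warn(
                f"chromosome {chrom} has {k} SNPs (<{WINDOW_SIZE}); no windows formed"
            )
            offset += k
            continue
        names = grp["name"].to_numpy()
        pos = grp["pos_bp"].to_numpy()
        for s in range(0, k - WINDOW_SIZE + 1, stride):
            out.append(
                WindowDef(
                    window_id=wid,
                    chrom=str(chrom),
                    first_index=offset + s,
                    start_bp=int(pos[s]),
                    end_bp=int(pos[s + WINDOW_SIZE - 1]),
                    marker_first=str(names[s]),
                    marker_last=str(names[s + WINDOW_SIZE - 1]),
                )
            )
            wid += 1
        offset += k
    return out


def window_variance(
    u_mean: np.ndarray, Z: np.ndarray, windows: list[WindowDef]
) -> pd.DataFrame:
    """Genetic variance per window from posterior-mean SNP effects.

    gv is the variance across animals of Z_w @ u_w; gv_pct its percentage
    of the total genetic variance var(Z @ u); rank 1 is the largest
    gv_pct.  Ties in gv_pct get deterministic ranks by (chromosome,
    start_bp).
    """
    u_mean = np.asarray(u_mean, float)
    if Z.shape[1] != u_mean.size:
        raise ValueError("effect vector does not match genotype design columns")
    if windows and windows[-1].first_index + WINDOW_SIZE > Z.shape[1]:
        raise ValueError("window indices exceed marker set")
    total = float(np.var(Z @ u_mean, ddof=1))
    rows = []
    for w in windows:
        gw = Z[:, w.first_index : w.first_index + WINDOW_SIZE] @ u_mean[
            w.first_index : w.first_index + WINDOW_SIZE
        ]
        gv = float(np.var(gw, ddof=1))
        rows.append(
            {
                "window_id": w.window_id,
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "marker_first": w.marker_first,
                "marker_last": w.marker_last,
                "first_index": w.first_index,
                "gv": gv,
                "gv_pct": 100.0 * gv / total if total > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        order = sorted(
            range(len(df)),
            key=lambda i: (
                -df["gv_pct"].iat[i],
                chrom_sort_key(df["chrom"].iat[i]),
                df["start_bp"].iat[i],
            ),
        )
        ranks = np.empty(len(df), dtype=int)
        ranks[order] = np.arange(1, len(df) + 1)
        df["rank"] = ranks
    return df


def expected_qtl_count(m_snps: int, pi: float) -> int:
    """K = m*(1-pi) rounded to the nearest integer (half-to-even)."""
    return int(np.rint(m_snps * (1.0 - pi)))


def select_putative_qtl(
    results: pd.DataFrame, m_snps: int, pi: float
) -> pd.DataFrame:
    """Top-K windows by genetic-variance share, K = round(m*(1-pi)).

    K exceeding the number of windows is clamped with a warning.  The
    returned frame is ordered by rank (ties already broken
    deterministically by :func:`window_variance`).
    """
    K = expected_qtl_count(m_snps, pi)
    if K > len(results):
        warnings.warn(
            f"requested top {K} windows but only {len(results)} exist; clamping"
        )
        K = len(results)
    return results.sort_values("rank").head(K).reset_index(drop=True)
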