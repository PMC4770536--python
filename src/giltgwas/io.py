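"""Text-format readers and writers: PLINK PED/MAP, TSV/CSV tables, BED.

PED is whitespace-delimited with six leading columns (family, id, sire,
dam, sex, phenotype) then two allele columns per SNP; "0 0" marks a
missing call.  MAP has chromosome, SNP id, genetic distance (written as
0) and bp position.  On reading, the counted allele of each SNP is the
lexicographically greater of its two observed alleles (recorded in the
marker table as ``allele1``); analysis results are invariant to this
choice up to effect-sign flips.

Genomic coordinates are 1-based inclusive internally (MAP convention);
BED export converts to 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .qc import MISSING, GenotypeMatrix


def write_ped_map(geno: GenotypeMatrix, prefix: str, phen: pd.DataFrame | None = None):
    """Write ``prefix.ped`` and ``prefix.map``; phenotype column from ``phen`` if given."""
    mk = geno.markers
    with open(f"{prefix}.map", "w") as fh:
        for _, row in mk.iterrows():
            fh.write(f"{row['chrom']}\t{row['name']}\t0\t{row['pos_bp']}\n")
    phen_map = (
        dict(zip(phen["animal_id"].astype(str), phen["age_days"]))
        if phen is not None
        else {}
    )
    a1 = mk["allele1"].to_numpy() if "allele1" in mk else np.repeat("B", len(mk))
    a2 = mk["allele2"].to_numpy() if "allele2" in mk else np.repeat("A", len(mk))
    with open(f"{prefix}.ped", "w") as fh:
        for i, aid in enumerate(geno.animal_ids):
            fields = ["FAM", str(aid), "0", "0", "0", str(phen_map.get(str(aid), -9))]
            codes = geno.codes[i]
            for j, c in enumerate(codes):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a2[j], a2[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix: str) -> GenotypeMatrix:
    """Read ``prefix.ped`` + ``prefix.map`` into a :class:`GenotypeMatrix`."""
    mk = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "name", "cm", "pos_bp"],
        dtype={"chrom": str, "name": str},
    )
    m = len(mk)
    ids = []
    rows = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * m}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2)

    codes = np.empty((len(ids), m), dtype=np.int8)
    a1_out, a2_out = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(set(obs.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {mk['name'].iat[j]} has >2 alleles: {uniq}")
        counted = uniq[-1] if uniq else "0"  # lexicographically greater allele
        other = uniq[0] if len(uniq) == 2 else (uniq[0] if uniq else "0")
        missing = (col[:, 0] == "0") | (col[:, 1] == "0")
        codes[:, j] = (col[:, 0] == counted).astype(np.int8) + (
            col[:, 1] == counted
        ).astype(np.int8)
        codes[missing, j] = MISSING
        a1_out.append(counted)
        a2_out.append(other if other != counted else counted)
    markers = pd.DataFrame(
        {
            "name": mk["name"],
            "chrom": mk["chrom"].astype(str),
            "pos_bp": mk["pos_bp"].astype(int),
            "allele1": a1_out,
            "allele2": a2_out,
        }
    )
    return GenotypeMatrix(codes=codes, animal_ids=ids, markers=markers)


# -- flat tables ---------------------------------------------------------

def write_phenotypes(phen: pd.DataFrame, path: str):
    phen[["animal_id", "age_days", "year_season"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"animal_id": str, "year_season": str})


def write_pedigree(ped: Pedigree, path: str):
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path: str) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    return Pedigree.from_frame(df)


def write_truthset(truth, path: str):
    pd.DataFrame(
        {
            "snp_index": np.arange(truth.true_effects.size),
            "true_effect": truth.true_effects,
            "included": truth.true_included.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


# -- BED (0-based half-open) ---------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str):
    """Write candidate intervals (1-based inclusive) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['interval_start_bp']) - 1}\t"
                f"{int(row['interval_end_bp'])}\t{row.get('name', row.get('window_id', '.'))}\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end0", "name"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "interval_start_bp": df["start0"] + 1,
            "interval_end_bp": df["end0"],
            "name": df["name"],
        }
    )
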