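"""Candidate intervals, QTL-region grouping and end-to-end pipeline.

``run_pipeline`` executes the whole analysis from a config mapping (or
YAML file): simulate or load genotypes/phenotypes/pedigree -> QC ->
optional pedigree REML priors -> BayesC-pi (estimate pi) -> BayesC with
pi fixed -> 5-SNP window scan -> putative-QTL selection -> parametric
bootstrap -> PFP -> LD around significant windows -> candidate
intervals.  Every stage writes a TSV (or BED) into the output directory
and the run is summarised in a JSON metadata record with the seeds and
thresholds in effect.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .bayesc import McmcConfig, estimate_pi, marker_h2, run_mcmc, year_season_design
from .bootstrap import bootstrap_window_test, pfp_adjust
from .ld import pairwise_r2
from .pedigree import build_amatrix, reml_fit, variance_priors
from .qc import (
    QcError,
    encode_center_impute,
    filter_animals,
    filter_snps,
    mendel_check,
)
from .simulate import (
    SimConfig,
    inject_missingness,
    simulate_genotypes,
    simulate_pedigree_genotypes,
    simulate_phenotypes,
)
from .windows import build_windows, select_putative_qtl, window_variance


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def candidate_intervals(windows: pd.DataFrame, flank_bp: int = 300_000) -> pd.DataFrame:
    """Extend each significant window by ``flank_bp`` on both sides, clipped at 1.

    Input needs columns chrom, start_bp, end_bp (and optionally window_id);
    output carries interval_start_bp / interval_end_bp in 1-based
    inclusive coordinates for downstream gene annotation.
    """
    out = windows.copy()
    out["interval_start_bp"] = np.maximum(1, out["start_bp"].astype(int) - flank_bp)
    out["interval_end_bp"] = out["end_bp"].astype(int) + flank_bp
    out["flank_bp"] = flank_bp
    return out


def merge_adjacent(windows: pd.DataFrame, max_gap_bp: int = 1_000_000) -> pd.DataFrame:
    """Group same-chromosome windows whose spans lie within ``max_gap_bp``.

    Distance is edge-to-edge (gap between one window's end and the next
    window's start).  Returns one row per region with its span and member
    window ids.
    """
    if windows.empty:
        return pd.DataFrame(
            columns=["region_id", "chrom", "start_bp", "end_bp", "n_windows", "members"]
        )
    df = windows.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    regions = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start_bp")
        cur = None
        for _, row in grp.iterrows():
            if cur is not None and row["start_bp"] - cur["end_bp"] <= max_gap_bp:
                cur["end_bp"] = max(cur["end_bp"], int(row["end_bp"]))
                cur["members"].append(row.get("window_id", len(cur["members"])))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": str(chrom),
                    "start_bp": int(row["start_bp"]),
                    "end_bp": int(row["end_bp"]),
                    "members": [row.get("window_id", 0)],
                }
        regions.append(cur)
    return pd.DataFrame(
        {
            "region_id": range(len(regions)),
            "chrom": [r["chrom"] for r in regions],
            "start_bp": [r["start_bp"] for r in regions],
            "end_bp": [r["end_bp"] for r in regions],
            "n_windows": [len(r["members"]) for r in regions],
            "members": [",".join(str(m) for m in r["members"]) for r in regions],
        }
    )


def manhattan_plot(window_results: pd.DataFrame, path: str):
    """Basic per-window genetic-variance plot along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .windows import chrom_sort_key

    df = window_results.copy()
    df["_key"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_key", "start_bp"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
        ax.scatter(grp.index, grp["gv_pct"], s=6, label=None,
                   color="C0" if i % 2 == 0 else "C1")
    ax.set_xlabel("5-SNP window (genome order)")
    ax.set_ylabel("% of genetic variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _sim_config_from(cfg: dict, seed: int) -> SimConfig:
    kwargs = dict(cfg)
    plan = kwargs.pop("chromosome_plan", None)
    if plan is not None:
        kwargs["chromosome_plan"] = [
            (str(c), int(n), int(length)) for c, n, length in plan
        ]
    kwargs.setdefault("seed", seed)
    return SimConfig(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config, out_dir: str, seed: int | None = None) -> dict:
    """Run the full analysis; returns a dict of in-memory results.

    ``config`` is a mapping or a path to a YAML file.  ``seed`` overrides
    the config seed.  Partial outputs are retained on failure; the error
    names the failing stage.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    rng_seeds = {
        "simulate": seed,
        "mcmc_pi": seed + 11,
        "mcmc": seed + 13,
        "bootstrap": seed + 17,
    }
    meta = {
        "seed": seed,
        "stage_seeds": rng_seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    results: dict = {}

    def done(stage, **info):
        meta["stages"].append({"name": stage, **info})
        _write_meta(out, meta)

    # ---- inputs ----------------------------------------------------------
    geno, phen, ped, truth = _stage("input")(_load_inputs)(cfg, rng_seeds, out)
    results.update(genotypes=geno, phenotypes=phen, pedigree=ped, truth=truth)
    done("input", n_animals=geno.n_animals, n_markers=geno.n_markers)

    # ---- QC --------------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    geno, phen, qc_frames = _stage("qc")(_run_qc)(geno, phen, ped, qc_cfg)
    pd.concat(qc_frames).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    gio.write_ped_map(geno, str(out / "qc"), phen=phen)
    results["genotypes_qc"] = geno
    done("qc", n_animals=geno.n_animals, n_markers=geno.n_markers, **qc_cfg)

    Z, col_means = encode_center_impute(geno)
    phen = phen.set_index("animal_id").loc[[str(a) for a in geno.animal_ids]].reset_index()
    y = phen["age_days"].to_numpy(float)
    X = year_season_design(phen)

    # ---- REML priors -----------------------------------------------------
    mcmc_cfg = dict(cfg.get("mcmc", {}))
    priors = None
    if ped is not None and cfg.get("reml", {}).get("enabled", True):
        def _reml():
            A = build_amatrix(ped)
            vc = reml_fit(phen, A)
            mean_het = float((Z**2).mean())
            pi0 = float(mcmc_cfg.get("pi", 0.9935))
            pr = variance_priors(vc, geno.n_markers, pi0, mean_het)
            return vc, pr

        vc, priors = _stage("reml")(_reml)()
        pd.DataFrame(
            [
                {
                    "sigma2_a": vc.sigma2_a,
                    "sigma2_e": vc.sigma2_e,
                    "h2": vc.h2,
                    "se_h2": vc.se_h2,
                    "n_iter": vc.n_iter,
                }
            ]
        ).to_csv(out / "varcomp.tsv", sep="\t", index=False)
        results["variance_components"] = vc
        done("reml", h2=vc.h2)

    # ---- BayesC-pi then BayesC ------------------------------------------
    base = McmcConfig(
        n_iter=int(mcmc_cfg.get("n_iter", 4000)),
        burn_in=int(mcmc_cfg.get("burn_in", 1000)),
        thin=int(mcmc_cfg.get("thin", 1)),
        pi=float(mcmc_cfg.get("pi", 0.9935)),
        seed=rng_seeds["mcmc_pi"],
    )
    if priors is not None:
        base = base.with_priors(priors)
    if mcmc_cfg.get("estimate_pi", True):
        pi_hat, pi_summary = _stage("pi")(estimate_pi)(y, X, Z, base, markers=geno.markers)
        results["pi_estimate"] = pi_hat
        pd.DataFrame({"pi": pi_summary.chains["pi"]}).to_csv(
            out / "pi_chain.csv", index=False
        )
        done("pi", pi=pi_hat)
    else:
        pi_hat = base.pi

    from dataclasses import replace

    fit_cfg = replace(base, pi=min(max(pi_hat, 1e-6), 1 - 1e-6),
                      estimate_pi=False, seed=rng_seeds["mcmc"])
    summary = _stage("gwas")(run_mcmc)(y, X, Z, fit_cfg, markers=geno.markers)
    summary.effects_frame().to_csv(out / "snp_effects.tsv", sep="\t", index=False)
    pd.DataFrame(summary.chains).to_csv(out / "chains.csv", index=False)
    results["posterior"] = summary
    results["h2_marker"] = marker_h2(summary)
    done("gwas", h2_marker=results["h2_marker"], pi_used=fit_cfg.pi)

    # ---- windows ---------------------------------------------------------
    wmode = cfg.get("windows", {}).get("mode", "non_overlapping")
    windows = _stage("windows")(build_windows)(geno.markers, mode=wmode)
    wres = _stage("windows")(window_variance)(summary.u_mean, Z, windows)
    wres.to_csv(out / "windows.tsv", sep="\t", index=False)
    qtl = select_putative_qtl(wres, geno.n_markers, fit_cfg.pi)
    qtl.to_csv(out / "putative_qtl.tsv", sep="\t", index=False)
    results["window_results"] = wres
    results["putative_qtl"] = qtl
    done("windows", n_windows=len(windows), n_putative=len(qtl))
    if cfg.get("report", {}).get("plot", False):
        manhattan_plot(wres, str(out / "windows.png"))

    # ---- bootstrap -------------------------------------------------------
    bs_cfg = cfg.get("bootstrap", {})
    B = int(bs_cfg.get("B", 99))
    n_test = min(int(bs_cfg.get("n_windows", 3)), len(qtl))
    alpha = float(bs_cfg.get("alpha", 0.05))
    rep_cfg = replace(
        fit_cfg,
        n_iter=int(bs_cfg.get("n_iter", max(fit_cfg.n_iter // 4, 400))),
        burn_in=int(bs_cfg.get("burn_in", max(fit_cfg.burn_in // 4, 100))),
    )
    win_by_id = {w.window_id: w for w in windows}
    boot_rows = []
    sig_windows = []
    for i in range(n_test):
        row = qtl.iloc[i]
        w = win_by_id[int(row["window_id"])]
        res = _stage("bootstrap")(bootstrap_window_test)(
            summary, X, Z, w, float(row["gv"]), B, rep_cfg,
            seed=rng_seeds["bootstrap"] + 1000 * i,
        )
        boot_rows.append(
            {
                "window_id": w.window_id,
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "observed_gv": res.observed_gv,
                "B": B,
                "k": res.exceed_count,
                "p_lower": res.p_lower,
                "p_upper": res.p_upper,
                "minus_log10_p_upper": -np.log10(res.p_upper),
                "significant": res.significant_at(alpha),
            }
        )
        if res.significant_at(alpha):
            sig_windows.append(row)
    boot = pd.DataFrame(boot_rows)
    boot.to_csv(out / "bootstrap.tsv", sep="\t", index=False)
    results["bootstrap"] = boot
    done("bootstrap", B=B, n_tested=n_test, n_significant=len(sig_windows))

    # ---- PFP -------------------------------------------------------------
    pfp_cfg = cfg.get("pfp", {})
    if len(boot):
        pfp = pfp_adjust(
            boot["p_upper"].to_numpy(),
            pi0=float(pfp_cfg.get("pi0", 0.95)),
            power=float(pfp_cfg.get("power", 0.8)),
        )
        results["pfp"] = pfp
        done("pfp", pfp=pfp)

    # ---- LD and intervals ------------------------------------------------
    sig = pd.DataFrame(sig_windows) if sig_windows else qtl.head(0)
    flank = int(cfg.get("report", {}).get("flank_bp", 300_000))
    if len(sig) and cfg.get("ld", {}).get("enabled", True):
        ld_frames = []
        for _, row in sig.iterrows():
            ld_frames.append(
                _stage("ld")(pairwise_r2)(
                    geno,
                    region=(row["chrom"], int(row["start_bp"]) - flank,
                            int(row["end_bp"]) + flank),
                    method=cfg.get("ld", {}).get("method", "em"),
                )
            )
        ld = pd.concat(ld_frames, ignore_index=True)
        ld.to_csv(out / "ld.tsv", sep="\t", index=False)
        results["ld"] = ld
        done("ld", n_pairs=len(ld))

    intervals = candidate_intervals(
        sig if len(sig) else qtl.head(0), flank_bp=flank
    )
    gio.write_bed(
        intervals.assign(name=lambda d: "win" + d["window_id"].astype(str))
        if len(intervals)
        else intervals.assign(name=[]),
        str(out / "intervals.bed"),
    )
    regions = merge_adjacent(sig, max_gap_bp=int(cfg.get("report", {}).get(
        "merge_gap_bp", 1_000_000)))
    regions.to_csv(out / "regions.tsv", sep="\t", index=False)
    results["intervals"] = intervals
    results["regions"] = regions
    done("report", n_significant=len(sig), n_regions=len(regions))
    return results


def _write_meta(out: Path, meta: dict):
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _load_inputs(cfg, rng_seeds, out: Path):
    truth = None
    ped = None
    if "simulate" in cfg:
        sim = _sim_config_from(cfg["simulate"], rng_seeds["simulate"])
        with_ped = cfg.get("simulate_pedigree", True)
        if with_ped:
            ped, geno_full = simulate_pedigree_genotypes(
                sim,
                n_sires=int(cfg.get("n_sires", 37)),
                n_dams=int(cfg.get("n_dams", 380)),
            )
            # phenotype only the offspring generation
            n_parents = len(ped) - sim.n_animals
            geno_off = geno_full.subset(
                animals=np.arange(n_parents, len(ped))
            )
            phen, truth = simulate_phenotypes(geno_off, sim)
            geno = geno_full
        else:
            geno = simulate_genotypes(sim)
            phen, truth = simulate_phenotypes(geno, sim)
        if sim.missing_rate > 0:
            geno = inject_missingness(geno, sim)
        gio.write_ped_map(geno, str(out / "sim"), phen=phen)
        gio.write_phenotypes(phen, str(out / "phenotypes.tsv"))
        if ped is not None:
            gio.write_pedigree(ped, str(out / "pedigree.csv"))
        if truth is not None:
            gio.write_truthset(truth, str(out / "truth.tsv"))
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        geno = gio.read_ped_map(inp["ped_prefix"])
        phen = gio.read_phenotypes(inp["phenotypes"])
        ped = gio.read_pedigree(inp["pedigree"]) if "pedigree" in inp else None
    else:
        raise PipelineError("config needs a 'simulate' or 'inputs' section")
    return geno, phen, ped, truth


def _run_qc(geno, phen, ped, qc_cfg):
    frames = []
    geno, rep = filter_snps(
        geno,
        min_call_rate=float(qc_cfg.get("min_call_rate", 0.95)),
        min_maf=float(qc_cfg.get("min_maf", 0.05)),
    )
    frames.append(rep.to_frame())
    geno, rep = filter_animals(geno, max_missing=float(qc_cfg.get("max_missing", 0.05)))
    frames.append(rep.to_frame())
    if ped is not None:
        failing, rep = mendel_check(
            geno, ped, max_error_rate=float(qc_cfg.get("mendel_max_error_rate", 0.01))
        )
        frames.append(rep.to_frame())
        if failing:
            keep = [i for i, a in enumerate(geno.animal_ids) if a not in set(failing)]
            geno = geno.subset(animals=keep)
    # keep only phenotyped & genotyped animals, in genotype order
    phen_ids = set(phen["animal_id"].astype(str))
    keep = [i for i, a in enumerate(geno.animal_ids) if str(a) in phen_ids]
    if not keep:
        raise QcError("no genotyped animal has a phenotype")
    geno = geno.subset(animals=keep)
    phen = (
        phen.set_index(phen["animal_id"].astype(str))
        .loc[[str(a) for a in geno.animal_ids]]
        .reset_index(drop=True)
    )
    return geno, phen, frames
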