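"""Synthetic-data generator: marginals, LD, transmission, truth bookkeeping."""

import numpy as np
import pytest

from giltgwas.qc import MISSING, mendel_check
from giltgwas.simulate import (
    SimConfig,
    TruthSet,
    inject_missingness,
    simulate_genotypes,
    simulate_pedigree_genotypes,
    simulate_phenotypes,
)


def small_cfg(**kw):
    base = dict(
        n_animals=200,
        chromosome_plan=[("1", 25, 10_000_000), ("2", 25, 10_000_000)],
        pi_true=0.9,
        sigma2_u_true=1.0,
        sigma2_e_true=10.0,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenotypes:
    def test_codes_and_positions(self):
        g = simulate_genotypes(small_cfg())
        assert set(np.unique(g.codes)) <= {0, 1, 2}
        for _, grp in g.markers.groupby("chrom"):
            assert (np.diff(grp["pos_bp"]) > 0).all()

    def test_maf_within_configured_range(self):
        # recompute frequencies from the emitted matrix; allow binomial error
        cfg = small_cfg(
            n_animals=500,
            chromosome_plan=[("1", 500, 50_000_000), ("2", 500, 50_000_000)],
            maf_range=(0.05, 0.5),
            seed=4,
        )
        g = simulate_genotypes(cfg)
        maf = g.maf()
        eps = 3 * np.sqrt(0.05 * 0.95 / (2 * cfg.n_animals))
        assert maf.min() >= 0.05 - eps
        assert maf.max() <= 0.5

    def test_independent_loci_baseline_r2(self):
        # with ld_rho = 0 the mean adjacent-SNP r^2 is ~1/n (finite-sample bias)
        cfg = small_cfg(
            n_animals=400, chromosome_plan=[("1", 200, 50_000_000)], ld_rho=0.0, seed=2
        )
        g = simulate_genotypes(cfg)
        x = g.codes.astype(float)
        r2 = [
            np.corrcoef(x[:, j], x[:, j + 1])[0, 1] ** 2 for j in range(199)
        ]
        assert np.mean(r2) == pytest.approx(1 / cfg.n_animals, rel=0.5)

    def test_near_duplication_at_high_rho(self):
        cfg = small_cfg(
            n_animals=300,
            chromosome_plan=[("1", 5, 1_000_000)],
            maf_range=(0.3, 0.3),  # equal frequencies so copying implies identity
            ld_rho=0.999,
            seed=3,
        )
        g = simulate_genotypes(cfg)
        x = g.codes.astype(float)
        r2 = np.corrcoef(x[:, 0], x[:, 1])[0, 1] ** 2
        # thresholding the latent AR(1) attenuates the allelic correlation
        # slightly below ld_rho, so "near copies" rather than exact duplicates
        assert r2 > 0.9

    def test_seed_determinism(self):
        a = simulate_genotypes(small_cfg())
        b = simulate_genotypes(small_cfg())
        assert np.array_equal(a.codes, b.codes)
        assert a.markers.equals(b.markers)

    def test_rejects_degenerate_config(self):
        with pytest.raises(ValueError):
            small_cfg(n_animals=1)
        with pytest.raises(ValueError):
            small_cfg(chromosome_plan=[])
        with pytest.raises(ValueError):
            small_cfg(chromosome_plan=[("1", 3, 1000)])  # < 5 SNPs


class TestPedigreeGenotypes:
    def test_faithful_transmission_no_conflicts(self):
        cfg = small_cfg(mendel_error_rate=0.0, n_animals=100, seed=7)
        ped, geno = simulate_pedigree_genotypes(cfg, n_sires=5, n_dams=20)
        failing, rep = mendel_check(geno, ped, max_error_rate=0.0)
        assert failing == []
        # direct recount: no opposing homozygotes offspring vs true parents
        idx = {a: i for i, a in enumerate(geno.animal_ids)}
        for child, sire, dam in ped.records():
            if sire is None:
                continue
            go = geno.codes[idx[child]]
            for p in (sire, dam):
                gp = geno.codes[idx[p]]
                assert not (((go == 0) & (gp == 2)) | ((go == 2) & (gp == 0))).any()

    def test_fixed_cross_homozygous_parents(self):
        cfg = small_cfg(n_animals=50, seed=8)
        ped, geno = simulate_pedigree_genotypes(cfg, n_sires=3, n_dams=10)
        idx = {a: i for i, a in enumerate(geno.animal_ids)}
        for child, sire, dam in ped.records():
            if sire is None:
                continue
            both2 = (geno.codes[idx[sire]] == 2) & (geno.codes[idx[dam]] == 2)
            assert (geno.codes[idx[child]][both2] == 2).all()

    def test_corruption_rate_matches_nominal(self):
        # brute-force count of changed calls across offspring trios
        rate = 0.02
        cfg_clean = small_cfg(
            n_animals=60,
            chromosome_plan=[("1", 2500, 100_000_000), ("2", 2500, 100_000_000)],
            mendel_error_rate=0.0,
            seed=12,
        )
        cfg_err = small_cfg(
            n_animals=60,
            chromosome_plan=[("1", 2500, 100_000_000), ("2", 2500, 100_000_000)],
            mendel_error_rate=rate,
            seed=12,
        )
        _, clean = simulate_pedigree_genotypes(cfg_clean, n_sires=4, n_dams=15)
        ped, dirty = simulate_pedigree_genotypes(cfg_err, n_sires=4, n_dams=15)
        n_off, m = 60, 5000
        changed = (clean.codes[-n_off:] != dirty.codes[-n_off:]).mean()
        sd = np.sqrt(rate * (1 - rate) / (n_off * m))
        assert abs(changed - rate) < 3 * sd
        # corrupted trios now show conflicts the parentage test can catch
        failing, _ = mendel_check(dirty, ped, max_error_rate=0.001)
        assert len(failing) > 0

    def test_parent_input_guard(self):
        with pytest.raises(ValueError):
            simulate_pedigree_genotypes(small_cfg(), n_sires=0, n_dams=5)


class TestPhenotypes:
    def test_no_signal_limit(self):
        cfg = small_cfg(sigma2_u_true=0.0)
        g = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(g, cfg)
        assert truth.true_h2_marker == 0.0
        assert (truth.true_effects == 0).all()

    def test_expected_nonzero_count(self):
        # sparse architecture: E[#included] = m * (1 - pi)
        cfg = small_cfg(
            n_animals=50,
            chromosome_plan=[("1", 2000, 100_000_000), ("2", 2000, 100_000_000)],
            pi_true=0.9935,
            seed=21,
        )
        g = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(g, cfg)
        m = cfg.n_markers
        expect = m * (1 - cfg.pi_true)
        sd = np.sqrt(m * (1 - cfg.pi_true) * cfg.pi_true)
        assert abs(truth.true_included.sum() - expect) < 4 * sd

    def test_variance_fraction_recomputed_from_truth(self):
        cfg = small_cfg(
            n_animals=200,
            chromosome_plan=[("1", 250, 50_000_000), ("2", 250, 50_000_000)],
            pi_true=0.95,
            sigma2_u_true=1.0,
            sigma2_e_true=10.0,
            seed=5,
        )
        g = simulate_genotypes(cfg)
        phen, truth = simulate_phenotypes(g, cfg)
        Zc = g.codes.astype(float)
        Zc -= Zc.mean(axis=0)
        gval = Zc @ truth.true_effects
        y = phen["age_days"].to_numpy()
        assert truth.true_h2_marker == pytest.approx(
            np.var(gval, ddof=1) / np.var(y, ddof=1), rel=1e-10
        )

    def test_variance_bookkeeping_large_n(self):
        # var(Zu) -> sum_j 2 p_j q_j u_j^2 as n grows
        cfg = small_cfg(
            n_animals=10_000,
            chromosome_plan=[("1", 50, 10_000_000)],
            pi_true=0.5,
            sigma2_u_true=1.0,
            seed=6,
        )
        g = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(g, cfg)
        p = g.allele_freq()
        expected = float(np.sum(2 * p * (1 - p) * truth.true_effects**2))
        Zc = g.codes.astype(float)
        Zc -= Zc.mean(axis=0)
        observed = float(np.var(Zc @ truth.true_effects, ddof=1))
        assert observed == pytest.approx(expected, rel=0.05)

    def test_rejects_missing_genotypes(self):
        cfg = small_cfg(missing_rate=0.2)
        g = inject_missingness(simulate_genotypes(cfg), cfg)
        with pytest.raises(ValueError, match="missing"):
            simulate_phenotypes(g, cfg)

    def test_truthset_consistency_guard(self):
        with pytest.raises(ValueError):
            TruthSet(
                true_effects=np.array([1.0, 0.0]),
                true_included=np.array([False, False]),
                true_class_effects={},
                true_h2_marker=0.0,
                true_window_gv=None,
            )


class TestMissingness:
    def test_zero_rate_is_identity(self):
        cfg = small_cfg(missing_rate=0.0)
        g = simulate_genotypes(cfg)
        g2 = inject_missingness(g, cfg)
        assert np.array_equal(g.codes, g2.codes)

    def test_realized_rate(self):
        cfg = small_cfg(missing_rate=0.5, seed=9)
        g = simulate_genotypes(cfg)
        g2 = inject_missingness(g, cfg)
        frac = (g2.codes == MISSING).mean()
        sd = np.sqrt(0.25 / g.codes.size)
        assert abs(frac - 0.5) < 3 * sd

    def test_fully_missing_column_call_rate(self):
        cfg = small_cfg()
        g = simulate_genotypes(cfg)
        g.codes[:, 3] = MISSING
        assert g.call_rate()[3] == 0.0
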