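"""QC filters, Mendelian test, encoding and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from giltgwas.pedigree import Pedigree, PedigreeCycleError
from giltgwas.qc import (
    MISSING,
    GenotypeMatrix,
    QcError,
    encode_center_impute,
    filter_animals,
    filter_snps,
    genotype_pca,
    mendel_check,
    validate_phenotypes,
)

from conftest import make_geno, make_markers


class TestFilterSnps:
    def test_call_rate_boundary_is_strict(self, rng):
        # 40 animals: 2 missing = call rate exactly 0.95 (kept); 3 = 0.925 (dropped)
        codes = rng.integers(0, 2, size=(40, 3)).astype(np.int8) + rng.integers(
            0, 2, size=(40, 3)
        ).astype(np.int8)
        codes[:2, 1] = MISSING
        codes[:3, 2] = MISSING
        g = make_geno(codes)
        kept, rep = filter_snps(g, min_call_rate=0.95, min_maf=0.0)
        assert kept.markers["name"].tolist() == ["SNP1", "SNP2"]
        assert rep.removed["call_rate"] == 1

    def test_maf_boundary_is_strict(self):
        # 500 animals: 49 het copies -> MAF 0.049 (dropped); 50 -> 0.05 (kept)
        codes = np.zeros((500, 2), dtype=np.int8)
        codes[:49, 0] = 1
        codes[:50, 1] = 1
        g = make_geno(codes)
        kept, rep = filter_snps(g, min_call_rate=0.0, min_maf=0.05)
        assert kept.markers["name"].tolist() == ["SNP2"]
        assert rep.removed["maf"] == 1

    def test_toy_matrix_survivor_count(self, rng):
        # 10 SNPs: 2 on Y, 1 unknown chromosome, 1 low-MAF -> 6 survive
        codes = rng.integers(0, 2, size=(60, 10)).astype(np.int8) + rng.integers(
            0, 2, size=(60, 10)
        ).astype(np.int8)
        codes[:, 2] = 0
        codes[0, 2] = 1  # MAF 1/120 < 0.05
        g = make_geno(codes, chroms=[("1", 5), ("0", 1), ("Y", 2), ("2", 2)])
        kept, rep = filter_snps(g)
        assert kept.n_markers == 6
        assert rep.removed["y_chromosome"] == 2
        assert rep.removed["unknown_chromosome"] == 1
        assert rep.removed["maf"] == 1

    def test_all_removed_is_error(self):
        codes = np.zeros((10, 2), dtype=np.int8)  # monomorphic, MAF 0
        with pytest.raises(QcError):
            filter_snps(make_geno(codes))

    def test_report_conservation_and_idempotence(self, toy_geno):
        kept, rep = filter_snps(toy_geno, min_call_rate=0.9, min_maf=0.05)
        assert rep.n_removed + rep.n_retained == toy_geno.n_markers
        again, rep2 = filter_snps(kept, min_call_rate=0.9, min_maf=0.05)
        assert rep2.n_removed == 0
        assert np.array_equal(kept.codes, again.codes)


class TestFilterAnimals:
    def test_boundary_and_hand_count(self):
        # 4 animals x 20 SNPs with 0, 1 (=5%), 2 (=10%), 20 missing calls
        codes = np.ones((4, 20), dtype=np.int8)
        codes[1, :1] = MISSING
        codes[2, :2] = MISSING
        codes[3, :] = MISSING
        g = make_geno(codes)
        kept, rep = filter_animals(g, max_missing=0.05)
        assert kept.animal_ids == ["A1", "A2"]  # exactly 5% retained (strict >)
        assert rep.removed["missing_rate"] == 2
        assert rep.n_removed + rep.n_retained == 4

    def test_idempotence(self, toy_geno):
        toy_geno.codes[0, :15] = MISSING
        kept, _ = filter_animals(toy_geno, max_missing=0.5)
        again, rep2 = filter_animals(kept, max_missing=0.5)
        assert rep2.n_removed == 0


class TestMendelCheck:
    def trio(self, g_off, g_sire, m=100):
        codes = np.ones((3, m), dtype=np.int8)
        codes[0] = g_sire
        codes[2] = g_off
        geno = make_geno(codes)
        ped = Pedigree(ids=["A1", "A2", "A3"], sires=[None, None, "A1"],
                       dams=[None, None, "A2"])
        return geno, ped

    def test_opposing_homozygote_is_conflict(self):
        g_off = np.ones(100, dtype=np.int8)
        g_off[0] = 0
        g_sire = np.ones(100, dtype=np.int8)
        g_sire[0] = 2
        geno, ped = self.trio(g_off, g_sire)
        failing, _ = mendel_check(geno, ped, max_error_rate=0.0)
        assert failing == ["A3"]

    def test_heterozygote_never_conflicts(self):
        g_off = np.ones(100, dtype=np.int8)  # all het
        for sire_code in (0, 1, 2):
            geno, ped = self.trio(g_off, np.full(100, sire_code, dtype=np.int8))
            failing, _ = mendel_check(geno, ped, max_error_rate=0.0)
            assert failing == []

    def test_error_rate_threshold(self):
        # conflicts against the sire only; dam all-het contributes compared loci
        g_sire = np.ones(100, dtype=np.int8)
        g_off = np.ones(100, dtype=np.int8)
        g_sire[:2] = 2
        g_off[:2] = 0  # 2 conflicts / 200 compared = 0.01 -> passes (strict >)
        geno, ped = self.trio(g_off, g_sire)
        failing, _ = mendel_check(geno, ped, max_error_rate=0.01)
        assert failing == []
        g_sire[:3] = 2
        g_off[:3] = 0  # 3/200 = 0.015 -> fails
        geno, ped = self.trio(g_off, g_sire)
        failing, _ = mendel_check(geno, ped, max_error_rate=0.01)
        assert failing == ["A3"]

    def test_pedigree_cycle_detected(self, toy_geno):
        ped = Pedigree(ids=["A1", "A2"], sires=["A2", "A1"], dams=[None, None])
        with pytest.raises(PedigreeCycleError):
            mendel_check(toy_geno, ped)


class TestEncodeCenterImpute:
    def test_missing_imputed_to_column_mean(self):
        codes = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
        Z, means = encode_center_impute(make_geno(codes))
        assert means[0] == 1.0
        np.testing.assert_allclose(Z[:, 0], [-1, 0, 1, 0])

    def test_fully_observed_is_identity_after_centering(self, rng):
        codes = rng.integers(0, 3, size=(8, 4)).astype(np.int8)
        Z, means = encode_center_impute(make_geno(codes))
        np.testing.assert_allclose(Z, codes - codes.mean(axis=0), atol=1e-12)

    def test_output_columns_centered(self, rng):
        codes = rng.integers(0, 3, size=(5, 3)).astype(np.int8)
        codes[0, 1] = MISSING
        Z, _ = encode_center_impute(make_geno(codes))
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)

    def test_empty_column_is_error(self):
        codes = np.ones((4, 2), dtype=np.int8)
        codes[:, 1] = MISSING
        with pytest.raises(QcError):
            encode_center_impute(make_geno(codes))


class TestGenotypePca:
    def test_identical_animals_identical_scores(self, rng):
        codes = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
        codes[3] = codes[1]
        scores, _ = genotype_pca(make_geno(codes), k=2)
        np.testing.assert_allclose(scores[3], scores[1], atol=1e-9)

    def test_contract_k_columns_and_ordering(self, rng):
        codes = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
        scores, ev = genotype_pca(make_geno(codes), k=3)
        assert scores.shape == (10, 3)
        assert (np.diff(ev) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self, rng):
        codes = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        g = make_geno(codes)
        scores, ev = genotype_pca(g, k=3)
        Z, _ = encode_center_impute(g)
        C = Z @ Z.T / (6 - 1)
        w, V = np.linalg.eigh(C)
        w, V = w[::-1], V[:, ::-1]
        np.testing.assert_allclose(ev, w[:3], atol=1e-9)
        for j in range(3):  # eigenvector sign is arbitrary
            expected = V[:, j] * np.sqrt(w[j] * (6 - 1))
            assert np.allclose(scores[:, j], expected, atol=1e-8) or np.allclose(
                scores[:, j], -expected, atol=1e-8
            )

    def test_k_bounds(self, toy_geno):
        with pytest.raises(QcError):
            genotype_pca(toy_geno, k=0)
        with pytest.raises(QcError):
            genotype_pca(toy_geno, k=min(toy_geno.codes.shape) + 1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    data=st.lists(
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=6, max_size=6),
        min_size=4,
        max_size=12,
    )
)
def test_maf_folding_invariant(data):
    """MAF is unchanged when the counted allele is flipped (codes -> 2 - codes)."""
    codes = np.array(data, dtype=np.int8)
    g = make_geno(codes)
    flipped = np.where(codes == MISSING, MISSING, 2 - codes).astype(np.int8)
    g2 = make_geno(flipped)
    np.testing.assert_allclose(g.maf(), g2.maf(), atol=1e-12, equal_nan=True)
    assert np.nanmax(np.append(g.maf(), 0)) <= 0.5 + 1e-12


class TestGenotypeMatrixValidation:
    def test_rejects_bad_codes(self):
        with pytest.raises(QcError):
            make_geno(np.array([[0, 3]], dtype=np.int8))

    def test_rejects_nonincreasing_positions(self):
        mk = make_markers(2)
        mk.loc[1, "pos_bp"] = mk.loc[0, "pos_bp"]
        with pytest.raises(QcError):
            GenotypeMatrix(
                codes=np.zeros((2, 2), dtype=np.int8), animal_ids=["a", "b"], markers=mk
            )


class TestPhenotypeValidation:
    def test_accepts_plausible_table(self):
        df = pd.DataFrame(
            {"animal_id": ["a"], "age_days": [200.0], "year_season": ["Y05S1"]}
        )
        out = validate_phenotypes(df)
        assert list(out.columns) == ["animal_id", "age_days", "year_season"]

    def test_rejects_out_of_range_age_and_empty_class(self):
        df = pd.DataFrame(
            {"animal_id": ["a"], "age_days": [300.0], "year_season": ["Y"]}
        )
        with pytest.raises(QcError):
            validate_phenotypes(df)
        df2 = pd.DataFrame(
            {"animal_id": ["a"], "age_days": [200.0], "year_season": [""]}
        )
        with pytest.raises(QcError):
            validate_phenotypes(df2)
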