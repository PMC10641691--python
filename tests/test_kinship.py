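"""Relationship matrices: pedigree A/A-inverse/D, genomic G_A/G_D and the
single-step H blend, against hand calculations and dense-algebra oracles."""

import numpy as np
import pytest

from rrsgs import (
    KinshipMatrix,
    MarkerMatrix,
    Pedigree,
    SimulationConfig,
    build_A,
    build_A_inverse,
    build_D_pedigree,
    build_GA,
    build_GD,
    build_H,
    build_H_inverse,
    filter_markers,
    simulate_breeding_program,
    simulate_founder_genotypes,
)
from rrsgs.kinship import KinshipError


def random_pedigree(n, seed, n_founders=10):
    """Random multi-generation pedigree (parents always precede offspring)."""
    rng = np.random.default_rng(seed)
    ids = [f"x{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k < n_founders:
            sires.append(None)
            dams.append(None)
        else:
            s, d = rng.choice(k, size=2, replace=False)
            sires.append(ids[s])
            dams.append(ids[d])
    return Pedigree(ids, sires, dams)


class TestPedigreeA:
    def test_founders_only_identity(self):
        ped = Pedigree(list("abc"), [None] * 3, [None] * 3)
        np.testing.assert_array_equal(build_A(ped).values, np.eye(3))

    def test_classical_coefficients(self):
        ped = Pedigree(
            ["p", "q", "o1", "o2", "r", "h"],
            [None, None, "p", "p", None, "p"],
            [None, None, "q", "q", None, "r"],
        )
        A = build_A(ped)
        assert A.loc("p", "o1") == pytest.approx(0.5)  # parent-offspring
        assert A.loc("o1", "o2") == pytest.approx(0.5)  # full sibs
        assert A.loc("o1", "h") == pytest.approx(0.25)  # half sibs

    def test_offspring_of_full_sibs_inbred_diagonal(self):
        ped = Pedigree(
            ["p", "q", "s1", "s2", "x"],
            [None, None, "p", "p", "s1"],
            [None, None, "q", "q", "s2"],
        )
        assert build_A(ped).loc("x", "x") == pytest.approx(1.25)

    def test_symmetric_psd_diag_at_least_one(self):
        A = build_A(random_pedigree(80, 1)).values
        np.testing.assert_allclose(A, A.T)
        assert np.all(np.diag(A) >= 1.0 - 1e-12)
        assert np.linalg.eigvalsh(A).min() > -1e-10


class TestAInverse:
    def test_trio_known_pattern(self):
        ped = Pedigree(["a", "b", "c"], [None, None, "a"], [None, None, "b"])
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(build_A_inverse(ped).values, expected)

    def test_founders_only_identity(self):
        ped = Pedigree(list("ab"), [None] * 2, [None] * 2)
        np.testing.assert_array_equal(build_A_inverse(ped).values, np.eye(2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_product_with_A_is_identity(self, seed):
        ped = random_pedigree(50, seed)
        A = build_A(ped).values
        Ainv = build_A_inverse(ped).values
        assert np.abs(Ainv @ A - np.eye(50)).max() < 1e-8
        # dense numerical inverse as the independent oracle
        np.testing.assert_allclose(Ainv, np.linalg.inv(A), atol=1e-8)


class TestDominanceD:
    def test_full_sibs_quarter_and_parent_offspring_zero(self):
        ped = Pedigree(
            ["p", "q", "o1", "o2"], [None, None, "p", "p"], [None, None, "q", "q"]
        )
        D = build_D_pedigree(ped)
        assert D.loc("o1", "o2") == pytest.approx(0.25)
        assert D.loc("p", "o1") == 0.0
        assert np.all(np.diag(D.values) == 1.0)

    def test_double_first_cousins(self):
        # two sib pairs intermated; offspring x, y are double first cousins
        ped = Pedigree(
            ["a", "b", "c", "d", "s1", "s2", "t1", "t2", "x", "y"],
            [None, None, None, None, "a", "a", "c", "c", "s1", "s2"],
            [None, None, None, None, "b", "b", "d", "d", "t1", "t2"],
        )
        D = build_D_pedigree(ped)
        # d_xy = 1/4 (a_{s1,s2} a_{t1,t2} + a_{s1,t2} a_{t1,s2}) = 1/4 (0.25 + 0)
        assert D.loc("x", "y") == pytest.approx(0.0625)


class TestGenomicMatrices:
    def test_ga_hand_example_single_snp(self):
        m = MarkerMatrix(["i", "j"], ["s"], np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(
            build_GA(m).values, np.array([[2.0, -2.0], [-2.0, 2.0]])
        )

    def test_duplicated_individual_rows(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0.0, 1.0, 2.0], size=(1, 50))
        m = MarkerMatrix(["i", "j", "k"], [f"s{j}" for j in range(50)],
                         np.vstack([d, d, rng.choice([0.0, 1.0, 2.0], size=(1, 50))]))
        m = filter_markers(m, 0.0, 0.01)
        G = build_GA(m)
        assert G.loc("i", "j") == pytest.approx(G.loc("i", "i"))
        assert G.loc("i", "j") == pytest.approx(G.loc("j", "j"))

    def test_ga_mean_diagonal_one_under_hwe(self):
        m, _ = simulate_founder_genotypes(300, 5000, fst=0.0, seed=8)
        m = filter_markers(m, 0.0, 0.01)
        G = build_GA(m)
        assert np.mean(np.diag(G.values)) == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_snp_rejected(self):
        m = MarkerMatrix(["i", "j"], ["s"], np.array([[0.0], [0.0]]))
        with pytest.raises(KinshipError):
            build_GA(m)

    def test_gd_hand_examples(self):
        hom = MarkerMatrix(["i", "j"], ["s"], np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(build_GD(hom).values, np.ones((2, 2)))
        mixed = MarkerMatrix(["i", "j"], ["s"], np.array([[1.0], [0.0]]))
        GD = build_GD(mixed, freqs=np.array([0.5]))
        assert GD.loc("i", "j") == pytest.approx(-1.0)

    def test_gd_mean_diagonal_near_one_under_hwe(self):
        m, _ = simulate_founder_genotypes(300, 5000, fst=0.0, seed=9)
        m = filter_markers(m, 0.0, 0.01)
        GD = build_GD(m)
        assert np.mean(np.diag(GD.values)) == pytest.approx(1.0, abs=0.05)

    def test_ga_estimates_pedigree_expectation(self):
        """On a gene-dropped single-population pedigree the mean G_A - A
        entry tends to zero (no cross-population frequency structure)."""
        from rrsgs import drop_gametes

        founders, freqs = simulate_founder_genotypes(15, 2000, fst=0.0, seed=21)
        ped = random_pedigree(150, seed=21, n_founders=30)
        founders = MarkerMatrix(ped.ids[:30], founders.snp_ids, founders.dosages)
        geno = drop_gametes(ped, founders, seed=22)
        # center with base-population frequencies: G then estimates A
        base_p = freqs.loc[geno.snp_ids, "ancestral"].to_numpy()
        keep = (base_p > 0.01) & (base_p < 0.99)
        G = build_GA(geno.select_snps(keep), freqs=base_p[keep])
        A = build_A(ped).reorder(G.ids)
        assert abs(np.mean(G.values - A.values)) < 0.05


class TestSingleStepH:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = SimulationConfig(
            n_founders_per_species=8, n_snps=400, n_psp_families_per_species=8,
            offspring_per_family=6, n_hybrid_families_g1=4, n_hybrid_families_g2=4,
            n_parents_g2_per_species=3, seed=17,
        )
        prog = simulate_breeding_program(cfg)
        A = build_A(prog.pedigree_true)
        gen_ids = prog.genotypes.ids[::2]  # ~60/40 genotyped mix
        geno = filter_markers(prog.genotypes.select_individuals(gen_ids), 0.0, 0.01)
        GA = build_GA(geno)
        return A, GA, gen_ids

    def test_all_genotyped_degenerates_to_GA(self, setup):
        A, _, _ = setup
        prog_ids = A.ids
        m, _ = simulate_founder_genotypes(len(prog_ids) // 2, 300, 0.1, seed=3)
        m = filter_markers(MarkerMatrix(prog_ids[: m.n_individuals], m.snp_ids, m.dosages), 0.0, 0.01)
        A_sub = A.submatrix(m.ids)
        H = build_H(A_sub, build_GA(m), m.ids)
        np.testing.assert_allclose(
            H.reorder(m.ids).values, build_GA(m).values, atol=1e-12
        )

    def test_GA_equal_A22_recovers_A(self, setup):
        A, _, gen_ids = setup
        A22 = A.submatrix(gen_ids)
        A22 = KinshipMatrix("GA", A22.ids, A22.values)
        H = build_H(A, A22, gen_ids)
        np.testing.assert_allclose(H.values, A.values, atol=1e-10)
        Hinv = build_H_inverse(A, A22, gen_ids, ridge=0.0)
        np.testing.assert_allclose(
            Hinv.values, build_A_inverse_dense(A), atol=1e-8
        )

    def test_block_formula_matches_brute_force(self, setup):
        A, GA, gen_ids = setup
        H = build_H(A, GA, gen_ids)
        np.testing.assert_allclose(H.values, H.values.T)
        ung = [i for i in A.ids if i not in set(gen_ids)]
        iu = [A._index[i] for i in ung]
        ig = [A._index[i] for i in gen_ids]
        A11 = A.values[np.ix_(iu, iu)]
        A12 = A.values[np.ix_(iu, ig)]
        A22i = np.linalg.inv(A.values[np.ix_(ig, ig)])
        G = GA.reorder(gen_ids).values
        H11 = A11 + A12 @ A22i @ (G - A.values[np.ix_(ig, ig)]) @ A22i @ A12.T
        got = H.submatrix(ung).values
        np.testing.assert_allclose(got, H11, atol=1e-10)

    def test_H_inverse_matches_dense_inverse(self, setup):
        A, GA, gen_ids = setup
        ridge = 1e-6
        Hinv = build_H_inverse(A, GA, gen_ids, ridge=ridge)
        GA_r = KinshipMatrix("GA", GA.ids, GA.values + ridge * np.eye(len(GA.ids)))
        H_r = build_H(A, GA_r, gen_ids)
        assert np.abs(Hinv.values - np.linalg.inv(H_r.values)).max() < 1e-6

    def test_tau_zero_gives_A_inverse(self, setup):
        A, GA, gen_ids = setup
        Hinv = build_H_inverse(A, GA, gen_ids, tau=0.0, ridge=1e-6)
        np.testing.assert_allclose(Hinv.values, np.linalg.inv(A.values), atol=1e-8)


def build_A_inverse_dense(A):
    return np.linalg.inv(A.values)
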