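"""REML/BLUP machinery: closed-form oracles, likelihood-grid checks,
model-family equivalences, heritability and de-regression."""

import numpy as np
import pandas as pd
import pytest

from rrsgs import (
    KinshipMatrix,
    MarkerMatrix,
    ModelSpec,
    Pedigree,
    RandomTerm,
    build_A,
    build_GA,
    deregress,
    fit_ablup,
    fit_gblup,
    fit_hblup,
    heritability,
    reml_estimate,
    solve_mme,
)
from rrsgs.evaluation import EvaluationError, ebv_table, genomic_values, reml_loglik


def iid_kinship(ids):
    return KinshipMatrix("A", ids, np.eye(len(ids)))


class TestSolveMME:
    def test_identity_covariance_equals_ridge_regression(self, rng):
        """BLUP with K=I is ridge regression with penalty sigma2_e/sigma2_u."""
        n = 40
        ids = [f"i{k}" for k in range(n)]
        y = rng.normal(size=n)
        s2u, s2e = 0.5, 1.5
        df = pd.DataFrame({"id": ids, "y": y})
        spec = ModelSpec("y", random=(RandomTerm("u", "id", covariance=iid_kinship(ids)),))
        fit = solve_mme(spec, {"u": s2u, "residual": s2e}, df)
        # closed-form ridge oracle with intercept absorbed by GLS
        lam = s2e / s2u
        Z = np.eye(n)
        V = s2u * Z @ Z.T + s2e * np.eye(n)
        ones = np.ones((n, 1))
        b = ((ones.T @ np.linalg.solve(V, y)) / (ones.T @ np.linalg.solve(V, ones))).item()
        u_ridge = np.linalg.solve(Z.T @ Z + lam * np.eye(n), Z.T @ (y - b))
        np.testing.assert_allclose(
            fit.random_effects["u"].loc[ids].to_numpy(), u_ridge, atol=1e-10
        )

    def test_shrinkage_limit_zero_variance(self, rng):
        n = 20
        ids = [f"i{k}" for k in range(n)]
        df = pd.DataFrame({"id": ids, "y": rng.normal(size=n)})
        spec = ModelSpec("y", random=(RandomTerm("u", "id", covariance=iid_kinship(ids)),))
        fit = solve_mme(spec, {"u": 1e-14, "residual": 1.0}, df)
        assert np.abs(fit.random_effects["u"]).max() < 1e-10

    def test_gblup_equals_rrblup_marker_ridge(self, rng):
        """GBLUP with G = WW'/M reproduces RR-BLUP predictions W u-hat."""
        n, m = 50, 100
        X = rng.binomial(2, rng.uniform(0.15, 0.85, m), size=(n, m)).astype(float)
        ids = [f"i{k}" for k in range(n)]
        mm = MarkerMatrix(ids, [f"s{j}" for j in range(m)], X)
        p = mm.allele_freq()
        mm = mm.select_snps((p > 0.01) & (p < 0.99))
        p = mm.allele_freq()
        W = (mm.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
        GA = build_GA(mm)
        y = rng.normal(size=n)
        s2a, s2e = 0.7, 0.3
        df = pd.DataFrame({"id": ids, "y": y})
        spec = ModelSpec("y", random=(RandomTerm("additive", "id", covariance=GA),))
        fit = solve_mme(spec, {"additive": s2a, "residual": s2e}, df)
        V = s2a * GA.values + s2e * np.eye(n)
        ones = np.ones((n, 1))
        b = ((ones.T @ np.linalg.solve(V, y)) / (ones.T @ np.linalg.solve(V, ones))).item()
        u_markers = (s2a / mm.n_snps) * W.T @ np.linalg.solve(V, y - b)
        np.testing.assert_allclose(
            fit.random_effects["additive"].loc[ids].to_numpy(), W @ u_markers,
            atol=1e-6,
        )

    def test_reliability_increases_with_offspring_records(self):
        """Adding progeny records raises a parent's reliability (more data,
        smaller PEV)."""
        ids = ["p", "m"] + [f"o{k}" for k in range(8)]
        ped = Pedigree(ids, [None, None] + ["p"] * 8, [None, None] + ["m"] * 8)
        A = build_A(ped)
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(ids))
        comps = {"additive": 1.0, "residual": 1.0}
        spec = ModelSpec("y", random=(RandomTerm("additive", "id", covariance=A),))
        df_all = pd.DataFrame({"id": ids, "y": y})
        df_small = pd.DataFrame({"id": ["p", "m", "o0"], "y": y[:3]})
        r_small = solve_mme(spec, comps, df_small).reliabilities["p"]
        r_all = solve_mme(spec, comps, df_all).reliabilities["p"]
        assert r_all > r_small


class TestREML:
    def test_null_signal_boundary(self, rng):
        n = 500
        ids = [f"i{k}" for k in range(n)]
        df = pd.DataFrame({"id": ids, "y": rng.normal(size=n)})
        spec = ModelSpec("y", random=(RandomTerm("additive", "id", covariance=iid_kinship(ids)),))
        fit = reml_estimate(spec, df)
        h2 = fit.heritability()["h2_narrow"]
        assert h2 < 0.1

    def test_half_sib_heritability_recovery(self):
        """h2=0.5 in 100 half-sib families of 20 recovered within 0.1."""
        rng = np.random.default_rng(12)
        n_fam, n_off = 100, 20
        s2a, s2e = 0.5, 0.5
        sires = rng.normal(0, np.sqrt(s2a), n_fam)
        rows = []
        for f in range(n_fam):
            # offspring BV = sire/2 + mendelian(3/4 s2a); dam unknown
            bv = sires[f] / 2 + rng.normal(0, np.sqrt(0.75 * s2a), n_off)
            yv = bv + rng.normal(0, np.sqrt(s2e), n_off)
            for k, v in enumerate(yv):
                rows.append({"fam": f, "id": f"f{f}o{k}", "y": v})
        df = pd.DataFrame(rows)
        ids = ["s%d" % f for f in range(n_fam)] + list(df["id"])
        ped = Pedigree(
            ids,
            [None] * n_fam + [f"s{f}" for f in df["fam"]],
            [None] * len(ids),
        )
        A = build_A(ped)
        spec = ModelSpec("y", random=(RandomTerm("additive", "id", covariance=A),))
        fit = reml_estimate(spec, df)
        assert fit.heritability()["h2_narrow"] == pytest.approx(0.5, abs=0.1)

    def test_grid_search_likelihood_maximum_matches_estimate(self, rng):
        """Brute-force likelihood grid agrees with the REML optimum on a
        tiny half-sib dataset (structured covariance, identifiable)."""
        n_fam, n_off = 6, 5
        sires = [f"s{f}" for f in range(n_fam)]
        off = [f"o{f}_{k}" for f in range(n_fam) for k in range(n_off)]
        ped = Pedigree(
            sires + off,
            [None] * n_fam + [f"s{k // n_off}" for k in range(len(off))],
            [None] * (n_fam + len(off)),
        )
        K = build_A(ped).submatrix(off)
        n = len(off)
        ids = off
        fam_eff = np.repeat(rng.normal(0, 0.6, n_fam), n_off)
        y = fam_eff + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"id": ids, "y": y})
        spec = ModelSpec("y", random=(RandomTerm("additive", "id", covariance=K),))
        fit = reml_estimate(spec, df)
        X = np.ones((n, 1))
        grid = np.linspace(0.01, 4.0, 120)
        best = None
        for s2a in grid:
            for s2e in grid:
                ll = reml_loglik(y, X, [K.values], np.array([s2a, s2e]))
                if best is None or ll > best[0]:
                    best = (ll, s2a, s2e)
        res = 4.0 / 119
        assert fit.components["additive"] == pytest.approx(best[1], abs=2 * res)
        assert fit.components["residual"] == pytest.approx(best[2], abs=2 * res)

    def test_multi_component_ai_reml_recovers_block_and_genetic(self):
        """AI-REML with 3 components stays in-bounds and lands near truth."""
        rng = np.random.default_rng(5)
        n_blk, per_blk = 25, 40
        n = n_blk * per_blk
        ids = [f"i{k}" for k in range(n)]
        blocks = np.repeat(np.arange(n_blk), per_blk)
        s2b, s2u, s2e = 0.3, 0.6, 1.0
        fam = np.repeat(np.arange(n // 10), 10)
        fam_eff = rng.normal(0, np.sqrt(s2u), n // 10)
        y = (
            np.repeat(rng.normal(0, np.sqrt(s2b), n_blk), per_blk)
            + fam_eff[fam]
            + rng.normal(0, np.sqrt(s2e), n)
        )
        df = pd.DataFrame({"id": ids, "block": blocks, "fam": fam, "y": y})
        spec = ModelSpec(
            "y",
            random=(
                RandomTerm("block", "block"),
                RandomTerm("family", "fam"),
            ),
        )
        fit = reml_estimate(spec, df)
        assert fit.converged
        assert fit.components["block"] == pytest.approx(s2b, abs=0.2)
        assert fit.components["family"] == pytest.approx(s2u, abs=0.2)
        assert fit.components["residual"] == pytest.approx(s2e, abs=0.15)


class TestModelFamilies:
    def test_gblup_interpolates_training_candidates(self, rng):
        n = 60
        ids = [f"i{k}" for k in range(n)]
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(n, 200)).astype(float)
        mm = MarkerMatrix(ids, [f"s{j}" for j in range(200)], X)
        p = mm.allele_freq()
        GA = build_GA(mm.select_snps((p > 0.01) & (p < 0.99)))
        # G-structured pseudo-phenotypes (EBVs are nearly noise-free)
        L = np.linalg.cholesky(GA.values + 1e-8 * np.eye(n))
        ebv = pd.Series(L @ rng.normal(size=n), index=ids)
        fit = fit_gblup(ebv, GA)
        gebv = genomic_values(fit)["gebv"]
        assert np.corrcoef(gebv.loc[ids], ebv.loc[ids])[0, 1] > 0.98

    def test_hblup_equals_ablup_with_zero_genotyped(self, small_program, small_phenotypes):
        """With no genomic information H = A, so HBLUP solutions match a
        pedigree-only fit of the same pseudo-phenotypes."""
        ped = small_program.pedigree_true
        A = build_A(ped)
        g1 = small_program.ids_by_generation("G1")[:150]
        pseudo = pd.Series(
            np.random.default_rng(3).normal(size=len(g1)), index=g1
        )
        H_as_A = KinshipMatrix("H", A.ids, A.values.copy())
        fit_h = fit_hblup(pseudo, H_as_A)
        fit_a = fit_hblup(pseudo, A)  # same solver, flavor A
        np.testing.assert_allclose(
            genomic_values(fit_h)["gebv"], genomic_values(fit_a)["gebv"], atol=1e-6
        )

    def test_hblup_ungenotyped_full_sibs_share_gebv(self, small_program):
        """Ungenotyped full sibs carry identical H-model predictions: only
        pedigree information distinguishes them."""
        from rrsgs import build_H, filter_markers

        prog = small_program
        ped = prog.pedigree_true
        A = build_A(ped)
        g2 = prog.ids_by_generation("G2")
        fam = prog.truth.loc[g2, "family"]
        # genotype G1 only: every G2 candidate stays ungenotyped
        g1 = prog.ids_by_generation("G1")
        geno = filter_markers(prog.genotypes.select_individuals(g1), 0.0, 0.01)
        GA = build_GA(geno)
        H = build_H(A, GA, g1)
        rng = np.random.default_rng(4)
        pseudo = pd.Series(rng.normal(size=len(g1)), index=g1)
        pred = genomic_values(fit_hblup(pseudo, H))["gebv"]
        for f in fam.unique()[:3]:
            members = fam.index[fam == f]
            vals = pred.loc[members]
            assert vals.max() - vals.min() < 1e-8

    def test_ablup_ebv_table_contains_egv_with_dominance(self, small_program, small_phenotypes):
        from rrsgs import build_D_pedigree

        ph = small_phenotypes
        ph = ph[np.isclose(ph.nominal_age, 5.40) & (ph.trial == "HPT_G2")]
        ph = ph.rename(columns={"volume": "y"})
        A = build_A(small_program.pedigree_true)
        D = build_D_pedigree(small_program.pedigree_true)
        fit = fit_ablup(ph, A, D=D, response="y", blocks="fixed")
        tab = ebv_table(fit)
        assert {"ebv", "dominance", "egv"} <= set(tab.columns)
        np.testing.assert_allclose(tab["egv"], tab["ebv"] + tab["dominance"])


class TestSummaries:
    def test_heritability_additive_only(self):
        h = heritability({"additive": 305.16, "residual": 211.18})
        assert round(h["h2_narrow"], 2) == 0.59
        assert h["h2_narrow"] == h["h2_broad"]

    def test_heritability_with_dominance(self):
        h = heritability({"additive": 207.31, "dominance": 81.90, "residual": 193.16})
        assert round(h["h2_narrow"], 2) == 0.43
        assert round(h["h2_broad"], 2) == 0.60

    def test_heritability_zero_denominator(self):
        with pytest.raises(EvaluationError):
            heritability({"additive": 0.0, "residual": 0.0})

    def test_deregress_arithmetic(self):
        assert deregress(10.0, 0.5) == 20.0
        assert deregress(7.0, 1.0) == 7.0
        ebv = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        d = deregress(ebv, pd.Series([0.5, 0.5, 0.5], index=list("abc")))
        assert np.corrcoef(ebv, d)[0, 1] == pytest.approx(1.0)

    def test_deregress_invalid_reliability(self):
        with pytest.raises(EvaluationError):
            deregress(1.0, 0.0)
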