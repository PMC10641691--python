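"""Reproducible study-scale experiments over the library.

Each function runs one self-contained computational experiment of the
analysis — REML heritability recovery, sib-pair genomic relationship
checks, solver cross-validations against dense-algebra oracles, the
cross-generation relatedness ordering, and the growth-curve adjustment
comparison — and returns plain numbers. They are the building blocks of
the numbered analysis scripts and of the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assessment as asmt
from . import evaluation as ev
from . import growth, kinship
from .markers import MarkerMatrix
from .pedigree import Pedigree
from .pipeline import PipelineConfig, run_pipeline
from .qc import filter_markers
from .simulate import (
    SimulationConfig,
    drop_gametes,
    simulate_breeding_program,
    simulate_founder_genotypes,
    simulate_phenotypes,
)


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return list(rng.integers(0, 2**31 - 1, size=n))


# ----------------------------------------------------------------------
# REML parameter recovery
# ----------------------------------------------------------------------
def heritability_recovery(
    target_h2: float,
    n_replicates: int = 10,
    seed: int = 0,
    n_families: int = 50,
    offspring_per_family: int = 20,
) -> list[float]:
    """REML narrow-sense heritability estimates on replicate half-sib
    programs (default 2 species x 50 polymix families x 20 = 2,000 records
    at the later measurement age)."""
    estimates = []
    for rep_seed in _seed_stream(seed, n_replicates):
        cfg = SimulationConfig(
            n_founders_per_species=50,
            n_snps=400,
            n_psp_families_per_species=n_families,
            offspring_per_family=offspring_per_family,
            n_hybrid_families_g1=1,
            n_hybrid_families_g2=1,
            n_parents_g2_per_species=2,
            target_h2=target_h2,
            target_d2=0.0,
            seed=int(rep_seed),
        )
        prog = simulate_breeding_program(cfg)
        ph = simulate_phenotypes(prog, include_generations=("G1",))
        ph = ph[ph.trial.str.startswith("PSPT") & np.isclose(ph.nominal_age, 5.40)]
        A = kinship.build_A(prog.pedigree_true)
        fit = ev.fit_ablup(
            ph.rename(columns={"volume": "y"}), A, response="y", blocks="fixed"
        )
        estimates.append(fit.heritability()["h2_narrow"])
    return estimates


def sib_pair_genomic_relationships(
    n_snps: int = 5000, seed: int = 0, n_families: int = 25, fam_size: int = 8
) -> dict:
    """Mean G_A off-diagonals within gene-dropped full-sib and half-sib
    families (expected 0.5 and 0.25), centered by base-population
    frequencies."""
    founders, freqs = simulate_founder_genotypes(
        max(30, 2 * n_families) // 2, n_snps, fst=0.0, seed=seed
    )
    n_f = founders.n_individuals
    fids = founders.ids
    rng = np.random.default_rng(seed + 1)
    ids, sires, dams, fs_groups, hs_groups = list(fids), [None] * n_f, [None] * n_f, [], []
    for f in range(n_families):
        s, d = rng.choice(n_f, 2, replace=False)
        grp = []
        for k in range(fam_size):
            iid = f"fs{f}_{k}"
            ids.append(iid)
            sires.append(fids[s])
            dams.append(fids[d])
            grp.append(iid)
        fs_groups.append(grp)
    for f in range(n_families):
        d = rng.integers(n_f)
        grp = []
        for k in range(fam_size):
            s = rng.choice([j for j in range(n_f) if j != d])
            iid = f"hs{f}_{k}"
            ids.append(iid)
            sires.append(fids[s])
            dams.append(fids[d])
            grp.append(iid)
        hs_groups.append(grp)
    ped = Pedigree(ids, sires, dams)
    geno = drop_gametes(ped, founders, seed=seed + 2)
    base_p = freqs["ancestral"].to_numpy()
    keep = (base_p > 0.01) & (base_p < 0.99)
    G = kinship.build_GA(geno.select_snps(keep), freqs=base_p[keep])

    def group_mean(groups):
        vals = []
        for grp in groups:
            sub = G.submatrix(grp).values
            iu = np.triu_indices(len(grp), k=1)
            vals.append(sub[iu].mean())
        return float(np.mean(vals))

    return {"full_sib_mean": group_mean(fs_groups), "half_sib_mean": group_mean(hs_groups)}


# ----------------------------------------------------------------------
# Solver oracle equivalences
# ----------------------------------------------------------------------
def gblup_vs_rrblup_max_deviation(n: int = 50, m: int = 100, seed: int = 0) -> float:
    """Max |GBLUP BLUP - RR-BLUP marker-ridge prediction| on one dataset."""
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, rng.uniform(0.15, 0.85, m), size=(n, m)).astype(float)
    ids = [f"i{k}" for k in range(n)]
    mm = MarkerMatrix(ids, [f"s{j}" for j in range(m)], X)
    p = mm.allele_freq()
    mm = mm.select_snps((p > 0.01) & (p < 0.99))
    p = mm.allele_freq()
    W = (mm.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
    GA = kinship.build_GA(mm)
    y = rng.normal(size=n)
    s2a, s2e = 0.7, 0.3
    df = pd.DataFrame({"id": ids, "y": y})
    spec = ev.ModelSpec("y", random=(ev.RandomTerm("additive", "id", covariance=GA),))
    fit = ev.solve_mme(spec, {"additive": s2a, "residual": s2e}, df)
    V = s2a * GA.values + s2e * np.eye(n)
    ones = np.ones((n, 1))
    b = ((ones.T @ np.linalg.solve(V, y)) / (ones.T @ np.linalg.solve(V, ones))).item()
    pred_rr = W @ ((s2a / mm.n_snps) * W.T @ np.linalg.solve(V, y - b))
    return float(np.abs(fit.random_effects["additive"].loc[ids].to_numpy() - pred_rr).max())


def _mixed_genotyped_program(seed: int = 0):
    cfg = SimulationConfig(
        n_founders_per_species=8, n_snps=400, n_psp_families_per_species=8,
        offspring_per_family=6, n_hybrid_families_g1=4, n_hybrid_families_g2=4,
        n_parents_g2_per_species=3, seed=seed,
    )
    prog = simulate_breeding_program(cfg)
    A = kinship.build_A(prog.pedigree_true)
    gen_ids = prog.genotypes.ids[::2]
    geno = filter_markers(prog.genotypes.select_individuals(gen_ids), 0.0, 0.01)
    return prog, A, kinship.build_GA(geno), gen_ids


def h_inverse_vs_dense_max_deviation(seed: int = 0, ridge: float = 1e-5) -> float:
    """Max |H^-1 - dense_inverse(H)| with the same ridge on G_A.

    The centered G_A has a null vector, so ||H^-1|| scales like 1/ridge
    and the achievable absolute agreement scales with it; the ridge here
    is applied identically to both sides of the comparison.
    """
    _, A, GA, gen_ids = _mixed_genotyped_program(seed)
    Hinv = kinship.build_H_inverse(A, GA, gen_ids, ridge=ridge)
    GA_r = kinship.KinshipMatrix(
        "GA", GA.ids, GA.values + ridge * np.eye(len(GA.ids))
    )
    H = kinship.build_H(A, GA_r, gen_ids)
    return float(np.abs(Hinv.values - np.linalg.inv(H.values)).max())


def a_inverse_identity_max_deviation(n: int = 200, seed: int = 0) -> float:
    """Max |A^-1 A - I| on a random multi-generation pedigree."""
    rng = np.random.default_rng(seed)
    ids = [f"x{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k < 20:
            sires.append(None)
            dams.append(None)
        else:
            s, d = rng.choice(k, size=2, replace=False)
            sires.append(ids[s])
            dams.append(ids[d])
    ped = Pedigree(ids, sires, dams)
    A = kinship.build_A(ped).values
    Ainv = kinship.build_A_inverse(ped).values
    return float(np.abs(Ainv @ A - np.eye(n)).max())


def h_equals_a_max_deviation(seed: int = 0) -> float:
    """Max |H - A| when G_A is set to the pedigree expectation A22."""
    _, A, _, gen_ids = _mixed_genotyped_program(seed)
    A22 = A.submatrix(gen_ids)
    H = kinship.build_H(A, kinship.KinshipMatrix("GA", A22.ids, A22.values), gen_ids)
    return float(np.abs(H.values - A.values).max())


def hblup_vs_ablup_zero_genotyped_max_deviation(seed: int = 0) -> float:
    """With no genotyped individuals H = A: single-step solutions must
    match the pedigree-only fit of the same pseudo-phenotypes."""
    prog, A, _, _ = _mixed_genotyped_program(seed)
    g1 = prog.ids_by_generation("G1")
    rng = np.random.default_rng(seed + 3)
    L = np.linalg.cholesky(A.submatrix(g1).values + 1e-8 * np.eye(len(g1)))
    pseudo = pd.Series(L @ rng.normal(size=len(g1)), index=g1)
    H_as_A = kinship.KinshipMatrix("H", A.ids, A.values.copy())
    pred_h = ev.genomic_values(ev.fit_hblup(pseudo, H_as_A))["gebv"]
    pred_a = ev.genomic_values(ev.fit_hblup(pseudo, A))["gebv"]
    return float(np.abs(pred_h - pred_a).max())


# ----------------------------------------------------------------------
# Cross-generation relatedness ordering
# ----------------------------------------------------------------------
def relatedness_ordering(
    n_replicates: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Realized predictive ability of G2 candidates with parents-only (P)
    versus unrelated pure-species cohort (U) training, per replicate."""
    rows = []
    for k, rep_seed in enumerate(_seed_stream(seed, n_replicates)):
        cfg = PipelineConfig(
            simulation=SimulationConfig(
                n_founders_per_species=30,
                n_snps=1000,
                n_psp_families_per_species=30,
                offspring_per_family=25,
                n_hybrid_families_g1=6,
                n_hybrid_families_g2=14,
                offspring_per_family_g2=30,
                n_parents_g2_per_species=9,
                seed=int(rep_seed),
            ),
            models=("gblup",),
            training_combos=("P", "U"),
            genotyped_fraction_g2=0.50,
            n_uncles_per_species=40,
            uncles_unrelated=True,
            evaluation_ages=(5.40,),
            seed=int(rep_seed),
        )
        rep = run_pipeline(cfg).report
        rpa = rep[rep.metric == "rpa"].set_index("training_set")["value"]
        rows.append({"replicate": k, "rpa_parents": rpa["P"], "rpa_unrelated": rpa["U"]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Age adjustment
# ----------------------------------------------------------------------
def age_adjustment_comparison(
    n_trees: int = 500, seed: int = 0, meas_ages=(2.9, 5.6), scale: float = 0.6
) -> pd.DataFrame:
    """Fit all four growth models to trees whose scaled trajectories are
    genuine Logistic-1 curves measured off the reference ages; residual
    variance against noiseless truth, and percent reduction vs carrying
    the raw measurement to the nearest reference age."""
    rng = np.random.default_rng(seed)
    b0 = rng.uniform(10.0, 30.0, n_trees)
    b1 = rng.uniform(-0.95, -0.55, n_trees)
    ref = growth.REFERENCE_AGES
    rows, truth = [], []
    for i in range(n_trees):
        for a in meas_ages:
            v = scale / (1 + b0[i] * np.exp(b1[i] * a)) * (1 + rng.normal(0, 0.01))
            rows.append({"id": f"t{i}", "trial": "T", "age": a, "volume": v})
        for a in ref:
            truth.append(
                {"id": f"t{i}", "age": a, "volume": scale / (1 + b0[i] * np.exp(b1[i] * a))}
            )
    raw = pd.DataFrame(rows)
    truth = pd.DataFrame(truth)
    nearest = raw.copy()
    nearest["age"] = nearest["age"].map(dict(zip(meas_ages, ref)))
    adjusted = {
        model: growth.adjust_to_reference_ages(
            growth.fit_growth_model(raw, model, scaling_max=scale)
        )
        for model in growth.MODELS
    }
    return growth.adjustment_diagnostics(nearest, adjusted, truth)
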