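"""End-to-end experiment driver: simulate -> QC -> age-adjust -> ABLUP ->
pseudo-phenotypes -> kinship -> GBLUP/HBLUP per training set -> assessment.

The pipeline mirrors the cross-generational design: prediction models are
trained on prior-generation (G1) data — hybrids (H), the direct parents of
the G2 families (P), and pure-species relatives ("uncles", U) — and
validated against the pedigree values of the G2 candidates at harvest age.
A single global seed fans out to per-stage child seeds by stable hashing,
so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assessment as asmt
from . import evaluation as ev
from . import growth, kinship, qc
from .markers import MarkerMatrix
from .simulate import (
    BreedingProgram,
    SimulationConfig,
    _child_seed,
    simulate_breeding_program,
    simulate_phenotypes,
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_snp_call_rate: float = 0.90
    min_maf: float = 0.01
    min_sample_call_rate: float = 0.85
    adjustment_model: str = "logistic1"
    reference_ages: tuple[float, float] = growth.REFERENCE_AGES
    #: ages at which BLUP evaluations/assessments run (subset of reference
    #: ages; None = all)
    evaluation_ages: Optional[tuple[float, ...]] = None
    models: tuple[str, ...] = ("gblup", "gblup-gd", "hblup")
    training_combos: tuple[str, ...] = asmt.TRAINING_COMBOS
    selected_proportions: tuple[float, ...] = (0.025, 0.05, 0.10, 0.20, 0.50)
    genotyped_fraction_g2: float = 0.25
    n_uncles_per_species: int = 40
    #: restrict the U cohort to trees sharing no founder ancestor with the
    #: candidates (a genuinely unrelated cohort, for relatedness contrasts)
    uncles_unrelated: bool = False
    missing_rate: float = 0.02
    output_dir: Optional[str] = None
    seed: int = 2024

    def stage_seed(self, stage: str) -> int:
        return _child_seed(self.seed, f"pipeline:{stage}")


@dataclass
class PipelineResult:
    report: pd.DataFrame
    program: BreedingProgram
    cohorts: dict
    ebv_training: pd.DataFrame  # per age: EBV/EGV of G1 individuals
    ebv_reference: pd.DataFrame  # per age: EBV/EGV of G2 candidates
    manifest: dict


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).values.tobytes()
    ).hexdigest()[:12]


def define_cohorts(program: BreedingProgram, config: PipelineConfig) -> dict:
    """Pick the genotyped cohorts of the study design.

    H = G1 hybrids; P = the G1 pure-species trees that parent the G2
    families; U = a random sample of other G1 pure-species trees;
    candidates = a random sample of G2 trees genotyped at the seedling
    stage (the remainder of G2 stays ungenotyped).
    """
    rng = np.random.default_rng(config.stage_seed("cohorts"))
    truth = program.truth
    g1 = truth[truth["generation"] == "G1"]
    g2_ids = list(truth.index[truth["generation"] == "G2"])
    hybrids = list(g1.index[g1["species"] == "hybrid"])
    g2_parents = sorted(
        {
            p
            for i in g2_ids
            for p in (
                program.pedigree_true.sires[program.pedigree_true._index[i]],
                program.pedigree_true.dams[program.pedigree_true._index[i]],
            )
            if p is not None
        }
    )
    pure = [i for i in g1.index if g1.loc[i, "species"] != "hybrid"]
    non_parents = [i for i in pure if i not in set(g2_parents)]
    if config.uncles_unrelated:
        # founders behind the candidates (parents of the P cohort)
        ped = program.pedigree_true
        ancestors = set()
        for p in g2_parents:
            k = ped._index[p]
            ancestors.update(a for a in (ped.sires[k], ped.dams[k]) if a is not None)
        eligible = []
        for i in non_parents:
            k = ped._index[i]
            if ped.sires[k] not in ancestors and ped.dams[k] not in ancestors:
                eligible.append(i)
        non_parents = eligible
    uncles = []
    for sp in ("grandis", "urophylla"):
        cand = [i for i in non_parents if truth.loc[i, "species"] == sp]
        take = min(config.n_uncles_per_species, len(cand))
        uncles += list(rng.choice(cand, size=take, replace=False))
    n_cand = max(3, int(round(config.genotyped_fraction_g2 * len(g2_ids))))
    candidates = sorted(rng.choice(g2_ids, size=min(n_cand, len(g2_ids)), replace=False))
    return {
        "H": hybrids,
        "P": g2_parents,
        "U": sorted(uncles),
        "candidates_genotyped": list(candidates),
        "g2_all": g2_ids,
    }


def qc_genotypes(
    program: BreedingProgram, cohorts: dict, config: PipelineConfig
) -> MarkerMatrix:
    """Mask to the genotyped set, inject missingness, filter and impute."""
    geno_ids = (
        cohorts["H"] + cohorts["P"] + cohorts["U"] + cohorts["candidates_genotyped"]
    )
    m = program.genotypes.select_individuals(geno_ids)
    rng = np.random.default_rng(config.stage_seed("missingness"))
    X = m.dosages.copy()
    miss = rng.random(X.shape) < config.missing_rate
    X[miss] = np.nan
    m = MarkerMatrix(m.ids, m.snp_ids, X)
    m = qc.filter_samples(m, config.min_sample_call_rate)
    m = qc.filter_markers(m, config.min_snp_call_rate, config.min_maf)
    return qc.impute_missing(m)


def age_adjust(
    phenotypes: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Fit the configured growth model per tree and predict at the
    reference ages; returns id, trial, block, age, volume, mai."""
    fit = growth.fit_growth_model(phenotypes, model=config.adjustment_model)
    adj = growth.adjust_to_reference_ages(fit, config.reference_ages)
    meta = phenotypes[["id", "trial", "block"]].drop_duplicates("id")
    return adj.merge(meta, on=["id", "trial"], how="left")


def _ablup_by_age(
    adjusted: pd.DataFrame,
    pedigree_ids: Sequence[str],
    A: kinship.KinshipMatrix,
    D: Optional[kinship.KinshipMatrix],
    ages: Sequence[float],
    blocks: str = "fixed",
) -> pd.DataFrame:
    frames = []
    for age in ages:
        sub = adjusted[np.isclose(adjusted["age"], age)]
        fit_a = ev.fit_ablup(sub, A, response="mai", blocks=blocks)
        tab = ev.ebv_table(fit_a)[["ebv"]]
        if fit_a.reliabilities is not None:
            tab["reliability"] = fit_a.reliabilities
        if D is not None:
            fit_ad = ev.fit_ablup(sub, A, D=D, response="mai", blocks=blocks)
            tab_ad = ev.ebv_table(fit_ad)
            tab["egv"] = tab_ad["egv"]
        tab["age"] = age
        frames.append(tab.reset_index())
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full experiment; deterministic for a fixed config."""
    manifest: dict = {"seed": config.seed, "stages": []}

    def log(stage, **info):
        manifest["stages"].append({"stage": stage, **info})

    program = simulate_breeding_program(config.simulation)
    log("simulate", config_hash=config.simulation.config_hash(),
        n_individuals=len(program.pedigree))
    phenos = simulate_phenotypes(program, seed=config.stage_seed("phenotypes"))
    log("phenotypes", hash=_hash_df(phenos))

    cohorts = define_cohorts(program, config)
    genotypes = qc_genotypes(program, cohorts, config)
    log("qc", n_genotyped=genotypes.n_individuals, n_snps=genotypes.n_snps)

    adjusted = age_adjust(phenos, config)
    log("age_adjust", model=config.adjustment_model, hash=_hash_df(adjusted))

    truth = program.truth
    g1_ids = [i for i in truth.index if truth.loc[i, "generation"] == "G1"]
    g2_ids = cohorts["g2_all"]
    need_dominance = any(m in config.models for m in ("ablup-ad", "gblup-gd"))

    # ABLUP on the nominal pedigree: G1 training values and G2 reference values
    ped = program.pedigree
    A = kinship.build_A(ped)
    D = kinship.build_D_pedigree(ped) if need_dominance else None
    # training values use prior-generation (G1) records only — the data
    # available when candidates are seedlings; harvest-age reference values
    # come from the joint multi-trial evaluation of all records
    adj_g1 = adjusted[adjusted["id"].isin(set(g1_ids))]
    adj_all = adjusted[adjusted["id"].isin(set(g1_ids) | set(g2_ids))]
    eval_ages = config.evaluation_ages or config.reference_ages
    ebv_train = _ablup_by_age(adj_g1, ped.ids, A, D, eval_ages)
    ebv_ref = _ablup_by_age(adj_all, ped.ids, A, D, eval_ages)
    ebv_train = ebv_train[ebv_train["id"].isin(set(g1_ids))]
    ebv_ref = ebv_ref[ebv_ref["id"].isin(set(g2_ids))]
    log("ablup", hash_train=_hash_df(ebv_train), hash_ref=_hash_df(ebv_ref))

    # genomic relationship matrices on the QC'ed genotyped set
    GA = kinship.build_GA(genotypes)
    GD = kinship.build_GD(genotypes) if "gblup-gd" in config.models else None
    log("kinship", flavors=[f for f in ("A", "GA", "GD", "H") if f != "GD" or GD is not None])

    genotyped = set(genotypes.ids)
    harvest_age = config.reference_ages[-1]
    ref_h = ebv_ref[np.isclose(ebv_ref["age"], harvest_age)].set_index("id")
    fam = truth.loc[g2_ids, "family"]

    rows = []
    for combo in config.training_combos:
        tset = asmt.build_training_set(
            {k: cohorts[k] for k in ("H", "P", "U")}, combo
        )
        train_geno = [i for i in tset.members if i in genotyped]
        ebv_t = ebv_train[np.isclose(ebv_train["age"], harvest_age)].set_index("id")
        for model in config.models:
            if model in ("ablup", "ablup-ad"):
                continue  # ABLUP is the reference, not a genomic model
            if model == "gblup":
                y = ebv_t.loc[[i for i in train_geno if i in ebv_t.index], "ebv"]
                fit = ev.fit_gblup(y, GA)
                pred = ev.genomic_values(fit)["gebv"]
                target = [i for i in cohorts["candidates_genotyped"] if i in pred.index]
                genomic_vals = pred.loc[target]
                reference = ref_h.loc[[i for i in target if i in ref_h.index], "ebv"]
            elif model == "gblup-gd":
                if GD is None or "egv" not in ebv_t.columns:
                    continue
                y = ebv_t.loc[[i for i in train_geno if i in ebv_t.index], "egv"]
                fit = ev.fit_gblup(y, GA, GD=GD)
                pred = ev.genomic_values(fit)["gegv"]
                target = [i for i in cohorts["candidates_genotyped"] if i in pred.index]
                genomic_vals = pred.loc[target]
                reference = ref_h.loc[[i for i in target if i in ref_h.index], "egv"]
            elif model == "hblup":
                H = kinship.build_H(A, GA, genotypes.ids)
                y = ebv_t.loc[[i for i in tset.members if i in ebv_t.index], "ebv"]
                fit = ev.fit_hblup(y, H)
                pred = ev.genomic_values(fit)["gebv"]
                target = g2_ids
                genomic_vals = pred.loc[[i for i in target if i in pred.index]]
                reference = ref_h.loc[[i for i in target if i in ref_h.index], "ebv"]
            else:
                raise ValueError(f"unknown model {model!r}")
            rows.append(
                asmt.assessment_report(
                    genomic_vals,
                    reference,
                    model=model,
                    training_set=combo,
                    age=harvest_age,
                    proportions=config.selected_proportions,
                    family_map=fam,
                )
            )
    report = pd.concat(rows, ignore_index=True)
    log("assessment", hash=_hash_df(report[["model", "training_set", "metric", "value"]]))

    result = PipelineResult(
        report=report,
        program=program,
        cohorts=cohorts,
        ebv_training=ebv_train,
        ebv_reference=ebv_ref,
        manifest=manifest,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        program.write(out / "simulated")
        phenos.to_csv(out / "phenotypes.csv", index=False)
        adjusted.to_csv(out / "adjusted_phenotypes.csv", index=False)
        ebv_train.to_csv(out / "ebv_training.csv", index=False)
        ebv_ref.to_csv(out / "ebv_reference.csv", index=False)
        report.to_csv(out / "assessment_report.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result
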