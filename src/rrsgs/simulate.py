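"""Synthetic reciprocal-recurrent-selection breeding program generator.

Emulates a two-species eucalypt RRS design with known ground truth:

* G0 — two divergent founder species (default 30 + 30 parents), allele
  frequencies diverged from a common ancestral pool by a Balding-Nichols
  model with parameter ``fst``, genotypes in Hardy-Weinberg within species.
* G1 — pure-species maternal half-sib families from a polymix (the true
  sire is drawn from the species' pollen pool and recorded internally, but
  the exported nominal pedigree lists him as unknown), plus reciprocal
  interspecific hybrid full-sib families.
* G2 — hybrid full-sib families from selected G1 pure-species parents.

Genotypes descend by gene dropping at unlinked loci; the trait is stem
volume with an additive + dominance architecture and a shared Logistic
growth curve, measured in several trials with randomized complete blocks
at two (jittered) ages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .pedigree import Pedigree

SPECIES = ("grandis", "urophylla")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic breeding program (desk scale by default)."""

    n_founders_per_species: int = 30
    n_snps: int = 3000
    fst: float = 0.20
    n_psp_families_per_species: int = 30
    offspring_per_family: int = 20
    n_hybrid_families_g1: int = 12
    n_hybrid_families_g2: int = 12
    #: G2 family size; None = same as offspring_per_family
    offspring_per_family_g2: Optional[int] = None
    n_parents_g2_per_species: int = 9
    target_h2: float = 0.40
    target_d2: float = 0.15
    n_trials: int = 2  # pure-species progeny trials per species
    n_blocks_per_trial: int = 10
    block_variance: float = 0.002  # m^3 units squared
    residual_variance: float = 0.010
    trait_mean: float = 0.45  # asymptotic mean stem volume, m^3
    growth_beta0: float = 17.8  # shared Logistic curve y = 1/(1+b0 e^{b1 x})
    growth_beta1: float = -0.7368
    measurement_ages: tuple[float, ...] = (2.76, 5.40)
    age_jitter: float = 0.15  # per-trial departure from nominal ages, years
    seed: int = 2024

    def __post_init__(self):
        counts = (
            self.n_founders_per_species,
            self.n_snps,
            self.n_psp_families_per_species,
            self.offspring_per_family,
            self.n_hybrid_families_g1,
            self.n_hybrid_families_g2,
            self.n_parents_g2_per_species,
            self.n_trials,
            self.n_blocks_per_trial,
        )
        if any(c < 1 for c in counts):
            raise SimulationError("all counts must be >= 1")
        if self.offspring_per_family_g2 is not None and self.offspring_per_family_g2 < 1:
            raise SimulationError("all counts must be >= 1")
        if not (np.isfinite(self.fst) and 0.0 <= self.fst < 1.0):
            raise SimulationError("fst must lie in [0, 1)")
        if not 0.0 < self.target_h2 < 1.0:
            raise SimulationError("target_h2 must lie in (0, 1)")
        if self.target_d2 < 0 or self.target_h2 + self.target_d2 >= 1.0:
            raise SimulationError("need target_h2 + target_d2 < 1")
        ages = tuple(float(a) for a in self.measurement_ages)
        if any(a <= 0 for a in ages) or any(
            b <= a for a, b in zip(ages, ages[1:])
        ):
            raise SimulationError("measurement_ages must be positive and increasing")
        self.measurement_ages = ages

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------
# Founders
# ----------------------------------------------------------------------
def simulate_founder_genotypes(
    n_per_species: int, n_snps: int, fst: float, seed: int
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Draw G0 genotypes for the two species under a Balding-Nichols model.

    A common ancestral frequency p0 ~ U(0.05, 0.95) per SNP diverges into
    per-species frequencies p_s ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F); fst=0
    means no divergence (p_s = p0). Genotypes are Hardy-Weinberg binomial
    draws within species.

    Returns the founder MarkerMatrix (grandis rows first) and a DataFrame
    of per-species allele frequencies (columns ``grandis``, ``urophylla``,
    ``ancestral``; one row per SNP).
    """
    if n_snps < 1:
        raise SimulationError("n_snps must be >= 1")
    if not (np.isfinite(fst) and 0.0 <= fst < 1.0):
        raise SimulationError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    freqs = {}
    for sp in SPECIES:
        if fst == 0.0:
            freqs[sp] = p0.copy()
        else:
            ratio = (1.0 - fst) / fst
            freqs[sp] = rng.beta(p0 * ratio, (1.0 - p0) * ratio)
    ids, rows = [], []
    for sp in SPECIES:
        g = rng.binomial(2, freqs[sp], size=(n_per_species, n_snps)).astype(float)
        rows.append(g)
        tag = "Eg" if sp == "grandis" else "Eu"
        ids += [f"{tag}_F{k + 1:03d}" for k in range(n_per_species)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    mat = MarkerMatrix(ids, snp_ids, np.vstack(rows))
    freq_df = pd.DataFrame({**freqs, "ancestral": p0}, index=snp_ids)
    return mat, freq_df


# ----------------------------------------------------------------------
# Trait architecture
# ----------------------------------------------------------------------
@dataclass
class TraitArchitecture:
    """Per-SNP effects plus the variance components they imply."""

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    center_freq: np.ndarray  # frequencies used to center genotypic values

    def genetic_values(self, m: MarkerMatrix) -> pd.DataFrame:
        """True additive values and dominance deviations for each individual."""
        X = m.dosages
        p = self.center_freq
        add = (X - 2.0 * p) @ self.additive_effects
        het = (X == 1.0).astype(float)
        dom = (het - 2.0 * p * (1.0 - p)) @ self.dominance_effects
        return pd.DataFrame({"additive": add, "dominance": dom}, index=m.ids)


def simulate_trait_architecture(
    marker_freqs: np.ndarray,
    target_h2: float,
    target_d2: float,
    residual_variance: float,
    seed: int,
    founder_genotypes: Optional[MarkerMatrix] = None,
    founder_groups: Optional[Sequence] = None,
) -> TraitArchitecture:
    """Draw per-SNP additive and dominance effects scaled to target ratios.

    Effects are Gaussian, rescaled so the founder-population additive and
    dominance variances satisfy sigma2_a / (sigma2_a + sigma2_d + sigma2_e)
    = target_h2 (analogously for dominance). Scaling uses Hardy-Weinberg
    expectations from ``marker_freqs``, or the realized founder genotypes
    when supplied. With ``founder_groups`` (e.g. species labels) variances
    are taken within groups, so the targets are within-population
    heritabilities — the quantity trial-stratified mixed models estimate —
    rather than inflated by the between-species mean difference.
    """
    if target_h2 + target_d2 >= 1.0:
        raise SimulationError("need target_h2 + target_d2 < 1")
    p = np.asarray(marker_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise SimulationError("marker frequencies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_snps = p.size
    sigma2_res = 1.0 - target_h2 - target_d2
    if residual_variance > 0:
        sigma2_a = target_h2 / sigma2_res * residual_variance
        sigma2_d = target_d2 / sigma2_res * residual_variance
    else:
        # noiseless phenotypes: keep the additive:dominance ratio on a
        # fixed unit genetic scale (heritability is then trivially 1)
        total_genetic = 0.01
        sigma2_a = target_h2 / (target_h2 + target_d2) * total_genetic
        sigma2_d = target_d2 / (target_h2 + target_d2) * total_genetic

    beta = rng.normal(size=n_snps)
    delta = rng.normal(size=n_snps)
    q = 1.0 - p
    if founder_genotypes is not None:
        gv = TraitArchitecture(beta, delta, 0, 0, 0, p).genetic_values(founder_genotypes)
        if founder_groups is not None:
            grp = pd.Series(list(founder_groups), index=gv.index)
            centered = gv - gv.groupby(grp).transform("mean")
            var_a_raw = float(np.var(centered["additive"]))
            var_d_raw = float(np.var(centered["dominance"]))
        else:
            var_a_raw = float(np.var(gv["additive"]))
            var_d_raw = float(np.var(gv["dominance"]))
    else:
        var_a_raw = float(np.sum(2.0 * p * q * beta**2))
        var_d_raw = float(np.sum(2.0 * p * q * (1.0 - 2.0 * p * q) * delta**2))
    beta *= np.sqrt(sigma2_a / var_a_raw)
    if target_d2 == 0.0:
        delta = np.zeros(n_snps)
    else:
        delta *= np.sqrt(sigma2_d / var_d_raw)
    return TraitArchitecture(
        additive_effects=beta,
        dominance_effects=delta,
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d,
        sigma2_e=residual_variance,
        center_freq=p,
    )


# ----------------------------------------------------------------------
# Gene dropping
# ----------------------------------------------------------------------
def drop_gametes(
    pedigree: Pedigree, founder_genotypes: MarkerMatrix, seed: int
) -> MarkerMatrix:
    """Propagate genotypes down the pedigree at unlinked loci.

    Each offspring allele is drawn independently per locus from the
    corresponding parent: a parent with dosage g transmits the B allele
    with probability g/2. Founders must be fully genotyped; offspring with
    an unknown parent are not allowed (use the true pedigree).
    """
    n_snps = founder_genotypes.n_snps
    geno_index = {i: k for k, i in enumerate(founder_genotypes.ids)}
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    out = np.full((n, n_snps), np.nan)
    sire, dam = pedigree.parent_indices()
    for i in pedigree._order:
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            iid = pedigree.ids[i]
            if iid not in geno_index:
                raise SimulationError(f"founder {iid} has no genotype")
            g = founder_genotypes.dosages[geno_index[iid]]
            if np.isnan(g).any():
                raise SimulationError(f"founder {iid} has missing calls")
            out[i] = g
        elif s >= 0 and d >= 0:
            a1 = rng.random(n_snps) < out[s] / 2.0
            a2 = rng.random(n_snps) < out[d] / 2.0
            out[i] = a1.astype(float) + a2.astype(float)
        else:
            raise SimulationError(
                f"{pedigree.ids[i]} has exactly one known parent; gene dropping "
                "requires both parents (or none, for founders)"
            )
    return MarkerMatrix(pedigree.ids, founder_genotypes.snp_ids, out)


# ----------------------------------------------------------------------
# Full program
# ----------------------------------------------------------------------
@dataclass
class BreedingProgram:
    """A complete simulated dataset with ground truth."""

    config: SimulationConfig
    pedigree: Pedigree  # nominal (polymix sires recorded as unknown)
    pedigree_true: Pedigree
    genotypes: MarkerMatrix
    truth: pd.DataFrame  # id-indexed: additive, dominance, species, generation, family, trial, block
    founder_freqs: pd.DataFrame
    architecture: TraitArchitecture

    def ids_by_generation(self, generation: str) -> list[str]:
        return list(self.truth.index[self.truth["generation"] == generation])

    def write(self, outdir) -> None:
        """Write pedigrees, genotypes, truth and config to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(outdir / "pedigree_nominal.csv")
        self.pedigree_true.write_csv(outdir / "pedigree_true.csv")
        self.genotypes.write_csv(outdir / "genotypes.csv")
        self.truth.to_csv(outdir / "truth.csv", index_label="id")
        with open(outdir / "config.json", "w") as fh:
            json.dump(
                {**asdict(self.config), "config_hash": self.config.config_hash()},
                fh,
                indent=2,
                default=str,
            )


def _child_seed(seed: int, label: str) -> int:
    """Stable per-stage child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def simulate_breeding_program(config: SimulationConfig) -> BreedingProgram:
    """Run the G0 -> G1 -> G2 design and return all components."""
    cfg = config
    rng = np.random.default_rng(_child_seed(cfg.seed, "design"))
    founders, freq_df = simulate_founder_genotypes(
        cfg.n_founders_per_species, cfg.n_snps, cfg.fst, _child_seed(cfg.seed, "founders")
    )
    n_f = cfg.n_founders_per_species
    founder_ids = {
        "grandis": founders.ids[:n_f],
        "urophylla": founders.ids[n_f : 2 * n_f],
    }

    ids: list[str] = list(founders.ids)
    sires_t: list[Optional[str]] = [None] * len(ids)
    dams_t: list[Optional[str]] = [None] * len(ids)
    sires_n: list[Optional[str]] = [None] * len(ids)
    dams_n: list[Optional[str]] = [None] * len(ids)
    meta_rows: list[dict] = [
        {
            "id": i,
            "generation": "G0",
            "species": sp,
            "family": f"G0_{sp}",
            "trial": "G0",
            "block": 0,
        }
        for sp in SPECIES
        for i in founder_ids[sp]
    ]

    def add(iid, sire_true, dam, sire_nominal, generation, species, family, trial, block):
        ids.append(iid)
        sires_t.append(sire_true)
        dams_t.append(dam)
        sires_n.append(sire_nominal)
        dams_n.append(dam)
        meta_rows.append(
            {
                "id": iid,
                "generation": generation,
                "species": species,
                "family": family,
                "trial": trial,
                "block": block,
            }
        )

    # --- G1 pure species polymix half-sib families -------------------
    for sp in SPECIES:
        tag = "Eg" if sp == "grandis" else "Eu"
        pool = founder_ids[sp]
        for f in range(cfg.n_psp_families_per_species):
            dam = pool[f % n_f]
            trial = f"PSPT_{tag}{(f % cfg.n_trials) + 1}"
            fam = f"{tag}1_fam{f + 1:02d}"
            for k in range(cfg.offspring_per_family):
                candidates = [p for p in pool if p != dam]
                sire = candidates[rng.integers(len(candidates))]
                block = (k % cfg.n_blocks_per_trial) + 1
                add(
                    f"{tag}1_f{f + 1:02d}_o{k + 1:03d}",
                    sire,
                    dam,
                    None,  # polymix sire recorded-as-unknown in nominal pedigree
                    "G1",
                    sp,
                    fam,
                    trial,
                    block,
                )

    # --- G1 reciprocal hybrid full-sib families ----------------------
    for f in range(cfg.n_hybrid_families_g1):
        g_par = founder_ids["grandis"][rng.integers(n_f)]
        u_par = founder_ids["urophylla"][rng.integers(n_f)]
        # alternate cross direction (reciprocal design)
        dam, sire = (g_par, u_par) if f % 2 == 0 else (u_par, g_par)
        fam = f"H1_fam{f + 1:02d}"
        for k in range(cfg.offspring_per_family):
            block = (k % cfg.n_blocks_per_trial) + 1
            add(
                f"H1_f{f + 1:02d}_o{k + 1:03d}",
                sire,
                dam,
                sire,
                "G1",
                "hybrid",
                fam,
                "HPT_G1",
                block,
            )

    # genotypes + truth for everything so far (needed to select G2 parents)
    ped_true_partial = Pedigree(list(ids), list(sires_t), list(dams_t))
    geno_partial = drop_gametes(
        ped_true_partial, founders, _child_seed(cfg.seed, "gametes_g1")
    )
    arch = simulate_trait_architecture(
        freq_df[list(SPECIES)].mean(axis=1).to_numpy(),
        cfg.target_h2,
        cfg.target_d2,
        cfg.residual_variance,
        _child_seed(cfg.seed, "architecture"),
        founder_genotypes=founders,
        founder_groups=["grandis"] * n_f + ["urophylla"] * n_f,
    )
    gv_partial = arch.genetic_values(geno_partial)

    # --- G2: phenotypic forward selection of G1 pure-species parents ---
    # ranking on a single own-performance record (genotypic value + noise),
    # the realistic accuracy of field selection rather than true merit
    sel_rng = np.random.default_rng(_child_seed(cfg.seed, "selection"))
    g2_parents = {}
    for sp in SPECIES:
        cands = [
            i
            for i, m in zip(ids, meta_rows)
            if m["generation"] == "G1" and m["species"] == sp
        ]
        merit = (
            gv_partial.loc[cands, "additive"]
            + gv_partial.loc[cands, "dominance"]
            + sel_rng.normal(
                0.0,
                np.sqrt(cfg.residual_variance + cfg.block_variance),
                len(cands),
            )
        )
        ranked = merit.sort_values(ascending=False)
        g2_parents[sp] = list(ranked.index[: cfg.n_parents_g2_per_species])

    pairs = [(g, u) for g in g2_parents["grandis"] for u in g2_parents["urophylla"]]
    pair_idx = rng.choice(len(pairs), size=min(cfg.n_hybrid_families_g2, len(pairs)), replace=False)
    for f, pk in enumerate(pair_idx):
        g_par, u_par = pairs[pk]
        dam, sire = (g_par, u_par) if f % 2 == 0 else (u_par, g_par)
        fam = f"H2_fam{f + 1:02d}"
        fam_size = cfg.offspring_per_family_g2 or cfg.offspring_per_family
        for k in range(fam_size):
            block = (k % cfg.n_blocks_per_trial) + 1
            add(
                f"H2_f{f + 1:02d}_o{k + 1:03d}",
                sire,
                dam,
                sire,
                "G2",
                "hybrid",
                fam,
                "HPT_G2",
                block,
            )

    meta = pd.DataFrame(meta_rows).set_index("id")
    ped_true = Pedigree(list(ids), list(sires_t), list(dams_t), meta=meta)
    ped_nominal = Pedigree(list(ids), list(sires_n), list(dams_n), meta=meta)

    # drop G2 gametes conditional on the G1 genotypes already realized
    partial_set = set(ped_true_partial.ids)
    g2_triplets = [
        (i, s, d)
        for i, s, d in zip(ids, sires_t, dams_t)
        if i not in partial_set
    ]
    g2_parent_ids = sorted({p for _, s, d in g2_triplets for p in (s, d)})
    ped_g2 = Pedigree(
        ids=g2_parent_ids + [t[0] for t in g2_triplets],
        sires=[None] * len(g2_parent_ids) + [t[1] for t in g2_triplets],
        dams=[None] * len(g2_parent_ids) + [t[2] for t in g2_triplets],
    )
    geno_g2 = drop_gametes(
        ped_g2,
        geno_partial.select_individuals(g2_parent_ids),
        _child_seed(cfg.seed, "gametes_g2"),
    )
    stacked = pd.concat(
        [geno_partial.to_frame(), geno_g2.to_frame().loc[[t[0] for t in g2_triplets]]]
    )
    genotypes = MarkerMatrix(list(ids), founders.snp_ids, stacked.loc[list(ids)].to_numpy())
    gv = arch.genetic_values(genotypes)
    truth = meta.join(gv)
    truth = truth.rename_axis("id")
    _check_structure(truth, ped_true)
    return BreedingProgram(
        config=cfg,
        pedigree=ped_nominal,
        pedigree_true=ped_true,
        genotypes=genotypes,
        truth=truth,
        founder_freqs=freq_df,
        architecture=arch,
    )


def _check_structure(truth: pd.DataFrame, ped: Pedigree) -> None:
    """Hybrids must have parents of different species labels."""
    sp = truth["species"]
    for iid, s, d in zip(ped.ids, ped.sires, ped.dams):
        if sp.loc[iid] == "hybrid" and s is not None and d is not None:
            if sp.loc[s] == sp.loc[d]:
                raise SimulationError(f"hybrid {iid} has same-species parents")


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------
def growth_factor(age, beta0: float, beta1: float):
    """Shared Logistic growth multiplier s(x) = 1/(1 + b0 e^{b1 x}) in (0,1)."""
    return 1.0 / (1.0 + beta0 * np.exp(beta1 * np.asarray(age, dtype=float)))


def simulate_phenotypes(
    program: BreedingProgram,
    include_generations: Sequence[str] = ("G1", "G2"),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Emit volume measurements for field-trial individuals at each age.

    volume(x) = s(x) * (mu + additive + dominance) + block + s(x) * resid,
    where s is the shared Logistic factor, block ~ N(0, block_variance) per
    (trial, block), and the residual standard deviation scales with s so
    the narrow-sense heritability equals the target at every age. Ages
    carry a per-trial jitter (same trees measured together). Volumes are
    floored at 1 mm^3 to stay physically non-negative.
    """
    cfg = program.config
    rng = np.random.default_rng(
        _child_seed(cfg.seed, "phenotypes") if seed is None else seed
    )
    truth = program.truth
    mask = truth["generation"].isin(include_generations)
    df = truth.loc[mask]
    if (df["trial"] == "").any():
        raise SimulationError("individual missing trial/block assignment")

    trials = sorted(df["trial"].unique())
    block_effects = {
        (t, b): rng.normal(0.0, np.sqrt(cfg.block_variance))
        for t in trials
        for b in sorted(df.loc[df["trial"] == t, "block"].unique())
    }
    trial_age = {
        (t, a): a + rng.uniform(-cfg.age_jitter, cfg.age_jitter)
        for t in trials
        for a in cfg.measurement_ages
    }
    rows = []
    genetic = cfg.trait_mean + df["additive"] + df["dominance"]
    sd_e = np.sqrt(cfg.residual_variance)
    for nominal in cfg.measurement_ages:
        for t in trials:
            sub = df[df["trial"] == t]
            age = trial_age[(t, nominal)]
            s = growth_factor(age, cfg.growth_beta0, cfg.growth_beta1)
            resid = rng.normal(0.0, sd_e * s, size=len(sub))
            blocks = np.array([block_effects[(t, b)] for b in sub["block"]])
            vol = np.maximum(s * genetic.loc[sub.index].to_numpy() + blocks + resid, 1e-9)
            rows.append(
                pd.DataFrame(
                    {
                        "id": sub.index,
                        "trial": t,
                        "block": sub["block"].to_numpy(),
                        "nominal_age": nominal,
                        "age": age,
                        "volume": vol,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
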