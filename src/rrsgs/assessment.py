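"""Cross-generation validation metrics and training-set assembly.

Realized predictive ability (RPA) is the Pearson correlation between
seedling-stage genomic values (GEBV/GEGV) and the reference pedigree
values (EBV/EGV) of the same trees at harvest age; bias is 1 - b with b
the slope of the regression of reference on genomic values (b > 1 means
the genomic spread underestimates the reference spread). Rank concordance
is Spearman's rho; the coincidence rate is the percent overlap of the
top-k candidates under both rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRAINING_COMBOS = ("H", "P", "U", "H+P", "H+U", "P+U", "H+P+U")


class AssessmentError(ValueError):
    pass


# ----------------------------------------------------------------------
# Training sets
# ----------------------------------------------------------------------
@dataclass
class TrainingSetSpec:
    """A named union of disjoint cohorts (hybrids/parents/uncles)."""

    name: str
    members: list[str]
    provenance: dict = field(default_factory=dict)  # cohort -> ids

    @property
    def size(self) -> int:
        return len(self.members)


def build_training_set(cohorts: dict, combo_name: str) -> TrainingSetSpec:
    """Assemble a combination like ``"H+P"`` from cohort id lists.

    ``cohorts`` maps single-letter names (H, P, U) to id lists; cohorts
    must be pairwise disjoint and a requested cohort may not be empty.
    """
    parts = combo_name.replace(" ", "").split("+")
    if not parts or any(not p for p in parts):
        raise AssessmentError(f"unknown training combo {combo_name!r}")
    seen: set = set()
    members: list[str] = []
    provenance = {}
    for p in parts:
        if p not in cohorts:
            raise AssessmentError(f"unknown cohort {p!r}")
        ids = [str(i) for i in cohorts[p]]
        if not ids:
            raise AssessmentError(f"cohort {p!r} is empty")
        overlap = seen & set(ids)
        if overlap:
            raise AssessmentError(f"cohorts are not disjoint: {sorted(overlap)[:5]}")
        seen |= set(ids)
        members += ids
        provenance[p] = ids
    return TrainingSetSpec(name=combo_name, members=members, provenance=provenance)


# ----------------------------------------------------------------------
# Paired metrics
# ----------------------------------------------------------------------
def _align(genomic, reference) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(genomic).astype(float)
    r = pd.Series(reference).astype(float)
    common = g.index.intersection(r.index)
    if len(common) < 3:
        raise AssessmentError("need at least 3 id-aligned pairs")
    g, r = g.loc[common], r.loc[common]
    if g.std() == 0 or r.std() == 0:
        raise AssessmentError("zero variance in one of the value vectors")
    return g.to_numpy(), r.to_numpy()


def realized_predictive_ability(genomic, reference) -> float:
    """Pearson correlation of id-aligned genomic vs reference values."""
    g, r = _align(genomic, reference)
    return float(np.corrcoef(g, r)[0, 1])


def prediction_bias(genomic, reference) -> float:
    """1 - b, b = OLS slope of reference on genomic (b > 1: underestimation)."""
    g, r = _align(genomic, reference)
    slope = float(np.cov(r, g)[0, 1] / np.var(g, ddof=1))
    return 1.0 - slope


def rank_concordance(genomic, reference) -> float:
    """Spearman rho (Pearson correlation of mid-ranked values)."""
    g, r = _align(genomic, reference)
    return float(stats.spearmanr(g, r).statistic)


def top_k_count(n: int, proportion: float) -> int:
    """Nearest-integer top-k with a minimum of 1 (197 x 2.5 % -> 5)."""
    if n <= 0:
        raise AssessmentError("empty candidate set")
    if not 0.0 < proportion <= 1.0:
        raise AssessmentError("selected proportion must lie in (0, 1]")
    return max(1, int(round(proportion * n)))


def coincidence_rate(genomic, reference, selected_proportion: float) -> float:
    """Percent overlap of the top-k by genomic vs reference ranking.

    Ties are broken deterministically by id order (stable sort on value
    descending, then id).
    """
    g = pd.Series(genomic).astype(float)
    r = pd.Series(reference).astype(float)
    common = g.index.intersection(r.index)
    if len(common) == 0:
        raise AssessmentError("empty candidate set")
    k = top_k_count(len(common), selected_proportion)

    def top(series: pd.Series) -> set:
        df = series.loc[common].rename("v").rename_axis("id").reset_index()
        df = df.sort_values(["v", "id"], ascending=[False, True], kind="mergesort")
        return set(df["id"].head(k))

    return 100.0 * len(top(g) & top(r)) / k


def family_assessment(
    values: pd.DataFrame, family_map: pd.Series, proportions: Sequence[float] = (0.5,)
) -> dict:
    """Family-mean metrics: RPA/Spearman/coincidence on per-family means.

    ``values`` has columns genomic, reference (id index); families with no
    scored members are skipped.
    """
    df = values.join(family_map.rename("family"), how="inner").dropna(subset=["family"])
    fam = df.groupby("family")[["genomic", "reference"]].mean()
    if len(fam) < 2:
        raise AssessmentError("need at least 2 families")
    out = {
        "family_means": fam,
        "n_families": len(fam),
        "rpa": realized_predictive_ability(fam["genomic"], fam["reference"]),
        "spearman": rank_concordance(fam["genomic"], fam["reference"]),
    }
    out["coincidence"] = {
        p: coincidence_rate(fam["genomic"], fam["reference"], p) for p in proportions
    }
    return out


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------
def assessment_report(
    genomic: pd.Series,
    reference: pd.Series,
    model: str,
    training_set: str,
    age: float,
    proportions: Sequence[float] = (0.025, 0.05, 0.10, 0.20, 0.50),
    family_map: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Tidy one-row-per-metric table for (model, training set, age)."""
    common = genomic.index.intersection(reference.index)
    base = {
        "model": model,
        "training_set": training_set,
        "age": age,
        "n_predicted": len(common),
    }
    rows = []
    try:
        rows.append({**base, "metric": "rpa", "value": realized_predictive_ability(genomic, reference)})
        rows.append({**base, "metric": "bias", "value": prediction_bias(genomic, reference)})
        rows.append({**base, "metric": "spearman", "value": rank_concordance(genomic, reference)})
        for p in proportions:
            rows.append(
                {**base, "metric": f"coincidence_{p:g}", "value": coincidence_rate(genomic, reference, p)}
            )
    except AssessmentError as exc:
        rows.append({**base, "metric": "rpa", "value": np.nan, "note": str(exc)})
    if family_map is not None:
        try:
            fam = family_assessment(
                pd.DataFrame({"genomic": genomic, "reference": reference}).dropna(),
                family_map,
            )
            rows.append({**base, "metric": "family_rpa", "value": fam["rpa"]})
        except AssessmentError as exc:
            rows.append({**base, "metric": "family_rpa", "value": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Cross-validation
# ----------------------------------------------------------------------
def make_folds(
    ids: Sequence[str],
    k: int,
    seed: int,
    family_map: Optional[pd.Series] = None,
) -> list[list[str]]:
    """Partition ids into k near-equal folds (stratified by family).

    With stratification whole families are kept in the same fold, which
    prevents full sibs from leaking across the train/test split.
    """
    ids = [str(i) for i in ids]
    if k < 2:
        raise AssessmentError("k must be >= 2")
    if k >= len(ids):
        raise AssessmentError("k-fold with fold size <= 1 is undefined")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    if family_map is not None:
        fams: dict = {}
        for i in ids:
            fams.setdefault(str(family_map.get(i, i)), []).append(i)
        groups = list(fams.values())
        rng.shuffle(groups)
        # greedy: smallest fold gets the next family
        for grp in groups:
            folds[min(range(k), key=lambda j: len(folds[j]))].extend(grp)
    else:
        perm = list(rng.permutation(ids))
        for j, i in enumerate(perm):
            folds[j % k].append(i)
    return [f for f in folds if f]


def cross_validate(
    fit_predict,
    reference: pd.Series,
    k: int = 10,
    seed: int = 0,
    family_map: Optional[pd.Series] = None,
) -> dict:
    """k-fold predictive ability for a caller-supplied model function.

    ``fit_predict(train_ids, test_ids) -> pd.Series`` returns predictions
    for the test ids; the per-fold predictive ability is the Pearson
    correlation against ``reference``; folds with undefined correlation
    are skipped and reported.
    """
    ids = [str(i) for i in reference.index]
    folds = make_folds(ids, k, seed, family_map=family_map)
    corrs, skipped = [], []
    for j, test in enumerate(folds):
        train = [i for i in ids if i not in set(test)]
        pred = fit_predict(train, test)
        try:
            corrs.append(realized_predictive_ability(pred, reference.loc[test]))
        except AssessmentError as exc:
            skipped.append((j, str(exc)))
    return {
        "mean_pa": float(np.mean(corrs)) if corrs else np.nan,
        "fold_pa": corrs,
        "skipped_folds": skipped,
        "n_folds": len(folds),
    }


def direct_validation(predictions: pd.Series, reference: pd.Series) -> float:
    """Single-correlation validation for disjoint train/test populations."""
    return realized_predictive_ability(predictions, reference)
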