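"""SNP/sample quality control, expected-frequency imputation, platform
merging and Mendelian parentage verification.

The imputation rule replaces a missing call by the most probable genotype
implied by the expected B-allele dosage 2p: homozygote 0 when 2p < 2/3,
heterozygote 1 when 2/3 <= 2p < 4/3, homozygote 2 when 2p >= 4/3 (both
interval boundaries left-closed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerDataError, MarkerMatrix
from .pedigree import Pedigree


class QCError(ValueError):
    pass


def filter_markers(
    m: MarkerMatrix, min_call_rate: float = 0.90, min_maf: float = 0.01
) -> MarkerMatrix:
    """Keep SNPs with call rate >= min_call_rate and MAF >= min_maf.

    Both thresholds are inclusive; SNP order is preserved. MAF is computed
    on non-missing calls; an all-missing SNP is always removed.
    """
    for t in (min_call_rate, min_maf):
        if not 0.0 <= t <= 1.0:
            raise QCError("thresholds must lie in [0, 1]")
    cr = m.call_rate_snps()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maf = m.maf()
    keep = (cr >= min_call_rate) & ~np.isnan(maf) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("no SNPs passed the marker filters", stacklevel=2)
    return m.select_snps(keep)


def filter_samples(m: MarkerMatrix, min_call_rate: float = 0.85) -> MarkerMatrix:
    """Keep individuals with call rate >= min_call_rate (inclusive)."""
    if not 0.0 <= min_call_rate <= 1.0:
        raise QCError("threshold must lie in [0, 1]")
    keep = m.call_rate_samples() >= min_call_rate
    if not keep.any():
        raise QCError("all samples removed by call-rate filter")
    return m.select_individuals(keep)


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Fill missing dosages with the genotype expected from 2p.

    Deterministic and idempotent: non-missing entries are untouched, and a
    second application is a no-op.
    """
    X = m.dosages.copy()
    miss = np.isnan(X)
    if not miss.any():
        return MarkerMatrix(m.ids, m.snp_ids, X)
    n_calls = (~miss).sum(axis=0)
    bad = np.flatnonzero(n_calls == 0)
    if bad.size:
        raise QCError(
            f"SNPs with zero calls cannot be imputed (e.g. {m.snp_ids[bad[0]]}); "
            "apply filter_markers first"
        )
    two_p = 2.0 * m.allele_freq()
    imputed = np.where(two_p < 2.0 / 3.0, 0.0, np.where(two_p < 4.0 / 3.0, 1.0, 2.0))
    X[miss] = np.broadcast_to(imputed, X.shape)[miss]
    return MarkerMatrix(m.ids, m.snp_ids, X)


def intersect_platforms(a: MarkerMatrix, b: MarkerMatrix) -> MarkerMatrix:
    """Merge two genotyping platforms on their shared SNPs.

    Columns are the snp-id intersection in ``a``'s order; rows are the
    concatenation of both individual sets (which must be disjoint).
    """
    dup = set(a.ids) & set(b.ids)
    if dup:
        raise QCError(f"duplicate individual ids across platforms: {sorted(dup)[:5]}")
    shared = [s for s in a.snp_ids if s in set(b.snp_ids)]
    if not shared:
        raise QCError("platforms share no SNPs")
    a_sub = a.select_snps([a.snp_ids.index(s) for s in shared])
    b_index = {s: k for k, s in enumerate(b.snp_ids)}
    b_sub = b.select_snps([b_index[s] for s in shared])
    return MarkerMatrix(
        a.ids + b.ids, shared, np.vstack([a_sub.dosages, b_sub.dosages])
    )


@dataclass
class ParentageReport:
    """Opposing-homozygote conflict rates per genotyped parent-offspring pair."""

    table: pd.DataFrame  # columns: offspring, parent, n_informative, conflict_rate, flagged
    skipped: list[tuple[str, str]]  # ungenotyped pairs

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def verify_parentage(
    m: MarkerMatrix, pedigree: Pedigree, max_conflict_rate: float = 0.01
) -> ParentageReport:
    """Check genotyped parent-offspring pairs for opposing homozygotes.

    The conflict rate of a pair is the fraction of SNPs (non-missing in
    both) where one member is dosage 0 and the other dosage 2 — impossible
    under true parentage barring genotyping error.
    """
    gset = {i: k for k, i in enumerate(m.ids)}
    rows = []
    skipped: list[tuple[str, str]] = []
    X = m.dosages
    for child, s, d in zip(pedigree.ids, pedigree.sires, pedigree.dams):
        if child not in gset:
            continue
        for parent in (s, d):
            if parent is None:
                continue
            if parent not in gset:
                skipped.append((child, parent))
                continue
            g_c = X[gset[child]]
            g_p = X[gset[parent]]
            ok = ~np.isnan(g_c) & ~np.isnan(g_p)
            n = int(ok.sum())
            conflicts = int(np.sum((np.abs(g_c - g_p) == 2.0) & ok))
            rate = conflicts / n if n else np.nan
            rows.append(
                {
                    "offspring": child,
                    "parent": parent,
                    "n_informative": n,
                    "conflict_rate": rate,
                    "flagged": bool(n and rate > max_conflict_rate),
                }
            )
    table = pd.DataFrame(
        rows, columns=["offspring", "parent", "n_informative", "conflict_rate", "flagged"]
    )
    return ParentageReport(table=table, skipped=skipped)
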