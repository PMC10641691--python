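"""SNP dosage matrix container and plain-text readers/writers.

Dosages follow the 0/1/2 B-allele count convention; missing calls are
``NaN``. Two interchange formats are supported: a delimited matrix with a
header row of SNP ids and a first column of individual ids, and a minimal
PLINK ``.raw``-style dialect (FID IID PAT MAT SEX PHENOTYPE then one column
per SNP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING_CODES = ("NA", "na", "-9", "")


class MarkerDataError(ValueError):
    pass


@dataclass
class MarkerMatrix:
    """Individuals × SNPs dosage matrix.

    ``dosages`` is float (NaN = missing); values must be in {0, 1, 2, NaN}.
    """

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise MarkerDataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} snps"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise MarkerDataError("dosages must be 0, 1, 2 or missing")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP B-allele frequency p on non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def select_snps(self, mask) -> "MarkerMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MarkerMatrix(
            self.ids,
            [self.snp_ids[j] for j in idx],
            self.dosages[:, idx],
        )

    def select_individuals(self, which) -> "MarkerMatrix":
        """Subset/reorder rows by boolean mask, positions, or id list."""
        which = list(which)
        if which and isinstance(which[0], str):
            index = {i: k for k, i in enumerate(self.ids)}
            missing = [i for i in which if i not in index]
            if missing:
                raise MarkerDataError(f"ids not genotyped: {missing[:5]}")
            idx = np.array([index[i] for i in which])
        else:
            arr = np.asarray(which)
            idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return MarkerMatrix(
            [self.ids[k] for k in idx],
            self.snp_ids,
            self.dosages[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)

    # -- plain-text IO --------------------------------------------------
    def write_csv(self, path, sep: str = ",") -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep=sep, na_rep="NA")

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "MarkerMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(MISSING_CODES))
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))

    def write_raw(self, path) -> None:
        """PLINK .raw-style dialect (space separated, NA for missing)."""
        df = self.to_frame()
        out = pd.DataFrame(
            {
                "FID": self.ids,
                "IID": self.ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")

    @classmethod
    def read_raw(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, sep=r"\s+", na_values=list(MISSING_CODES))
        snp_cols = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
        return cls(
            list(df["IID"].astype(str)),
            snp_cols,
            df[snp_cols].to_numpy(float),
        )
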