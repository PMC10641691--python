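"""Pedigree container: parentage records, topological order, inbreeding.

A pedigree is a directed acyclic graph of (individual, sire, dam) records.
Unknown parents are represented by ``None``. Individuals are re-ordered
internally so that parents always precede offspring (topological order),
which is what the tabular relationship-matrix recursions require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

UNKNOWN = None
#: sentinels accepted in input tables for an unknown parent
_UNKNOWN_CODES = {None, "", "0", 0, "NA", "na", ".", "unknown"}


class PedigreeError(ValueError):
    """Raised for structural problems (cycles, missing parents)."""


def _clean_parent(value) -> Optional[str]:
    if value in _UNKNOWN_CODES:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    return str(value)


@dataclass
class Pedigree:
    """Parentage records with optional generation/species/trial annotations.

    Parameters
    ----------
    ids, sires, dams
        Parallel sequences. Parents may be ``None`` (unknown). Every named
        parent must itself appear as an individual.
    meta
        Optional DataFrame indexed by individual id with columns such as
        ``generation``, ``species``, ``trial``, ``block``, ``family``.
    """

    ids: list[str]
    sires: list[Optional[str]]
    dams: list[Optional[str]]
    meta: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.sires = [_clean_parent(s) for s in self.sires]
        self.dams = [_clean_parent(d) for d in self.dams]
        if len({len(self.ids), len(self.sires), len(self.dams)}) != 1:
            raise PedigreeError("ids, sires, dams must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        known = set(self.ids)
        for p in self.sires + self.dams:
            if p is not None and p not in known:
                raise PedigreeError(f"parent {p!r} has no own record")
        self._order = self._topological_order()
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    # ------------------------------------------------------------------
    def _topological_order(self) -> list[int]:
        """Kahn's algorithm; raises on cycles."""
        idx = {iid: k for k, iid in enumerate(self.ids)}
        n = len(self.ids)
        n_unmet = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for k, (s, d) in enumerate(zip(self.sires, self.dams)):
            for p in (s, d):
                if p is not None:
                    n_unmet[k] += 1
                    children[idx[p]].append(k)
        ready = [k for k in range(n) if n_unmet[k] == 0]
        order: list[int] = []
        while ready:
            k = ready.pop()
            order.append(k)
            for c in children[k]:
                n_unmet[c] -= 1
                if n_unmet[c] == 0:
                    ready.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        return order

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def topological_ids(self) -> list[str]:
        return [self.ids[k] for k in self._order]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire, dam) positional indices into ``self.ids``; -1 = unknown."""
        s = np.array([-1 if p is None else self._index[p] for p in self.sires])
        d = np.array([-1 if p is None else self._index[p] for p in self.dams])
        return s, d

    def inbreeding(self) -> pd.Series:
        """Wright's inbreeding coefficients F_i (from the tabular A diagonal)."""
        from .kinship import build_A  # local import avoids a cycle

        A = build_A(self)
        return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="F")

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sire": [s if s is not None else "" for s in self.sires],
                "dam": [d if d is not None else "" for d in self.dams],
            }
        )
        if self.meta is not None:
            df = df.merge(
                self.meta.reset_index().rename(columns={"index": "id"}),
                on="id",
                how="left",
            )
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        meta_cols = [c for c in df.columns if c not in ("id", "sire", "dam")]
        meta = df.set_index("id")[meta_cols] if meta_cols else None
        return cls(
            ids=list(df["id"]),
            sires=list(df["sire"]),
            dams=list(df["dam"]),
            meta=meta,
        )

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def subset_meta(self, column: str, values: Iterable) -> list[str]:
        """Ids whose metadata ``column`` is in ``values``."""
        if self.meta is None:
            raise PedigreeError("pedigree carries no metadata")
        vals = set(values)
        return [i for i in self.ids if self.meta.loc[i, column] in vals]
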