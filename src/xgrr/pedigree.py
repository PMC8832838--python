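"""Sexed pedigree container.

A pedigree is a topologically ordered table of individuals with optional
sire/dam links and a binary sex. It is the backbone for the autosomal (A)
and X-linked (S) relationship matrices, Y-lineage grouping, gene dropping
and the pedigree recursions used to simulate polygenic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"
MALE = "M"
FEMALE = "F"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class Pedigree:
    """Topologically ordered sexed pedigree.

    Parameters
    ----------
    table
        DataFrame with columns ``id``, ``sire``, ``dam``, ``sex``; ``"0"``
        marks an unknown parent, sex is ``"M"`` or ``"F"``. Rows may arrive
        in any order; construction sorts parents before offspring and
        validates sex consistency, uniqueness and acyclicity.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["id", "sire", "dam", "sex"]
        if list(df.columns[:4]) != required:
            df = df[required]
        for c in required:
            df[c] = df[c].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        if (df["id"] == UNKNOWN).any():
            raise PedigreeError(f"{UNKNOWN!r} is reserved for unknown parents")
        bad_sex = ~df["sex"].isin([MALE, FEMALE])
        if bad_sex.any():
            raise PedigreeError(f"invalid sex {df.loc[bad_sex, 'sex'].iloc[0]!r}")
        sex_of = dict(zip(df["id"], df["sex"]))
        for col, want, word in (("sire", MALE, "sire"), ("dam", FEMALE, "dam")):
            named = df[col][df[col] != UNKNOWN]
            for pid in named:
                if pid in sex_of and sex_of[pid] != want:
                    raise PedigreeError(
                        f"{word} {pid!r} is recorded with sex {sex_of[pid]!r}"
                    )
        df = _toposort(df)
        self.table = df.reset_index(drop=True)
        self._index = {iid: k for k, iid in enumerate(self.table["id"])}

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def is_male(self, iid: str) -> bool:
        return self.table["sex"].iloc[self._index[iid]] == MALE

    def sex_array(self) -> np.ndarray:
        return self.table["sex"].to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer sire/dam indices in topological order, -1 for unknown."""
        sire = np.array(
            [self._index.get(s, -1) for s in self.table["sire"]], dtype=np.int64
        )
        dam = np.array(
            [self._index.get(d, -1) for d in self.table["dam"]], dtype=np.int64
        )
        return sire, dam

    def ancestor_closure(self, ids) -> "Pedigree":
        """Sub-pedigree of ``ids`` and all their ancestors.

        Parents outside the closure never occur (ancestors are closed
        under the parent relation), so the result is a valid pedigree.
        """
        sire, dam = self.parent_indices()
        keep = np.zeros(self.n, dtype=bool)
        stack = [self._index[i] for i in ids]
        while stack:
            k = stack.pop()
            if keep[k]:
                continue
            keep[k] = True
            for p in (sire[k], dam[k]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        return Pedigree(self.table.loc[keep])


def _toposort(df: pd.DataFrame) -> pd.DataFrame:
    """Order parents before offspring; raise on cycles or missing order."""
    ids = df["id"].to_list()
    pos = {iid: k for k, iid in enumerate(ids)}
    sire = [pos.get(s, -1) for s in df["sire"]]
    dam = [pos.get(d, -1) for d in df["dam"]]
    n = len(ids)
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done
    order: list[int] = []
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, 0)]
        while stack:
            node, phase = stack.pop()
            if phase == 0:
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise PedigreeError("pedigree contains a cycle")
                state[node] = 1
                stack.append((node, 1))
                for p in (sire[node], dam[node]):
                    if p >= 0 and state[p] != 2:
                        if state[p] == 1:
                            raise PedigreeError(
                                f"pedigree contains a cycle through {ids[p]!r}"
                            )
                        stack.append((p, 0))
            else:
                state[node] = 2
                order.append(node)
    return df.iloc[order]
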