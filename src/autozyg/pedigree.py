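"""Pedigree inbreeding: Wright's F via memoized kinship recursion.

The inbreeding coefficient of an animal is the kinship (coancestry) of its
parents; kinship is computed by the classical recursive rule, which is
equivalent to the tabular method but touches only the ancestor pairs a
query actually needs.  Any animal with an unknown parent gets F = 0
(founders are assumed unrelated and non-inbred).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd


class Pedigree:
    """Acyclic pedigree: animal -> (sire, dam, birth_year).

    Parents named but never listed as animals are treated as founders.
    Construction verifies acyclicity and reports one cycle on failure.
    """

    def __init__(
        self,
        parents: Mapping[str, tuple[Optional[str], Optional[str]]],
        birth_year: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
        for animal, (sire, dam) in parents.items():
            self.parents[str(animal)] = (
                str(sire) if sire is not None else None,
                str(dam) if dam is not None else None,
            )
        # implicit founders: named parents without their own record
        for sire, dam in list(self.parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self.birth_year = dict(birth_year) if birth_year else {}
        self._depth: dict[str, int] = {}
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._check_acyclic_and_depths()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam[, birth_year]."""
        parents = {}
        years = {}
        for row in df.itertuples(index=False):
            sire = None if pd.isna(row.sire) or row.sire in ("0", None) else str(row.sire)
            dam = None if pd.isna(row.dam) or row.dam in ("0", None) else str(row.dam)
            parents[str(row.animal)] = (sire, dam)
            if hasattr(row, "birth_year") and not pd.isna(row.birth_year):
                years[str(row.animal)] = int(row.birth_year)
        return cls(parents, years)

    def animals(self) -> list[str]:
        return list(self.parents)

    def is_founder(self, animal: str) -> bool:
        s, d = self.parents.get(animal, (None, None))
        return s is None and d is None

    # -- internals ----------------------------------------------------------

    def _check_acyclic_and_depths(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {a: WHITE for a in self.parents}
        for start in self.parents:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            path: list[str] = []
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if color[node] == BLACK:
                        continue
                    if color[node] == GREY:
                        i = path.index(node)
                        cycle = path[i:] + [node]
                        raise ValueError(
                            "pedigree contains a cycle: " + " -> ".join(cycle)
                        )
                    color[node] = GREY
                    path.append(node)
                    stack.append((node, 1))
                    for p in self.parents[node]:
                        if p is not None:
                            if color[p] == GREY:
                                i = path.index(p)
                                raise ValueError(
                                    "pedigree contains a cycle: "
                                    + " -> ".join(path[i:] + [p])
                                )
                            if color[p] == WHITE:
                                stack.append((p, 0))
                else:
                    color[node] = BLACK
                    path.pop()
                    d = 0
                    for p in self.parents[node]:
                        if p is not None:
                            d = max(d, self._depth[p] + 1)
                    self._depth[node] = d

    def _kinship(self, a: Optional[str], b: Optional[str]) -> float:
        """Coancestry f(a, b); unknown (None) contributes 0."""
        if a is None or b is None:
            return 0.0
        if a == b:
            key = (a, a)
            hit = self._kin_cache.get(key)
            if hit is not None:
                return hit
            s, d = self.parents[a]
            val = 0.5 * (1.0 + self._kinship(s, d))
            self._kin_cache[key] = val
            return val
        key = (a, b) if a < b else (b, a)
        hit = self._kin_cache.get(key)
        if hit is not None:
            return hit
        # recurse on the deeper animal so ancestors terminate at founders
        if self._depth[a] < self._depth[b]:
            a, b = b, a
        s, d = self.parents[a]
        if s is None and d is None:
            val = 0.0  # distinct founders are unrelated
        else:
            val = 0.5 * (self._kinship(s, b) + self._kinship(d, b))
        self._kin_cache[key] = val
        return val


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Kinship (coancestry) of two pedigree members.

    Symmetric; 0 for distinct founders; kinship(x, x) = (1 + F(x)) / 2.
    """
    for x in (a, b):
        if str(x) not in ped.parents:
            raise KeyError(f"unknown animal id: {x!r}")
    return ped._kinship(str(a), str(b))


def inbreeding(ped: Pedigree, animal: str) -> float:
    """Wright's F for one animal: the kinship of its parents (0 if any unknown)."""
    if str(animal) not in ped.parents:
        raise KeyError(f"unknown animal id: {animal!r}")
    s, d = ped.parents[str(animal)]
    if s is None or d is None:
        return 0.0
    return ped._kinship(s, d)


def compute_fped(ped: Pedigree, animals: Optional[Iterable[str]] = None) -> pd.Series:
    """FPED for every animal (or the given subset), as a float Series.

    Founders and animals with any unknown parent get 0, matching the
    convention that animals without recorded ancestors are non-inbred.
    """
    ids = list(ped.parents) if animals is None else [str(a) for a in animals]
    vals = np.array([inbreeding(ped, a) for a in ids])
    if ((vals < 0) | (vals >= 1)).any():
        raise AssertionError("inbreeding coefficients outside [0, 1)")
    return pd.Series(vals, index=ids, name="fped")


def write_fped(f: pd.Series, path) -> None:
    f.rename_axis("animal").to_csv(path, sep="\t", header=["fped"])
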