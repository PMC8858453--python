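"""Core in-memory containers shared across the pipeline.

Genotypes are dosage-coded (0/1/2 copies of the alternate allele),
haplotypes allele-coded (0/1), both stored as small integer arrays with a
single MISSING sentinel.  Pedigrees are directed acyclic parent maps with
generation, breed and sample-availability metadata; generation 1 is the
most recent generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype or haplotype allele.
MISSING: int = -1

#: Parent code meaning "unknown".
UNKNOWN: str = "0"

MARKER_MAP_COLUMNS = ("chrom", "marker_id", "cm", "bp")


def make_marker_map(
    chrom: Sequence[int],
    bp: Sequence[int],
    cm: Sequence[float] | None = None,
    marker_id: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a marker map frame (chrom, marker_id, cm, bp).

    Positions must be strictly increasing within each chromosome; bp
    positions are 1-based as in PLINK ``.map`` files.
    """
    chrom = np.asarray(chrom)
    bp = np.asarray(bp, dtype=np.int64)
    n = len(bp)
    if cm is None:
        cm = np.zeros(n, dtype=float)
    if marker_id is None:
        marker_id = [f"M{c}_{p}" for c, p in zip(chrom, bp)]
    mm = pd.DataFrame(
        {"chrom": chrom, "marker_id": list(marker_id), "cm": np.asarray(cm, float), "bp": bp}
    )
    for _, grp in mm.groupby("chrom", sort=False):
        d = np.diff(grp["bp"].to_numpy())
        if len(d) and (d <= 0).any():
            raise ValueError("bp positions must be strictly increasing within a chromosome")
    return mm


@dataclass
class GenotypeMatrix:
    """Animals x markers dosage matrix, values in {0,1,2,MISSING}."""

    ids: list[str]
    values: np.ndarray  # (n_animals, n_markers) int8
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of animal ids")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("column count does not match marker map")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.values.copy(), self.markers.copy())

    def row(self, animal_id: str) -> np.ndarray:
        return self.values[self.ids.index(animal_id)]

    def subset_animals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.ids.index(i) for i in ids]
        return GenotypeMatrix([self.ids[i] for i in idx], self.values[idx].copy(), self.markers)

    def subset_markers(self, marker_idx: Sequence[int]) -> "GenotypeMatrix":
        marker_idx = np.asarray(marker_idx, dtype=int)
        return GenotypeMatrix(
            list(self.ids),
            self.values[:, marker_idx].copy(),
            self.markers.iloc[marker_idx].reset_index(drop=True),
        )


@dataclass
class HaplotypeMatrix:
    """Two phased haplotypes per animal; rows 2i and 2i+1 belong to animal i."""

    ids: list[str]
    values: np.ndarray  # (2*n_animals, n_markers) int8, alleles {0,1,MISSING}
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape[0] != 2 * len(self.ids):
            raise ValueError("haplotype matrix must have exactly two rows per animal")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("column count does not match marker map")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def animal_haplotypes(self, animal_id: str) -> np.ndarray:
        i = self.ids.index(animal_id)
        return self.values[2 * i : 2 * i + 2]

    def subset_animals(self, ids: Iterable[str]) -> "HaplotypeMatrix":
        idx = [self.ids.index(i) for i in ids]
        rows = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
        return HaplotypeMatrix([self.ids[i] for i in idx], self.values[rows].copy(), self.markers)

    def to_genotypes(self) -> GenotypeMatrix:
        """Sum allele pairs into dosages; any missing allele yields MISSING."""
        h = self.values
        g = h[0::2].astype(np.int16) + h[1::2].astype(np.int16)
        g[(h[0::2] == MISSING) | (h[1::2] == MISSING)] = MISSING
        return GenotypeMatrix(list(self.ids), g.astype(np.int8), self.markers)


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Directed acyclic parent map with per-animal metadata.

    The underlying frame has columns id, sire, dam, sex ('M'/'F'),
    generation (1 = most recent), breed, available (bool).  Unknown parents
    are coded UNKNOWN ("0").
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    REQUIRED = ("id", "sire", "dam", "sex", "generation", "breed", "available")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing_cols:
            raise PedigreeError(f"pedigree table lacks columns: {missing_cols}")
        t = self.table.reset_index(drop=True).copy()
        t["id"] = t["id"].astype(str)
        t["sire"] = t["sire"].astype(str).replace("", UNKNOWN)
        t["dam"] = t["dam"].astype(str).replace("", UNKNOWN)
        t["available"] = t["available"].astype(bool)
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate animal id: {dup}")
        self.table = t
        self._index = {a: k for k, a in enumerate(t["id"])}
        known = set(self._index)
        for col in ("sire", "dam"):
            bad = t.loc[(t[col] != UNKNOWN) & ~t[col].isin(known), col]
            if len(bad):
                raise PedigreeError(f"{col} {bad.iloc[0]!r} has no pedigree record")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self._topological_or_cycle()
        if isinstance(order, str):
            raise PedigreeError(f"pedigree contains a cycle through animal {order!r}")

    def _topological_or_cycle(self):
        """Kahn's algorithm over parent->offspring edges; returns order or a cycle member id."""
        t = self.table
        n = len(t)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for k, (s, d) in enumerate(zip(t["sire"], t["dam"])):
            for p in (s, d):
                if p != UNKNOWN:
                    children[self._index[p]].append(k)
                    indeg[k] += 1
        queue = [k for k in range(n) if indeg[k] == 0]
        order: list[int] = []
        while queue:
            k = queue.pop()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            stuck = int(np.nonzero(indeg > 0)[0][0])
            return str(t["id"].iloc[stuck])
        return order

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, animal_id: str) -> bool:
        return str(animal_id) in self._index

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def parents(self, animal_id: str) -> tuple[str, str]:
        k = self._index[str(animal_id)]
        return self.table["sire"].iat[k], self.table["dam"].iat[k]

    def breed_of(self, animal_id: str) -> str:
        return self.table["breed"].iat[self._index[str(animal_id)]]

    def is_available(self, animal_id: str) -> bool:
        return bool(self.table["available"].iat[self._index[str(animal_id)]])

    @property
    def founders(self) -> list[str]:
        t = self.table
        m = (t["sire"] == UNKNOWN) & (t["dam"] == UNKNOWN)
        return list(t.loc[m, "id"])

    def topological_order(self) -> list[str]:
        """Animal ids with every known parent preceding its offspring."""
        order = self._topological_or_cycle()
        return [self.table["id"].iat[k] for k in order]

    def generation_members(self, generation: int) -> list[str]:
        t = self.table
        return list(t.loc[t["generation"] == generation, "id"])

    def breeds(self) -> list[str]:
        return list(dict.fromkeys(self.table["breed"]))
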