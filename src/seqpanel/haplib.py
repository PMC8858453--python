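"""Haplotype cores and the per-core haplotype library.

Chromosomes are cut into cores of consecutive SNPs (default 100, the
recommended window for ~60k chip density); within each core every distinct
haplotype string is catalogued with its population frequency and its
carriers.  Call-rate gates (90% per SNP, 90% per individual) are applied
before library construction; a haplotype with any remaining missing allele
inside a core is excluded from that core only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, HaplotypeMatrix


@dataclass(frozen=True)
class Core:
    chrom: int
    start: int  # global marker index, half-open [start, end)
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CorePartition:
    """Contiguous, non-overlapping cores covering every marker per chromosome."""

    cores: list[Core]

    def __len__(self) -> int:
        return len(self.cores)

    def __iter__(self):
        return iter(self.cores)


def partition_cores(marker_map: pd.DataFrame, core_length: int = 100) -> CorePartition:
    """Cut each chromosome into cores of ``core_length`` consecutive SNPs.

    A terminal remainder of at least half a core length becomes its own
    core; a shorter remainder is merged into the previous core.  A
    chromosome shorter than the core length forms a single core.
    """
    if core_length < 2:
        raise ValueError("core_length must be >= 2")
    cores: list[Core] = []
    chrom = marker_map["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        lo, n = int(idx[0]), len(idx)
        if n < 2:
            raise ValueError(f"chromosome {c} has fewer than 2 markers")
        starts = list(range(0, n, core_length))
        remainder = n - starts[-1]
        if len(starts) > 1 and remainder * 2 < core_length:
            starts.pop()  # merge short remainder into the previous core
        bounds = starts + [n]
        for s, e in zip(bounds[:-1], bounds[1:]):
            cores.append(Core(int(c), lo + s, lo + e))
    return CorePartition(cores)


@dataclass
class CoreLibrary:
    """Distinct haplotypes of one core with frequencies and carriers."""

    core: Core
    marker_idx: np.ndarray          # global indices of included markers
    haplotypes: list[str]           # distinct allele strings, most frequent first
    frequencies: np.ndarray         # same order, sums to 1 over included copies
    carriers: list[Counter]         # per haplotype: animal id -> copy count
    n_included_copies: int
    empty: bool = False

    def frequency_of(self, hap: str) -> float:
        return float(self.frequencies[self.haplotypes.index(hap)])


@dataclass
class HaplotypeLibrary:
    cores: list[CoreLibrary]
    included_animals: list[str]
    excluded_animals: list[str] = field(default_factory=list)
    excluded_markers: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cores)

    def __iter__(self):
        return iter(self.cores)


def build_library(
    H: HaplotypeMatrix,
    partition: CorePartition,
    snp_callrate_min: float = 0.90,
    ind_callrate_min: float = 0.90,
) -> HaplotypeLibrary:
    """Catalogue distinct core haplotypes with frequencies and carriers.

    Markers below ``snp_callrate_min`` (over all haplotype rows) and
    individuals below ``ind_callrate_min`` (over both haplotypes) are
    excluded genome-wide first; then, per core, any haplotype still
    carrying a missing allele is dropped from that core's denominator.
    """
    v = H.values
    obs = v != MISSING
    snp_cr = obs.mean(axis=0)
    keep_snp = snp_cr >= snp_callrate_min
    ind_cr = 0.5 * (obs[0::2].mean(axis=1) + obs[1::2].mean(axis=1))
    keep_ind = ind_cr >= ind_callrate_min

    included = [a for a, k in zip(H.ids, keep_ind) if k]
    excluded = [a for a, k in zip(H.ids, keep_ind) if not k]
    hap_rows = np.nonzero(np.repeat(keep_ind, 2))[0]
    hap_owner = np.repeat(np.asarray(H.ids, dtype=object), 2)[hap_rows]
    sub = v[hap_rows]

    cores: list[CoreLibrary] = []
    for core in partition:
        span = np.arange(core.start, core.end)
        m_idx = span[keep_snp[span]]
        block = sub[:, m_idx]
        complete = ~(block == MISSING).any(axis=1)
        counts: Counter = Counter()
        carriers: dict[str, Counter] = {}
        for row, owner in zip(block[complete], hap_owner[complete]):
            s = "".join(str(int(x)) for x in row)
            counts[s] += 1
            carriers.setdefault(s, Counter())[owner] += 1
        total = sum(counts.values())
        if total == 0 or len(m_idx) == 0:
            cores.append(
                CoreLibrary(core, m_idx, [], np.empty(0), [], 0, empty=True)
            )
            continue
        # most frequent first; ties by allele string for determinism
        ordered = sorted(counts, key=lambda s: (-counts[s], s))
        freqs = np.array([counts[s] / total for s in ordered])
        cores.append(
            CoreLibrary(core, m_idx, ordered, freqs, [carriers[s] for s in ordered], total)
        )
    return HaplotypeLibrary(
        cores,
        included_animals=included,
        excluded_animals=excluded,
        excluded_markers=[int(j) for j in np.nonzero(~keep_snp)[0]],
    )


def write_library(lib: HaplotypeLibrary, path: str | Path) -> None:
    """Serialize as TSV: core index, chrom, start, end, haplotype, frequency, n_carriers."""
    with open(path, "w") as fh:
        fh.write("core\tchrom\tstart\tend\thaplotype\tfrequency\tn_carriers\n")
        for k, cl in enumerate(lib.cores):
            for s, f, car in zip(cl.haplotypes, cl.frequencies, cl.carriers):
                fh.write(
                    f"{k}\t{cl.core.chrom}\t{cl.core.start}\t{cl.core.end}\t{s}\t"
                    f"{f:.10g}\t{len(car)}\n"
                )
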