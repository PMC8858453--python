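"""Breed-specific marker quality control.

Rules, applied in a fixed order: (1) call rate < 95% removed, (2) MAF < 1%
removed, (3) windowed LD pruning — within 3 kb, of any pair with genotypic
r^2 > 0.8 the left (smaller-position) marker is kept.  Per-animal call
rates are reported but animals are never dropped here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix


@dataclass
class MarkerStats:
    maf: np.ndarray          # per marker, NaN when every entry is missing
    call_rate: np.ndarray    # per marker
    animal_call_rate: np.ndarray


@dataclass
class QCReport:
    """Per-rule removal counts and the surviving marker indices."""

    n_input: int
    removed_callrate: list[int] = field(default_factory=list)
    removed_maf: list[int] = field(default_factory=list)
    removed_ld: list[int] = field(default_factory=list)
    surviving: list[int] = field(default_factory=list)
    rule_order: tuple[str, ...] = ("call_rate", "maf", "ld_prune")

    def __post_init__(self) -> None:
        n_removed = len(self.removed_callrate) + len(self.removed_maf) + len(self.removed_ld)
        if n_removed + len(self.surviving) != self.n_input:
            raise ValueError("removed + surviving must equal the input marker count")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "rule_order": list(self.rule_order),
            "n_removed_callrate": len(self.removed_callrate),
            "n_removed_maf": len(self.removed_maf),
            "n_removed_ld": len(self.removed_ld),
            "removed_callrate": self.removed_callrate,
            "removed_maf": self.removed_maf,
            "removed_ld": self.removed_ld,
            "surviving": self.surviving,
        }


def marker_stats(G: GenotypeMatrix) -> MarkerStats:
    """Per-marker MAF and call rate, plus per-animal call rate.

    MAF = min(p, 1-p) with p the mean non-missing dosage / 2; markers with
    no non-missing entry get MAF = NaN.
    """
    v = G.values
    if v.shape[0] == 0:
        raise ValueError("genotype matrix has zero animals")
    obs = v != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(obs, v, 0).sum(axis=0) / (2.0 * n_obs), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return MarkerStats(
        maf=maf,
        call_rate=n_obs / v.shape[0],
        animal_call_rate=obs.sum(axis=1) / v.shape[1],
    )


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete animals.

    Returns NaN when fewer than two complete pairs remain or either column
    has zero variance among them.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("columns have different lengths")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    sx = (xs**2).sum()
    sy = (ys**2).sum()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = (xs * ys).sum() / np.sqrt(sx * sy)
    return float(r * r)


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
    r2_max: float = 0.8,
    window_bp: int = 3000,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate, MAF and windowed LD filters; return survivors + report.

    LD pruning scans each chromosome left to right: a marker is dropped if
    any already-kept marker within ``window_bp`` (inclusive) has r^2 above
    ``r2_max`` with it, so the left member of a high-LD pair survives.
    """
    stats = marker_stats(G)
    n = G.n_markers
    removed_cr = [j for j in range(n) if stats.call_rate[j] < callrate_min]
    alive = np.ones(n, dtype=bool)
    alive[removed_cr] = False
    removed_maf = [
        j for j in range(n) if alive[j] and (np.isnan(stats.maf[j]) or stats.maf[j] < maf_min)
    ]
    alive[removed_maf] = False

    removed_ld: list[int] = []
    bp = G.markers["bp"].to_numpy()
    chrom = G.markers["chrom"].to_numpy()
    for c in np.unique(chrom):
        idx = [j for j in np.nonzero(chrom == c)[0] if alive[j]]
        kept: list[int] = []
        for j in idx:
            pruned = False
            for i in reversed(kept):
                if bp[j] - bp[i] > window_bp:
                    break
                r2 = ld_r2(G.values[:, i], G.values[:, j])
                if not np.isnan(r2) and r2 > r2_max:
                    pruned = True
                    break
            if pruned:
                removed_ld.append(j)
                alive[j] = False
            else:
                kept.append(j)

    surviving = [j for j in range(n) if alive[j]]
    report = QCReport(
        n_input=n,
        removed_callrate=removed_cr,
        removed_maf=removed_maf,
        removed_ld=sorted(removed_ld),
        surviving=surviving,
    )
    return G.subset_markers(surviving), report
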