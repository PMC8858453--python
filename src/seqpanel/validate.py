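"""Masking/imputation validation of reference-panel choices.

A chosen panel keeps its full genotypes; every other animal becomes a
target whose genotypes are masked at a random SNP subset — either a fixed
count (LD1, emulating a lower-density chip) or half of all markers (LD2).
Targets are imputed back from the panel and scored as the Pearson
correlation r between true genotype and imputed dosage, per masked marker
across targets, stratified by minor allele frequency class
(1-3%, 3-5%, >5%).  Repetitions give the mean/min/max per cell; a random
panel is additionally averaged over independent panel draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypeMatrix, Pedigree
from .genio import ReportTable
from .haplib import CorePartition
from .impute import DosageMatrix, impute
from .qc import marker_stats

logger = logging.getLogger("seqpanel")

MAF_CLASSES = (("1-3%", 0.01, 0.03), ("3-5%", 0.03, 0.05), (">5%", 0.05, 0.5))

#: LD1 masks this fraction of surviving markers when no count is given
#: (the fixed-chip-count scenario expressed as a fraction).
LD1_FRACTION = 0.231


@dataclass
class MaskPlan:
    """Masked marker sets per replicate for one scenario."""

    scenario: str                 # "LD1" or "LD2"
    masked: list[np.ndarray]      # per replicate, sorted marker indices
    seeds: list[int]

    def __post_init__(self) -> None:
        if self.scenario not in ("LD1", "LD2"):
            raise ValueError("scenario must be LD1 or LD2")


def make_mask(
    marker_map: pd.DataFrame,
    scenario: str,
    n_snps_or_fraction: float | int | None,
    n_replicates: int,
    seed: int,
) -> MaskPlan:
    """Draw per-replicate masked marker sets (uniform, without replacement).

    The same masked set applies to every target animal of a replicate
    (chip-panel semantics); the reference panel is never masked.  LD2
    always masks half of the markers; LD1 masks ``n_snps_or_fraction``
    (a count if > 1, else a fraction; default 23.1% of the markers).
    """
    m = len(marker_map)
    if scenario == "LD2":
        count = m // 2
    elif n_snps_or_fraction is None:
        count = int(np.floor(LD1_FRACTION * m))
    elif n_snps_or_fraction > 1:
        # a fixed chip count scales down to at most 23.1% of the markers
        count = min(int(n_snps_or_fraction), int(np.floor(LD1_FRACTION * m)))
    else:
        count = int(np.floor(n_snps_or_fraction * m))
    if count > m:
        raise ValueError(f"cannot mask {count} of {m} markers")
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    masked, seeds = [], []
    for child in ss:
        rng = np.random.default_rng(child)
        masked.append(np.sort(rng.choice(m, size=count, replace=False)))
        seeds.append(int(child.generate_state(1)[0] % (2**31)))
    return MaskPlan(scenario, masked, seeds)


@dataclass
class ClassAccuracy:
    """Per-MAF-class mean of per-marker correlations for one imputation run."""

    mean_r: dict            # class label -> mean r (np.nan when class empty)
    n_markers: dict         # class label -> markers scored
    n_zero_variance: int    # masked markers excluded for constant truth


def imputation_accuracy(
    true: GenotypeMatrix,
    imputed: DosageMatrix,
    masked: np.ndarray,
    maf: np.ndarray,
) -> ClassAccuracy:
    """Score one run: per masked marker, r(truth, dosage) across targets.

    Markers whose true genotypes are constant among the targets are
    excluded (r undefined) and counted; a marker with varying truth but a
    constant imputed dosage scores r = 0 (the dosage carries no signal).
    Markers are binned by pre-masking MAF into (1,3], (3,5] and (5,50]%.
    """
    t = true.values[:, masked].astype(float)
    d = imputed.values[:, masked]
    tc = t - t.mean(axis=0)
    dc = d - d.mean(axis=0)
    st = (tc**2).sum(axis=0)
    sd = (dc**2).sum(axis=0)
    valid = st > 1e-12
    r = np.zeros(len(masked))
    informative = valid & (sd > 1e-12)
    r[informative] = (tc * dc).sum(axis=0)[informative] / np.sqrt(st[informative] * sd[informative])

    mean_r, n_markers = {}, {}
    m_maf = np.asarray(maf)[masked]
    for label, lo, hi in MAF_CLASSES:
        in_class = valid & (m_maf > lo) & (m_maf <= hi)
        n_markers[label] = int(in_class.sum())
        mean_r[label] = float(r[in_class].mean()) if in_class.any() else float("nan")
    n_zero = int((~valid).sum())
    if n_zero:
        logger.debug("%d masked markers with constant truth excluded", n_zero)
    return ClassAccuracy(mean_r, n_markers, n_zero)


def run_validation_experiment(
    G: GenotypeMatrix,
    H_true: HaplotypeMatrix,
    pedigree: Pedigree,
    panels: Mapping[str, Sequence[Sequence[str]]],
    partition: CorePartition,
    scenarios: Sequence[str] = ("LD1", "LD2"),
    n_repetitions: int = 20,
    ld1_snps: float | int | None = None,
    seed: int = 0,
) -> ReportTable:
    """Mask, impute and score every panel under every scenario.

    ``panels`` maps a label to one or more panel draws (a single draw for
    the combined/haplotype panels, many for the random baseline); draws of
    one label are averaged within each repetition, and mean/min/max per
    cell are taken over repetitions.  All panels of a run share the mask
    plan, so differences are attributable to panel composition alone.
    """
    breeds = pedigree.breeds()
    breed = breeds[0] if len(breeds) == 1 else "ALL"
    maf = marker_stats(G).maf
    all_ids = list(G.ids)

    sizes = {len(draw) for draws in panels.values() for draw in draws}
    if len(sizes) > 1:
        logger.warning("panel sizes differ across panels: %s", sorted(sizes))

    rows = []
    replicate_rows = []
    for s_i, scenario in enumerate(scenarios):
        plan = make_mask(G.markers, scenario, ld1_snps, n_repetitions, seed + 1000 * s_i)
        for label, draws in panels.items():
            per_rep = {lab: [] for lab, *_ in MAF_CLASSES}       # draw-averaged
            per_draw_all = {lab: [] for lab, *_ in MAF_CLASSES}  # every single run
            for rep, masked in enumerate(plan.masked):
                per_draw = {lab: [] for lab, *_ in MAF_CLASSES}
                for d_i, draw in enumerate(draws):
                    panel = [str(a) for a in draw]
                    overlap_free = [a for a in all_ids if a not in set(panel)]
                    G_masked = G.copy()
                    t_idx = [G.ids.index(a) for a in overlap_free]
                    G_masked.values[np.ix_(t_idx, masked)] = MISSING
                    dos = impute(overlap_free, panel, G_masked, H_true, pedigree, partition)
                    truth = G.subset_animals(overlap_free)
                    acc = imputation_accuracy(truth, dos, masked, maf)
                    for lab in per_draw:
                        per_draw[lab].append(acc.mean_r[lab])
                        per_draw_all[lab].append(acc.mean_r[lab])
                        replicate_rows.append(
                            {
                                "breed": breed, "panel": label, "scenario": scenario,
                                "maf_class": lab, "repetition": rep, "draw": d_i,
                                "r": acc.mean_r[lab],
                            }
                        )
                for lab in per_rep:
                    vals = np.asarray(per_draw[lab], float)
                    per_rep[lab].append(
                        float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
                    )
            # mean over repetitions of draw-averaged accuracy; min/max over
            # every individual run so random-panel spread across draws shows
            for lab, *_ in MAF_CLASSES:
                means = np.asarray(per_rep[lab], float)
                alls = np.asarray(per_draw_all[lab], float)
                if np.isnan(alls).all():
                    mean = mn = mx = float("nan")
                else:
                    mean = float(np.nanmean(means))
                    mn, mx = float(np.nanmin(alls)), float(np.nanmax(alls))
                rows.append(
                    {
                        "breed": breed, "panel": label, "scenario": scenario,
                        "maf_class": lab, "mean": mean, "min": mn, "max": mx,
                    }
                )
    report = ReportTable(pd.DataFrame(rows))
    report.replicates = pd.DataFrame(replicate_rows)  # replicate-level values retained
    return report


def compare_panels(report: ReportTable, baseline: str = "random") -> pd.DataFrame:
    """Per-cell accuracy difference vs the baseline panel, in percentage points."""
    r = report.rows
    if baseline not in set(r["panel"]):
        raise ValueError(f"baseline panel {baseline!r} not in report")
    base = r[r["panel"] == baseline].set_index(["breed", "scenario", "maf_class"])["mean"]
    out = []
    for _, row in r[r["panel"] != baseline].iterrows():
        key = (row["breed"], row["scenario"], row["maf_class"])
        out.append(
            {
                "breed": row["breed"], "panel": row["panel"], "scenario": row["scenario"],
                "maf_class": row["maf_class"],
                "delta_points": 100.0 * (row["mean"] - base.loc[key]),
            }
        )
    return pd.DataFrame(out)
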