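"""Readers and writers for the on-disk formats used by the pipeline.

Genotypes travel as PLINK-style ``.ped``/``.map`` text (two allele columns
per marker, missing allele "0"), pedigrees as CSV, phased haplotypes as a
tab-separated table, and accuracy reports as TSV or JSON.  All writers are
deterministic so that identical inputs yield byte-identical files.

Coordinate conventions: bp positions are 1-based as in ``.map``; internal
marker indices are 0-based with half-open windows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    MISSING,
    UNKNOWN,
    GenotypeMatrix,
    HaplotypeMatrix,
    Pedigree,
    PedigreeError,
    make_marker_map,
)

logger = logging.getLogger("seqpanel")

_VALID_ALLELES = set("ACGT12")
_HAP_MISSING_CHAR = "."


# ---------------------------------------------------------------------------
# genotypes: PLINK .ped/.map
# ---------------------------------------------------------------------------

def write_genotypes(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``G`` as ``<prefix>.ped`` / ``<prefix>.map`` / ``<prefix>.alleles``.

    Dosages are emitted with reference allele "1" and alternate allele "2";
    the ``.alleles`` sidecar (marker_id, ref, alt) pins the orientation so a
    round trip is exact even for monomorphic markers.
    """
    prefix = Path(prefix)
    mm = G.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mm.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t{r['cm']:g}\t{r['bp']}\n")
    with open(prefix.with_suffix(".alleles"), "w") as fh:
        for mid in mm["marker_id"]:
            fh.write(f"{mid}\t1\t2\n")
    code = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for aid, row in zip(G.ids, G.values):
            cells = " ".join(code[int(v)] for v in row)
            fh.write(f"1 {aid} 0 0 0 -9 {cells}\n")


def read_genotypes(prefix: str | Path, allele_table: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read ``<prefix>.ped``/``.map`` into a dosage matrix.

    The dosage counts copies of the alternate allele.  Orientation comes
    from ``allele_table`` (marker_id, ref, alt), else from a ``.alleles``
    sidecar if present, else the lexicographically larger observed symbol
    is taken as the alternate allele.
    """
    prefix = Path(prefix)
    mm = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "bp"],
        dtype={"marker_id": str},
    )
    markers = make_marker_map(mm["chrom"], mm["bp"], mm["cm"], mm["marker_id"])
    n_markers = len(markers)

    if allele_table is None and prefix.with_suffix(".alleles").exists():
        allele_table = pd.read_csv(
            prefix.with_suffix(".alleles"), sep="\t", header=None,
            names=["marker_id", "ref", "alt"], dtype=str,
        )

    ids: list[str] = []
    a1_rows, a2_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{prefix.with_suffix('.ped')}:{ln}: expected {6 + 2 * n_markers} "
                    f"fields, found {len(parts)}"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            bad = set(alleles) - _VALID_ALLELES - {"0"}
            if bad:
                raise ValueError(f"invalid allele symbol(s) {sorted(bad)} on line {ln}")
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])

    a1 = np.asarray(a1_rows, dtype="U1")
    a2 = np.asarray(a2_rows, dtype="U1")
    if allele_table is not None:
        alt_of = dict(zip(allele_table["marker_id"], allele_table["alt"]))
        alt = np.asarray([alt_of[m] for m in markers["marker_id"]], dtype="U1")
    else:
        alt = np.empty(n_markers, dtype="U1")
        for j in range(n_markers):
            seen = set(a1[:, j]) | set(a2[:, j])
            seen.discard("0")
            alt[j] = max(seen) if seen else "0"

    dosage = (a1 == alt).astype(np.int8) + (a2 == alt).astype(np.int8)
    dosage[(a1 == "0") | (a2 == "0")] = MISSING
    return GenotypeMatrix(ids, dosage, markers)


# ---------------------------------------------------------------------------
# pedigree CSV
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    t = ped.table.copy()
    t["available"] = t["available"].astype(int)
    t.to_csv(path, index=False, lineterminator="\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and validate a pedigree CSV (id,sire,dam,sex,generation,breed,available).

    "0" or empty marks an unknown parent.  Parents referenced but absent
    are auto-added as founders with a warning; a cycle is a hard error.
    """
    t = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    t["sire"] = t["sire"].fillna(UNKNOWN)
    t["dam"] = t["dam"].fillna(UNKNOWN)
    known = set(t["id"].astype(str))
    dangling = []
    for col in ("sire", "dam"):
        for p in t[col].astype(str):
            if p != UNKNOWN and p not in known and p not in dangling:
                dangling.append(p)
    if dangling:
        warnings.warn(
            f"{len(dangling)} parent(s) without a pedigree record were added as founders: "
            f"{dangling[:5]}",
            stacklevel=2,
        )
        logger.warning("auto-added %d dangling parents as founders", len(dangling))
        extra = pd.DataFrame(
            {
                "id": dangling,
                "sire": UNKNOWN,
                "dam": UNKNOWN,
                "sex": "U",
                "generation": int(t["generation"].max()) + 1 if len(t) else 1,
                "breed": t["breed"].iloc[0] if len(t) else "NA",
                "available": 0,
            }
        )
        t = pd.concat([extra, t], ignore_index=True)
    return Pedigree(t)


# ---------------------------------------------------------------------------
# phased haplotypes TSV
# ---------------------------------------------------------------------------

def write_haplotypes(H: HaplotypeMatrix, path: str | Path) -> None:
    """Tab-separated: animal id, haplotype index (0/1), allele string."""
    with open(path, "w") as fh:
        for i, aid in enumerate(H.ids):
            for k in (0, 1):
                row = H.values[2 * i + k]
                s = "".join(_HAP_MISSING_CHAR if v == MISSING else str(int(v)) for v in row)
                fh.write(f"{aid}\t{k}\t{s}\n")


def read_haplotypes(path: str | Path, markers: pd.DataFrame) -> HaplotypeMatrix:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            aid, k, s = line.rstrip("\n").split("\t")
            if k == "0":
                ids.append(aid)
            rows.append(
                np.array([MISSING if ch == _HAP_MISSING_CHAR else int(ch) for ch in s], dtype=np.int8)
            )
    return HaplotypeMatrix(ids, np.vstack(rows), markers)


# ---------------------------------------------------------------------------
# accuracy report
# ---------------------------------------------------------------------------

REPORT_KEY = ("breed", "panel", "scenario", "maf_class")
REPORT_COLUMNS = REPORT_KEY + ("mean", "min", "max")


@dataclass
class ReportTable:
    """Per (breed, panel, scenario, MAF class) mean/min/max imputation accuracy.

    Accuracies are correlations on the [-1, 1] scale; absent cells (empty
    MAF class) are NaN.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REPORT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"report lacks columns {missing}")
        r = self.rows.reset_index(drop=True).copy()
        if r.duplicated(subset=list(REPORT_KEY)).any():
            raise ValueError("duplicate (breed, panel, scenario, maf_class) key")
        vals = r[["mean", "min", "max"]].to_numpy(float)
        ok = np.isnan(vals) | ((vals >= -1 - 1e-9) & (vals <= 1 + 1e-9))
        if not ok.all():
            raise ValueError("accuracy values must lie in [-1, 1] or be NaN")
        self.rows = r

    def cell(self, breed: str, panel: str, scenario: str, maf_class: str) -> pd.Series:
        r = self.rows
        m = (
            (r["breed"] == breed)
            & (r["panel"] == panel)
            & (r["scenario"] == scenario)
            & (r["maf_class"] == maf_class)
        )
        return r.loc[m].iloc[0]


def _report_sorted(report: ReportTable) -> pd.DataFrame:
    return report.rows.sort_values(list(REPORT_KEY), kind="mergesort").reset_index(drop=True)


def write_report(report: ReportTable, path: str | Path, format: str = "tsv") -> None:
    """Write the report with accuracies as percentages to 2 decimals.

    Column order is fixed (breed, panel, scenario, maf_class, mean, min,
    max); TSV cells carry a trailing "%", the JSON variant stores the same
    rounded percent values as numbers.  An empty report is an error.
    """
    if len(report.rows) == 0:
        raise ValueError("refusing to write an empty report")
    rows = _report_sorted(report)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for _, r in rows.iterrows():
                cells = [str(r[c]) for c in REPORT_KEY]
                for c in ("mean", "min", "max"):
                    v = r[c]
                    cells.append("NA" if pd.isna(v) else f"{100.0 * v:.2f}%")
                fh.write("\t".join(cells) + "\n")
    elif format == "json":
        recs = []
        for _, r in rows.iterrows():
            rec = {c: r[c] for c in REPORT_KEY}
            for c in ("mean", "min", "max"):
                v = r[c]
                rec[c] = None if pd.isna(v) else round(100.0 * float(v), 2)
            recs.append(rec)
        with open(path, "w") as fh:
            json.dump(recs, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_values(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Parse a written report back to numeric percent values (for checks)."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for c in ("mean", "min", "max"):
            df[c] = df[c].map(lambda s: np.nan if s == "NA" else float(s.rstrip("%")))
        return df
    with open(path) as fh:
        recs = json.load(fh)
    df = pd.DataFrame(recs)
    for c in ("mean", "min", "max"):
        df[c] = df[c].astype(float)
    return df


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def read_sim_config(path: str | Path):
    """Read one or more breed SimConfigs from a YAML file.

    A top-level ``breeds:`` list gives one config per breed; otherwise the
    whole document is a single config.
    """
    from .popsim import SimConfig

    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def mk(d):
        if "founder_maf_distribution" in d:
            d = dict(d)
            d["founder_maf_distribution"] = tuple(d["founder_maf_distribution"])
        return SimConfig(**d)

    if isinstance(doc, dict) and "breeds" in doc:
        shared = {k: v for k, v in doc.items() if k != "breeds"}
        return [mk({**shared, **b}) for b in doc["breeds"]]
    return [mk(doc)]
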