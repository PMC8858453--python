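"""Deterministic core-library imputation engine.

Two stages fill a target animal's masked genotypes from a reference panel:

1. **Mendelian family fill** — a missing genotype is filled whenever both
   parents' genotypes at the marker are observed and jointly determine the
   offspring uniquely (both parents homozygous); iterated to a fixpoint.
2. **Core-library matching** — within each haplotype core, every unordered
   pair of reference haplotypes consistent with the target's observed
   genotypes is enumerated; the dosage at a missing marker is the
   frequency-weighted mean of the pair sums.  If no pair is consistent the
   dosage falls back to twice the reference allele frequency.

The engine never overwrites an observed genotype, leaves no entry missing,
and is fully deterministic, which makes reference panels directly
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, UNKNOWN, GenotypeMatrix, HaplotypeMatrix, Pedigree
from .haplib import CorePartition, build_library

logger = logging.getLogger("seqpanel")

# provenance codes
OBSERVED, MENDELIAN, LIBRARY, FALLBACK = 0, 1, 2, 3

#: Largest number of distinct core haplotypes used for pair enumeration;
#: beyond this the most frequent ones are kept (pair cost is quadratic).
MAX_CORE_HAPLOTYPES = 512


@dataclass
class DosageMatrix:
    """Real-valued dosages in [0,2] with per-entry provenance."""

    ids: list[str]
    values: np.ndarray          # float64 (n_animals, n_markers)
    provenance: np.ndarray      # int8, codes OBSERVED/MENDELIAN/LIBRARY/FALLBACK
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if (v < -1e-9).any() or (v > 2 + 1e-9).any():
            raise ValueError("dosages must lie in [0, 2]")
        self.values = v


def mendelian_fill(
    G: GenotypeMatrix, pedigree: Pedigree, return_mask: bool = False
):
    """Fill missing genotypes that both parents determine uniquely.

    Only the unambiguous case (both parents observed and homozygous) is
    filled: offspring dosage = sire/2 + dam/2.  Iterates to a fixpoint so
    fills can cascade down the pedigree.  Observed entries are never
    changed; trios whose observed genotypes are Mendelian-impossible are
    counted and left untouched.
    """
    out = G.copy()
    v = out.values
    pos = {a: k for k, a in enumerate(out.ids)}
    trios = []
    for a in out.ids:
        if a not in pedigree:
            continue
        s, d = pedigree.parents(a)
        if s != UNKNOWN and d != UNKNOWN and s in pos and d in pos:
            trios.append((pos[a], pos[s], pos[d]))
    filled = np.zeros(v.shape, dtype=bool)
    n_conflicts = 0
    if trios:
        o_idx, s_idx, d_idx = map(np.array, zip(*trios))
        # conflicts: parents homozygous, offspring observed but not the forced value
        gs, gd, go = v[s_idx], v[d_idx], v[o_idx]
        det = ((gs == 0) | (gs == 2)) & ((gd == 0) | (gd == 2))
        forced = gs // 2 + gd // 2
        n_conflicts = int((det & (go != MISSING) & (go != forced)).sum())
        while True:
            gs, gd, go = v[s_idx], v[d_idx], v[o_idx]
            det = ((gs == 0) | (gs == 2)) & ((gd == 0) | (gd == 2))
            fill = det & (go == MISSING)
            if not fill.any():
                break
            rows, cols = np.nonzero(fill)
            v[o_idx[rows], cols] = (gs // 2 + gd // 2)[rows, cols]
            filled[o_idx[rows], cols] = True
    if n_conflicts:
        logger.info("mendelian_fill: %d conflicting observed trios left untouched", n_conflicts)
    out._n_mendelian_conflicts = n_conflicts  # diagnostic, not part of the contract
    if return_mask:
        return out, filled
    return out


def _core_pair_sums(haps: np.ndarray, freqs: np.ndarray):
    """Unordered pair sums and weights: w = f_i f_j, doubled off-diagonal."""
    k = len(freqs)
    iu, ju = np.triu_indices(k)
    S = haps[iu] + haps[ju]                      # (n_pairs, core_len) values 0/1/2
    w = freqs[iu] * freqs[ju] * np.where(iu == ju, 1.0, 2.0)
    return S.astype(np.int8), w


def impute_with_library(
    G_target: GenotypeMatrix,
    reference_haplotypes: HaplotypeMatrix,
    partition: CorePartition,
    max_core_haplotypes: int = MAX_CORE_HAPLOTYPES,
) -> DosageMatrix:
    """Impute missing genotypes by consistent-pair enumeration per core.

    For each target animal and core, a reference haplotype pair (h_i, h_j)
    is consistent when h_i[k] + h_j[k] equals the observed genotype at all
    non-missing markers k of the core.  The dosage at a missing marker m is
    the weighted mean of h_i[m] + h_j[m] over consistent pairs with weight
    f_i * f_j (doubled for i != j).  With no consistent pair (or an empty
    core library) the dosage is twice the reference allele frequency.
    """
    lib = build_library(reference_haplotypes, partition, snp_callrate_min=0.0, ind_callrate_min=0.0)
    ref_v = reference_haplotypes.values
    ref_obs = ref_v != MISSING
    with np.errstate(invalid="ignore"):
        ref_freq = np.where(
            ref_obs.sum(axis=0) > 0,
            np.where(ref_obs, ref_v, 0).sum(axis=0) / np.maximum(ref_obs.sum(axis=0), 1),
            0.5,
        )

    out = G_target.values.astype(float)
    prov = np.zeros(out.shape, dtype=np.int8)
    miss = G_target.values == MISSING
    prov[miss] = FALLBACK
    # start from the fallback everywhere missing; library pass overwrites
    out[miss] = np.broadcast_to(2.0 * ref_freq, out.shape)[miss]

    for cl in lib.cores:
        span = np.arange(cl.core.start, cl.core.end)
        g_core = G_target.values[:, span]
        miss_core = g_core == MISSING
        if not miss_core.any():
            continue
        if cl.empty or len(cl.haplotypes) == 0:
            continue  # whole-core fallback already in place
        haps = np.array(
            [[int(ch) for ch in s] for s in cl.haplotypes[:max_core_haplotypes]], dtype=np.int8
        )
        freqs = cl.frequencies[:max_core_haplotypes]
        if len(cl.haplotypes) > max_core_haplotypes:
            logger.info(
                "core %s: %d haplotypes capped to %d most frequent",
                cl.core, len(cl.haplotypes), max_core_haplotypes,
            )
        # markers the library actually covers within this core
        cover = np.isin(span, cl.marker_idx)
        S, w = _core_pair_sums(haps[:, np.isin(cl.marker_idx, span[cover])], freqs)

        g_cov = g_core[:, cover]
        obs_cov = g_cov != MISSING
        # group targets by identical observed pattern so the consistency
        # test is one one-hot matmul per group (chip masks share patterns)
        patterns: dict[bytes, list[int]] = {}
        for i in range(g_cov.shape[0]):
            if not miss_core[i].any():
                continue
            patterns.setdefault(obs_cov[i].tobytes(), []).append(i)
        cov_idx = span[cover]
        for key, rows in patterns.items():
            pat = np.frombuffer(key, dtype=bool)
            n_obs = int(pat.sum())
            gg = g_cov[np.ix_(rows, np.nonzero(pat)[0])]
            Sp = S[:, pat]
            if n_obs == 0:
                consistent = np.ones((len(rows), S.shape[0]), dtype=bool)
            else:
                matches = np.zeros((len(rows), S.shape[0]))
                for val in (0, 1, 2):
                    matches += (gg == val).astype(np.float64) @ (Sp == val).T.astype(np.float64)
                consistent = matches >= n_obs - 1e-9
            cw = consistent * w  # (rows, pairs)
            tot = cw.sum(axis=1)
            ok = tot > 0
            if ok.any():
                dose = (cw[ok] @ S) / tot[ok, None]
                rr = np.asarray(rows)[ok]
                fill = miss_core[np.ix_(rr, np.nonzero(cover)[0])]
                for t, row_i in enumerate(rr):
                    cols = cov_idx[fill[t]]
                    out[row_i, cols] = dose[t][fill[t]]
                    prov[row_i, cols] = LIBRARY
    return DosageMatrix(list(G_target.ids), out, prov, G_target.markers)


def impute(
    targets: list[str],
    reference_panel: list[str],
    G_all: GenotypeMatrix,
    H_reference: HaplotypeMatrix,
    pedigree: Pedigree,
    partition: CorePartition,
) -> DosageMatrix:
    """Full imputation of ``targets`` from a reference panel.

    Runs the Mendelian family fill first (parents may sit in the reference
    panel, whose genotypes are complete), then the core-library engine on
    whatever is still missing.  Panels must be disjoint.
    """
    overlap = set(targets) & set(reference_panel)
    if overlap:
        raise ValueError(f"reference panel overlaps targets: {sorted(overlap)[:5]}")
    stacked = G_all.subset_animals(list(targets) + list(reference_panel))
    filled, mask = mendelian_fill(stacked, pedigree, return_mask=True)
    n_t = len(targets)
    G_t = GenotypeMatrix(list(targets), filled.values[:n_t], G_all.markers)
    H_ref = H_reference.subset_animals(reference_panel)
    dos = impute_with_library(G_t, H_ref, partition)
    # entries the family step filled entered the library pass as observed;
    # relabel them with their true provenance
    dos.provenance[mask[:n_t]] = MENDELIAN
    return dos
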