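"""Forward pedigree gene-drop simulator for a livestock breeding nucleus.

Emulates the population structure the selection analysis assumes: discrete
cohorts bred from a limited number of sires and dams with strongly skewed
sire usage (few heavily used boars), biallelic SNPs on several autosomes,
and an excess of low-MAF markers via a U-shaped founder allele-frequency
spectrum.  Breeds are simulated independently; recombination follows a
no-interference (Haldane) model with Poisson crossover counts on the
Morgan map length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, UNKNOWN, GenotypeMatrix, HaplotypeMatrix, Pedigree, make_marker_map

#: Geometric decay of mating probability over the ranked sire list; rank-1
#: sires father roughly half of each cohort, mimicking heavy boar reuse.
SIRE_USAGE_DECAY: float = 0.5

#: Weight of the immediately previous cohort when drawing parents; the
#: remainder comes from one cohort earlier, giving mildly overlapping
#: generations as seen in closed nucleus herds.
RECENT_PARENT_WEIGHT: float = 0.8


@dataclass
class SimConfig:
    """Parameters of one simulated breed.

    Defaults describe a small nucleus population: ~50 founders, five
    cohorts, ten sires and fifty dams used per generation, two autosomes
    of 1 Morgan each carrying 500 equally spaced markers (1 kb apart).
    """

    n_founders: int = 50
    n_generations: int = 5
    offspring_per_mating: int = 2
    n_sires_used: int = 10
    n_dams_used: int = 25
    n_chromosomes: int = 2
    markers_per_chromosome: int = 500
    chromosome_length_morgans: float = 1.0
    marker_spacing_bp: int = 1000
    founder_maf_distribution: tuple = ("beta", 0.5, 0.5)
    missing_rate: float = 0.0
    availability_rate: float = 1.0
    breed: str = "B1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_founders",
            "n_generations",
            "offspring_per_mating",
            "n_sires_used",
            "n_dams_used",
            "n_chromosomes",
            "markers_per_chromosome",
            "marker_spacing_bp",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chromosome_length_morgans <= 0:
            raise ValueError("chromosome_length_morgans must be > 0")
        for name in ("missing_rate", "availability_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        kind = self.founder_maf_distribution[0]
        if kind not in ("uniform", "beta"):
            raise ValueError("founder_maf_distribution must be ('uniform',lo,hi) or ('beta',a,b)")
        if self.n_sires_used > self.n_founders // 2:
            raise ValueError(
                f"n_sires_used={self.n_sires_used} exceeds the {self.n_founders // 2} "
                "males available among founders"
            )


def default_marker_map(config: SimConfig) -> pd.DataFrame:
    """Equally spaced markers: bp on a fixed grid, cM proportional to bp."""
    chrom, bp, cm = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        m = config.markers_per_chromosome
        pos = (np.arange(m) + 1) * config.marker_spacing_bp
        chrom.extend([c] * m)
        bp.extend(pos.tolist())
        # marker i sits at (i+0.5)/m of the Morgan length
        cm.extend((100.0 * config.chromosome_length_morgans * (np.arange(m) + 0.5) / m).tolist())
    return make_marker_map(chrom, bp, cm)


def _founder_allele_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_chromosomes * config.markers_per_chromosome
    kind, a, b = config.founder_maf_distribution
    if kind == "uniform":
        maf = rng.uniform(a, b, size=n)
        # random orientation of which allele is minor
        flip = rng.random(n) < 0.5
        return np.where(flip, maf, 1.0 - maf)
    return rng.beta(a, b, size=n)


def gene_drop_gamete(
    parent_haplotypes: np.ndarray,
    positions_morgans: np.ndarray,
    chrom_ids: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one recombinant gamete from a parent's two haplotypes.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome map length in Morgans; crossover positions are uniform and
    the starting haplotype is chosen with probability 1/2 (Haldane model,
    no interference).

    Parameters
    ----------
    parent_haplotypes : (2, n_markers) array of the parent's phased alleles.
    positions_morgans : per-marker map position in Morgans (within chromosome).
    chrom_ids : per-marker chromosome identifier.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape[0] != 2 or parent_haplotypes.shape[1] != len(positions_morgans):
        raise ValueError("parent haplotypes must be (2, n_markers) matching the map")
    if len(chrom_ids) != len(positions_morgans):
        raise ValueError("chrom_ids and positions_morgans length mismatch")

    origin = np.empty(parent_haplotypes.shape[1], dtype=np.int8)
    for c in pd.unique(np.asarray(chrom_ids)):
        sel = np.nonzero(np.asarray(chrom_ids) == c)[0]
        pos = np.asarray(positions_morgans, dtype=float)[sel]
        length = float(pos[-1]) if len(pos) else 0.0
        n_xo = rng.poisson(length)
        start = int(rng.integers(0, 2))
        if n_xo == 0:
            origin[sel] = start
            continue
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        # parity of crossover count below each marker flips the origin
        below = np.searchsorted(xo, pos, side="left")
        origin[sel] = (start + below) % 2
    return parent_haplotypes[origin, np.arange(parent_haplotypes.shape[1])].copy()


def apply_missingness(G: GenotypeMatrix, rate: float, rng: np.random.Generator) -> GenotypeMatrix:
    """Return a copy of ``G`` with entries independently set MISSING at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0,1)")
    out = G.copy()
    if rate > 0:
        mask = rng.random(out.values.shape) < rate
        out.values[mask] = MISSING
    return out


def _draw_usage_weighted(ids: list[str], n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` parent assignments from ``ids`` with geometric usage weights."""
    w = SIRE_USAGE_DECAY ** np.arange(len(ids))
    w /= w.sum()
    return rng.choice(np.asarray(ids, dtype=object), size=n, p=w)


def simulate_population(
    config: SimConfig,
) -> tuple[Pedigree, HaplotypeMatrix, GenotypeMatrix]:
    """Simulate one breed: pedigree, true phased haplotypes and genotypes.

    Founders get generation ``n_generations``; the final cohort is
    generation 1 (most recent).  Each later cohort is bred from
    ``n_sires_used`` sires and ``n_dams_used`` dams drawn (recency- and
    usage-weighted) from the two preceding cohorts; every dam produces
    ``offspring_per_mating`` offspring with an independently drawn sire per
    mating.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    markers = default_marker_map(config)
    n_markers = len(markers)
    chrom_ids = markers["chrom"].to_numpy()
    pos_morgans = markers["cm"].to_numpy() / 100.0

    p = _founder_allele_freqs(config, rng)

    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sexes: list[str] = []
    cohort: list[int] = []  # 0 = founders, increasing forward in time
    hap_rows: list[np.ndarray] = []
    row_of: dict[str, int] = {}

    def add_animal(aid, sire, dam, sex, coh, h0, h1):
        row_of[aid] = len(ids)
        ids.append(aid)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        cohort.append(coh)
        hap_rows.append(h0)
        hap_rows.append(h1)

    # founders: deterministic half-male sex ratio, alleles Bernoulli(p)
    for i in range(config.n_founders):
        aid = f"{config.breed}_G{config.n_generations}_{i + 1:04d}"
        sex = "M" if i % 2 == 0 else "F"
        h0 = (rng.random(n_markers) < p).astype(np.int8)
        h1 = (rng.random(n_markers) < p).astype(np.int8)
        add_animal(aid, UNKNOWN, UNKNOWN, sex, 0, h0, h1)

    prev_cohorts: list[list[str]] = [ids.copy()]
    for g in range(1, config.n_generations):
        pool = prev_cohorts[-1]
        older = prev_cohorts[-2] if len(prev_cohorts) > 1 else []
        # recency-weighted eligible parents -> overlapping generations
        weights = {a: RECENT_PARENT_WEIGHT for a in pool}
        weights.update({a: 1.0 - RECENT_PARENT_WEIGHT for a in older})
        males = [a for a in pool + older if sexes[row_of[a]] == "M"]
        females = [a for a in pool + older if sexes[row_of[a]] == "F"]
        if config.n_sires_used > len(males):
            raise ValueError(
                f"n_sires_used={config.n_sires_used} exceeds {len(males)} available males "
                f"in cohort {g}"
            )
        if config.n_dams_used > len(females):
            raise ValueError(
                f"n_dams_used={config.n_dams_used} exceeds {len(females)} available females "
                f"in cohort {g}"
            )

        def pick(cands, n):
            w = np.array([weights[a] for a in cands])
            w /= w.sum()
            return list(rng.choice(np.asarray(cands, dtype=object), size=n, replace=False, p=w))

        gen_sires = pick(males, config.n_sires_used)
        gen_dams = pick(females, config.n_dams_used)
        matings = []
        sire_draws = _draw_usage_weighted(gen_sires, config.n_dams_used, rng)
        for dam, sire in zip(gen_dams, sire_draws):
            matings.extend([(str(sire), str(dam))] * config.offspring_per_mating)

        new_cohort: list[str] = []
        gen_label = config.n_generations - g
        for j, (sire, dam) in enumerate(matings):
            aid = f"{config.breed}_G{gen_label}_{j + 1:04d}"
            sex = "M" if rng.random() < 0.5 else "F"
            hs = hap_rows[2 * row_of[sire] : 2 * row_of[sire] + 2]
            hd = hap_rows[2 * row_of[dam] : 2 * row_of[dam] + 2]
            h_pat = gene_drop_gamete(np.vstack(hs), pos_morgans, chrom_ids, rng)
            h_mat = gene_drop_gamete(np.vstack(hd), pos_morgans, chrom_ids, rng)
            add_animal(aid, sire, dam, sex, g, h_pat, h_mat)
            new_cohort.append(aid)
        prev_cohorts.append(new_cohort)

    generation = [config.n_generations - c for c in cohort]
    available = rng.random(len(ids)) < config.availability_rate
    ped = Pedigree(
        pd.DataFrame(
            {
                "id": ids,
                "sire": sires,
                "dam": dams,
                "sex": sexes,
                "generation": generation,
                "breed": config.breed,
                "available": available,
            }
        )
    )
    H = HaplotypeMatrix(ids, np.vstack(hap_rows), markers)
    G = H.to_genotypes()
    if config.missing_rate > 0:
        G = apply_missingness(G, config.missing_rate, rng)
    return ped, H, G
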