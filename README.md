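# seqpanel

Choosing which animals of a genotyped, pedigreed livestock population to
re-sequence is a reference-panel design problem: the sequenced subset should
carry as much of the population's haplotype diversity as possible, so that
genotype imputation from the panel — especially of low-frequency variants —
is accurate for everyone else.  `seqpanel` implements a complete,
reproducible workflow for this decision and for quantifying its benefit,
aimed at animal-breeding researchers working with SNP-chip data and deep
pedigrees (the setting it models is a two-breed pig nucleus, but nothing is
pig-specific).

## What it does

Given SNP genotypes (0/1/2 dosage coding), phased haplotypes and a pedigree
per breed, the package provides:

* **Marker QC** — exclude markers with call rate < 95% or MAF < 1%, then
  prune one marker of any pair with genotypic r² > 0.8 within 3 kb.
* **Haplotype library** — chromosomes are cut into cores of 100 consecutive
  SNPs; each core's distinct haplotypes are catalogued with population
  frequencies and carriers (90% call-rate gates per SNP and individual).
* **H selection** — greedy haplotype-diversity selection: repeatedly pick
  the animal whose not-yet-covered core haplotypes sum to the largest
  population frequency, then mask them (frequency threshold 0 keeps every
  haplotype in play).
* **P1 selection** — greedy maximization of the explained pedigree
  relationship J(S) = p_S' A_SS⁻¹ p_S, where A is the numerator
  relationship matrix (Henderson's tabular method) and p_S[i] is the mean
  relationship of selected animal i to the population.
* **P2 selection** — key ancestors: the animals with the largest marginal
  expected genetic contribution to a reference generation, selected
  sequentially so that every reference gene is credited to exactly one
  ancestor (marginal contributions sum to at most 1).
* **C selection** — the practical combined heuristic under a per-breed
  budget and a sample-availability constraint: (1) H ∩ (P1 ∪ P2);
  (2) P1 ∩ P2; (3) H with both parents among the key ancestors;
  (4) H with exactly one such parent.
* **Validation** — mask a random SNP subset in all non-panel animals
  (LD₁: 23.1% of markers, LD₂: half of them), impute back from the panel
  with a deterministic engine (Mendelian family fill, then per-core
  consistent-haplotype-pair matching), and score the Pearson correlation r
  between true genotype and imputed dosage per masked marker, stratified by
  MAF class (1–3%, 3–5%, >5%), with mean/min/max over repetitions.
* **Population simulator** — a forward gene-drop simulator (skewed sire
  usage, Poisson/Haldane recombination, U-shaped founder allele-frequency
  spectrum) that generates breeds with the structure the workflow assumes,
  for testing and benchmarking.

## Worked example

```python
import numpy as np
import seqpanel as sp

cfg = sp.SimConfig(
    n_founders=60, n_generations=4, n_sires_used=8, n_dams_used=20,
    offspring_per_mating=4, n_chromosomes=2, markers_per_chromosome=1000,
    breed="LR", seed=1,
)
pedigree, haplotypes, genotypes = sp.simulate_population(cfg)

genotypes_qc, qc_report = sp.qc_filter(genotypes)
haplotypes_qc = sp.HaplotypeMatrix(
    haplotypes.ids, haplotypes.values[:, qc_report.surviving], genotypes_qc.markers
)
print(f"QC: {qc_report.n_input} markers -> {len(qc_report.surviving)}")

cores = sp.partition_cores(genotypes_qc.markers, core_length=100)
library = sp.build_library(haplotypes_qc, cores)
sel_h = sp.select_haplotype_greedy(library, genotypes.ids, n_target=40)
nrm = sp.build_nrm(pedigree)
sel_p1 = sp.select_pedigree_relationship(nrm, genotypes.ids, genotypes.ids, n_target=40)
key_anc = sp.select_key_ancestors(pedigree, cum_threshold=0.95)
combined = sp.combine_selection(sel_h, sel_p1, key_anc, pedigree, targets={"LR": 20})
print(f"key ancestors explain {key_anc.cumulative[-1]:.1%} of the reference genes")

rng = np.random.default_rng(99)
panels = {
    "combined": [combined.ids],
    "random": [sp.select_random(genotypes.ids, 20, rng).ids for _ in range(5)],
}
report = sp.run_validation_experiment(
    genotypes_qc, haplotypes_qc, pedigree, panels, cores,
    scenarios=["LD2"], n_repetitions=5, seed=1,
)
for _, row in report.rows.iterrows():
    print(f"{row['panel']:>9} {row['scenario']} MAF {row['maf_class']:>5}: "
          f"r = {row['mean']:.3f} [{row['min']:.3f}, {row['max']:.3f}]")
for _, row in sp.compare_panels(report, baseline="random").iterrows():
    print(f"gain combined vs random, MAF {row['maf_class']:>5}: "
          f"{row['delta_points']:+.1f} points")
```

prints

```
QC: 2000 markers -> 1641
key ancestors explain 95.6% of the reference genes
 combined LD2 MAF  1-3%: r = 0.420 [0.400, 0.451]
 combined LD2 MAF  3-5%: r = 0.492 [0.482, 0.513]
 combined LD2 MAF   >5%: r = 0.625 [0.622, 0.627]
   random LD2 MAF  1-3%: r = 0.179 [0.117, 0.269]
   random LD2 MAF  3-5%: r = 0.285 [0.231, 0.322]
   random LD2 MAF   >5%: r = 0.463 [0.448, 0.483]
gain combined vs random, MAF  1-3%: +24.1 points
gain combined vs random, MAF  3-5%: +20.7 points
gain combined vs random, MAF   >5%: +16.1 points
```

Read: on a 300-animal breed with 2,000 simulated SNPs, a targeted panel of
20 animals lifts imputation accuracy over a same-size random panel in every
MAF class, most strongly for low-frequency markers (1–3% MAF), and the
random panels vary far more between draws (their min–max range) than the
combined panel does across repetitions.

The same chain is available from the shell:

```bash
seqpanel simulate --config sim.yaml --out work --seed 7
seqpanel qc --workdir work --breed LR
seqpanel library --workdir work --breed LR --core-length 100
seqpanel select-h --workdir work --breed LR --n 100 --freq-threshold 0
seqpanel select-p1 --workdir work --breed LR --n 100
seqpanel select-p2 --workdir work --breed LR --reference-gen 1
seqpanel combine --workdir work --targets LR=28,LW=29
seqpanel validate --workdir work --breed LR --panels combined,haplotype,random
```

All commands are deterministic for a fixed `--seed` (byte-identical
outputs on rerun).

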