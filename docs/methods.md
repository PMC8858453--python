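# Methods

This note documents the models and procedures behind `seqpanel`, their
assumptions, the parameters that matter, and the design choices made where
several defensible options existed.

## Problem setting

A breeding population has SNP-chip genotypes for a few hundred to a few
thousand animals and a pedigree reaching further back.  A small subset is
to be re-sequenced; everyone else will later be imputed from that subset.
A good panel therefore maximizes the share of population haplotypes carried
by the panel, weighted toward what imputation needs — and because rare
haplotypes carry the low-frequency variants that imputation struggles with
most, panel composition matters most in the lowest MAF classes.  All
analyses are breed-specific: the workflow never pools breeds, because
haplotype frequencies and pedigree structure differ between closed lines.

## Marker quality control (`qc`)

Rules are applied in a fixed, logged order: (1) call rate < 0.95 removed,
(2) MAF < 0.01 removed, (3) windowed LD pruning.  MAF is min(p, 1−p) with p
the mean non-missing dosage over 2; LD is the squared Pearson correlation
of dosages over pairwise-complete animals (genotypic r², since phase is
not assumed at QC time).  Pruning scans each chromosome left to right and
drops a marker if any already-kept marker within 3 kb (inclusive) exceeds
r² = 0.8 with it, so the left member of a high-LD pair survives.  Left-keep
makes the scan deterministic and independent of MAF ordering; the surviving
set provably contains no high-LD pair within the window, and the filter is
idempotent.  Per-animal call rates are reported but animals are never
dropped here.  Rule order affects the per-rule removal counts, not the
final guarantee, which is why the order is recorded in the QC report.

## Haplotype cores and library (`haplib`)

Chromosomes are cut into cores of 100 consecutive SNPs — the window length
recommended for ~60k chip density, at which phasing accuracy peaks.  A
terminal remainder of at least half a core length becomes its own core,
otherwise it merges into the previous core; this keeps all cores near the
nominal length without leaving slivers.  Call-rate gates (0.90 per SNP over
all haplotype rows, 0.90 per individual) are applied genome-wide before
construction — the per-individual gate is genome-wide and the per-SNP gate
per-marker, the most natural reading when cores are just windows over one
chip.  Within a core, any haplotype still containing a missing allele is
excluded from that core's denominator only.  Frequencies are copy counts
over included copies and sum to 1 per core.

The library is built on simulated (true) haplotypes by default; externally
phased haplotypes can be supplied instead.  Robustness to phasing error is
out of scope — in the intended setting over 99% of genotypes phase
correctly, so truth is a fair stand-in.

## Selection strategies (`select`)

**H — haplotype diversity.**  Iteratively pick the candidate whose carried,
unmasked (core, haplotype) pairs sum to the largest population frequency;
then mask those pairs and repeat.  An animal carrying two copies of a
haplotype scores it once (coverage, not dosage).  The frequency threshold
defaults to 0 so every haplotype counts regardless of rarity.  With full
masking and threshold 0 the greedy is deterministic, so a single pass
suffices; a randomized tie-breaking restart mode exists for exploration
(`--restarts`), but the default resolves all ties to the smallest animal id
— reproducibility over micro-optimality, here and in every other strategy.

**P1 — explained relationship.**  The numerator relationship matrix A is
built by Henderson's tabular method (founders a(i,i)=1; offspring rows are
parental means; a(i,i)=1+a(s,d)/2; unknown parents contribute 0).  Greedy
forward selection maximizes J(S) = p_S' A_SS⁻¹ p_S with p_S[i] the mean
relationship of i to the population — the standard key-contributor
quadratic form, i.e. the population relationship variance explained by S.
A ridge of 1e−8 on A_SS guards against exact singularity (e.g. selecting an
animal together with its clone); J is non-decreasing along the greedy path.
The candidate and population sets default to the genotyped animals of
recent generations, matching how such selections are run in practice.

**P2 — key ancestors.**  The expected genetic contribution of ancestor a to
a reference animal i follows the gene-origin recursion c(a→i) = 1 if i = a,
else the parental mean with unknown parents contributing 0; the reported
value is the mean over the reference population (default: generation 1, the
most recent).  Contributions of *all* animals are obtained in one backward
pass that propagates reference weight up the pedigree.  Selection is
sequential: previously picked ancestors block descent paths (they absorb
instead of forwarding weight), and each candidate is additionally
discounted by the expected fraction of its own genome already explained by
the picked set (one forward pass).  With both corrections each reference
gene is credited to exactly one pick, so marginals never exceed raw
contributions and the cumulative explained fraction is bounded by 1 —
path-blocking alone would double-count whenever a founder is picked before
its own descendants.  Stopping is by count, by a minimum marginal, or by
cumulative explained fraction (default 0.95); the published analyses this
mirrors report the selected count without stating the rule, so both knobs
are exposed.

**C — combined heuristic.**  Per breed, animals are added in four
successive steps until the budget is met, skipping any animal without
available sample material: (1) H ∩ (P1 ∪ P2), in H rank order; (2) P1 ∩ P2,
in P1 rank order; (3) H-animals with both sire and dam among the key
ancestors; (4) H-animals with exactly one such parent ("one parent" is read
as exactly one, since the both-parents case is already consumed by step 3).
If the budget is unreachable after step 4, a shorter set is returned with a
warning rather than padding with animals no criterion supports.

## Imputation engine (`impute`)

The engine is deliberately simple, deterministic, and oracle-checkable; its
job is to *rank reference panels*, not to compete with production HMM
imputation.  A sliding-window haplotype matcher was intentionally not
replicated: the claims this package supports are comparative, and a
deterministic engine makes panel comparisons exactly reproducible.

1. **Mendelian family fill.**  A missing genotype is filled only when both
   parents are observed and homozygous at the marker (the offspring dosage
   is then forced); iterated to a fixpoint so fills cascade down the
   pedigree.  Observed genotypes are never overwritten; Mendelian-impossible
   observed trios are counted and left untouched.
2. **Core-library matching.**  Per target and core, all unordered pairs of
   reference core-haplotypes consistent with the observed genotypes
   (h_i[k]+h_j[k] = g[k] at every observed k) are enumerated; the dosage at
   a missing marker is the frequency-weighted mean of the pair sums with
   weight f_i·f_j, doubled off-diagonal.  With no consistent pair (or an
   empty core library) the dosage falls back to twice the reference allele
   frequency, flagged as such.  Libraries above 512 distinct haplotypes per
   core are capped to the most frequent 512 (pair cost is quadratic); the
   consistency test is three one-hot matrix products, with targets grouped
   by identical missing pattern since chip-style masks share one pattern.

Dosages stay in [0,2], nothing remains missing, and in the perfect-panel
limit (every target haplotype present in the reference, cores informative
enough to pin down the pair) the imputed dosage equals the true genotype.
Targets are treated as unphased throughout.

## Validation design (`validate`)

Panels keep full genotypes; all other animals are targets.  Per replicate a
uniform random SNP subset is masked in every target (chip-panel semantics —
the same set for all animals): scenario LD₁ masks a fixed count, defaulting
to 23.1% of surviving markers (a fixed chip count scales down to that cap
on smaller simulated chips), LD₂ masks half.  Accuracy is the Pearson r
between true genotype and imputed dosage per masked marker across targets
— per-marker rather than per-animal, because the question is stratified by
marker MAF.  Markers with constant truth among targets are excluded and
counted (r undefined); a marker whose imputed dosage is constant while the
truth varies scores r = 0, since the dosage carries no signal.  MAF classes
(1–3%, 3–5%, >5%] are assigned from the full pre-masking genotype set — the
only definition available to all panels equally.  Cell means average the
per-repetition (draw-averaged) values; cell min/max span every individual
run, so the between-draw spread of random panels is visible.  All panels of
a run share the mask plan, making differences attributable to panel
composition alone.

## Population simulator (`popsim`)

The simulator generates the population structure the selection methods
assume; it is first-class, tested code, not a fixture.

* **Pedigree:** per generation, a limited number of sires and dams breed
  the next cohort; sire assignments follow a truncated geometric usage
  distribution (decay 0.5), so a couple of boars father most of a cohort —
  without this skew, key-ancestor selection would be meaningless.  Parents
  are drawn from the two preceding cohorts with 80/20 recency weighting,
  giving mildly overlapping generations.  Generation 1 is the most recent.
* **Genomes:** founders draw per-marker allele frequencies from a
  Beta(0.5, 0.5) spectrum by default — U-shaped, hence an excess of
  low-MAF markers as on real chips after QC; no published spectrum exists
  for the motivating data, so this default is an explicit modelling choice
  (uniform(lo, hi) is available).  Markers are equally spaced in bp
  (default 1 kb, configurable because the 3 kb LD window depends on it) and
  in map distance.  Gametes recombine with Poisson crossover counts on the
  Morgan length and uniform positions (Haldane, no interference) — the
  simplest defensible model.  Genotypes are haplotype sums; missingness and
  sample-availability flags are applied independently at configurable
  rates.  Breeds are simulated independently.

What the simulator does *not* emulate: coalescent-exact founder LD (founder
haplotypes are locus-independent draws; within-breed LD arises only from
the pedigree), selection on phenotypes, genotyping error, and sex
chromosomes.  Passing validation on simulated data therefore demonstrates
the comparative behaviour of panel choices under realistic pedigree and
haplotype-sharing structure — not absolute accuracy levels on any real
chip, which depend on founder LD and marker density.

## Numerical and determinism choices

* Missing data sentinel −1; dosage matrices float64; genotypes int8.
* All ties everywhere resolve to the smallest animal id (score ties within
  1e−9, which also absorbs float summation-order noise).
* Every stochastic step takes an explicit seed or generator; identical
  seeds give byte-identical outputs, including through the CLI.
* Half-open 0-based marker windows internally; 1-based bp externally, as
  in `.map` files.
* Written genotypes pin allele orientation in a `.alleles` sidecar so
  `.ped` round trips are exact even for monomorphic markers; without a
  sidecar the lexicographically larger observed allele is the alternate.

## Desk-scale study sizes

The bundled experiments (test suite and `scripts/acceptance.py`) run on
simulated breeds of ~300 animals over 4 generations with 2 chromosomes ×
1,000 markers, panels of 20 animals, 3–5 masking repetitions and 5–6 random
panel draws.  These sizes were chosen so a full two-breed workflow
completes in minutes on one CPU while leaving each MAF class populated
with dozens of masked markers; the comparative conclusions (targeted vs
random panels, strongest gains at low MAF) are stable across seeds at this
scale, as the directional tests check across 10 independent populations.

## Known limitations

* The imputation engine ignores cross-core information; accuracy levels
  are conservative relative to HMM imputation, uniformly across panels.
* P1's greedy is a heuristic for a submodular-like but not exactly
  submodular objective; it is exhaustively verified only for the first
  pick and on small instances.
* The key-ancestor discount assumes the reference population is the target
  of interest; contributions to animals outside the reference are ignored.
* Availability is a Bernoulli flag; real sample logistics (DNA quality,
  consent, generation-dependent availability) are not modelled.
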