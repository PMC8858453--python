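"""Selection of animals for re-sequencing.

Four strategies:

* **H** — greedy haplotype-diversity selection: repeatedly pick the animal
  whose carried, not-yet-covered core haplotypes sum to the largest
  population frequency, then mask those haplotypes (frequency threshold 0
  keeps every haplotype in play).
* **P1** — greedy maximization of the expected genetic relationship
  between the selected set and a target population, using the pedigree
  numerator relationship matrix A and the explained-relationship
  criterion J(S) = p_S' A_SS^{-1} p_S with p_S[i] the mean relationship
  of i to the population.
* **P2** — key ancestors: animals with the largest marginal expected
  genetic contribution to a reference population, selected sequentially
  with previously chosen ancestors blocking their shared descent paths.
* **C** — the combined 4-step heuristic that merges H, P1 and P2 under a
  per-breed budget and a sample-availability constraint.

All ties are broken by smallest animal id, so every strategy is fully
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import UNKNOWN, Pedigree
from .haplib import HaplotypeLibrary

logger = logging.getLogger("seqpanel")


# ---------------------------------------------------------------------------
# numerator relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Pedigree numerator relationship matrix; diagonal = 1 + F."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values, float)
        if a.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if (np.diag(a) < 1.0 - 1e-9).any():
            raise ValueError("diagonal entries must be >= 1")
        self.values = a
        self._pos = {x: k for k, x in enumerate(self.ids)}

    def a(self, i: str, j: str) -> float:
        return float(self.values[self._pos[str(i)], self._pos[str(j)]])

    def inbreeding(self, i: str) -> float:
        return self.a(i, i) - 1.0

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self._pos[str(i)] for i in ids]
        return self.values[np.ix_(idx, idx)]


def build_nrm(pedigree: Pedigree, subset: Sequence[str] | None = None) -> RelationshipMatrix:
    """Henderson's tabular method over the whole pedigree.

    In topological order: founders have a(i,i)=1 and a(i,j)=0 to older
    animals; for a non-founder i with parents s,d, a(i,j)=(a(j,s)+a(j,d))/2
    for previously processed j and a(i,i)=1+a(s,d)/2.  An unknown parent
    contributes 0.  ``subset`` restricts the returned matrix (ancestors are
    still used in the recursion).
    """
    order = pedigree.topological_order()
    pos = {a: k for k, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, aid in enumerate(order):
        s, d = pedigree.parents(aid)
        si = pos[s] if s != UNKNOWN else None
        di = pos[d] if d != UNKNOWN else None
        if k:
            row = np.zeros(k)
            if si is not None:
                row += A[si, :k]
            if di is not None:
                row += A[di, :k]
            A[k, :k] = row / 2.0
            A[:k, k] = A[k, :k]
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    if subset is None:
        return RelationshipMatrix(order, A)
    subset = [str(i) for i in subset]
    idx = [pos[i] for i in subset]
    return RelationshipMatrix(subset, A[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# selection containers
# ---------------------------------------------------------------------------

@dataclass
class SelectionSet:
    """Ordered selection with per-animal scores; C-approach adds step labels."""

    approach: str  # H, P1, P2, C or RANDOM
    ids: list[str]
    scores: list[float]
    steps: list[int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("selection contains duplicate animal ids")
        if len(self.scores) != len(self.ids):
            raise ValueError("scores and ids differ in length")
        if self.steps is not None and len(self.steps) != len(self.ids):
            raise ValueError("step labels and ids differ in length")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self, pedigree: Pedigree | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ids) + 1),
                "id": self.ids,
                "score": self.scores,
            }
        )
        df.insert(2, "breed", [pedigree.breed_of(i) for i in self.ids] if pedigree else "NA")
        df["step"] = self.steps if self.steps is not None else 0
        df.insert(0, "approach", self.approach)
        return df


@dataclass
class ContributionResult:
    """Key ancestors ordered by marginal expected genetic contribution."""

    ids: list[str]
    raw: list[float]        # contribution with nothing blocked
    marginal: list[float]   # contribution given previously selected blocked
    cumulative: list[float]

    def __post_init__(self) -> None:
        for r, m in zip(self.raw, self.marginal):
            if m > r + 1e-9:
                raise ValueError("marginal contribution exceeds raw contribution")
        c = np.asarray(self.cumulative)
        if len(c) and ((np.diff(c) < -1e-12).any() or c[-1] > 1 + 1e-9):
            raise ValueError("cumulative contributions must be non-decreasing and <= 1")

    def __len__(self) -> int:
        return len(self.ids)

    def as_selection(self) -> SelectionSet:
        return SelectionSet("P2", list(self.ids), list(self.marginal))


# ---------------------------------------------------------------------------
# H: haplotype-diversity greedy
# ---------------------------------------------------------------------------

def select_haplotype_greedy(
    library: HaplotypeLibrary,
    candidates: Sequence[str],
    n_target: int,
    freq_threshold: float = 0.0,
    tie_rng: np.random.Generator | None = None,
) -> SelectionSet:
    """Greedy haplotype-coverage selection with masking.

    Each round scores every remaining candidate as the summed population
    frequency of the distinct, unmasked core haplotypes it carries whose
    frequency exceeds ``freq_threshold`` (0 admits all), picks the best
    (ties to the smallest id), and masks the winner's haplotypes.  When
    every score reaches 0 the remainder is filled in id order.

    With ``tie_rng`` set, exact ties are broken uniformly at random
    instead of by id — an exploration mode for randomized restarts; the
    default pass is fully deterministic.
    """
    candidates = [str(c) for c in candidates]
    if n_target > len(candidates):
        raise ValueError(f"n_target={n_target} exceeds {len(candidates)} candidates")
    if not 0.0 <= freq_threshold < 1.0:
        raise ValueError("freq_threshold must be in [0,1)")

    # column space = all (core, haplotype) pairs passing the threshold
    freqs: list[float] = []
    cols_of: dict[str, list[int]] = {c: [] for c in candidates}
    cand_set = set(candidates)
    for cl in library.cores:
        for s, f, car in zip(cl.haplotypes, cl.frequencies, cl.carriers):
            if f <= freq_threshold:
                continue  # library frequencies are > 0, so threshold 0 admits all
            carrying = [a for a in car if a in cand_set]
            if not carrying:
                continue
            col = len(freqs)
            freqs.append(float(f))
            for animal in carrying:
                cols_of[animal].append(col)
    f_arr = np.asarray(freqs)
    n_cols = len(f_arr)
    inc = np.zeros((len(candidates), n_cols), dtype=bool)
    order_pos = {c: k for k, c in enumerate(candidates)}
    for c, cols in cols_of.items():
        inc[order_pos[c], cols] = True

    unmasked = np.ones(n_cols, dtype=bool)
    remaining = sorted(candidates)
    chosen: list[str] = []
    scores: list[float] = []
    for _ in range(n_target):
        sc = inc[[order_pos[c] for c in remaining]] @ (f_arr * unmasked)
        best = float(sc.max()) if len(sc) else 0.0
        if best <= 0.0:
            break
        # ties (within float tolerance of the max) go to the smallest id;
        # remaining is id-sorted so the first qualifying index wins
        tied = np.nonzero(sc >= best - 1e-9)[0]
        pick = remaining[int(tied[0] if tie_rng is None else tie_rng.choice(tied))]
        chosen.append(pick)
        scores.append(best)
        unmasked &= ~inc[order_pos[pick]]
        remaining.remove(pick)
    for c in remaining:
        if len(chosen) >= n_target:
            break
        chosen.append(c)
        scores.append(0.0)
    return SelectionSet("H", chosen, scores)


# ---------------------------------------------------------------------------
# P1: relationship-maximizing greedy
# ---------------------------------------------------------------------------

def _explained_relationship(A_SS: np.ndarray, p_S: np.ndarray, eps: float = 1e-8) -> float:
    """J(S) = p_S' (A_SS + eps I)^{-1} p_S."""
    M = A_SS + eps * np.eye(len(p_S))
    try:
        x = np.linalg.solve(M, p_S)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "relationship submatrix singular beyond eps-regularization"
        ) from exc
    return float(p_S @ x)


def select_pedigree_relationship(
    nrm: RelationshipMatrix,
    candidates: Sequence[str],
    population: Sequence[str],
    n_target: int,
) -> SelectionSet:
    """Greedy forward selection maximizing the explained relationship J(S).

    p_S[i] is the mean relationship of selected animal i to the population;
    at each step the candidate whose addition gives the largest J is taken
    (ties to the smallest id).  J is non-decreasing along the greedy path.
    """
    candidates = sorted(str(c) for c in candidates)
    population = [str(p) for p in population]
    if n_target > len(candidates):
        raise ValueError("n_target exceeds candidate count")
    pop_idx = [nrm._pos[p] for p in population]
    pbar = {c: float(nrm.values[nrm._pos[c], pop_idx].mean()) for c in candidates}

    chosen: list[str] = []
    scores: list[float] = []
    j_prev = 0.0
    remaining = list(candidates)
    while len(chosen) < n_target:
        best_c, best_j = None, -np.inf
        for c in remaining:  # id order: first max wins ties
            S = chosen + [c]
            j = _explained_relationship(nrm.submatrix(S), np.array([pbar[i] for i in S]))
            if j > best_j + 1e-12:
                best_c, best_j = c, j
        assert best_c is not None
        if best_j < j_prev - 1e-9:
            logger.warning("explained relationship decreased at step %d", len(chosen) + 1)
        chosen.append(best_c)
        scores.append(best_j)
        remaining.remove(best_c)
        j_prev = best_j
    return SelectionSet("P1", chosen, scores)


# ---------------------------------------------------------------------------
# P2: key ancestors by marginal genetic contribution
# ---------------------------------------------------------------------------

def ancestor_contributions(
    pedigree: Pedigree,
    reference: Sequence[str],
    blocked: Sequence[str] = (),
) -> pd.Series:
    """Expected genetic contribution of every animal to ``reference``.

    The contribution of ancestor a to individual i follows the gene-origin
    recursion c(a->i) = 1 if i = a, 0 if i is blocked (and not a itself),
    else (c(a->sire) + c(a->dam))/2 with unknown parents contributing 0;
    the reported value is the mean over the reference animals.  Computed
    for all ancestors at once by one backward pass that propagates
    reference weight up the pedigree, with blocked animals absorbing
    (not forwarding) incoming weight.
    """
    reference = [str(r) for r in reference]
    if not reference:
        raise ValueError("reference population is empty")
    blocked_set = {str(b) for b in blocked}
    w0 = 1.0 / len(reference)
    order = pedigree.topological_order()
    pos = {a: k for k, a in enumerate(order)}
    received = np.zeros(len(order))
    for r in reference:
        received[pos[r]] += w0
    for aid in reversed(order):
        k = pos[aid]
        if received[k] == 0.0 or aid in blocked_set:
            continue
        s, d = pedigree.parents(aid)
        half = received[k] / 2.0
        if s != UNKNOWN:
            received[pos[s]] += half
        if d != UNKNOWN:
            received[pos[d]] += half
    # a blocked animal only keeps its own reference weight (self-path)
    contrib = received.copy()
    for b in blocked_set:
        if b in pos:
            contrib[pos[b]] = w0 * reference.count(b)
    return pd.Series(contrib, index=order)


def _explained_fraction(pedigree: Pedigree, selected: Sequence[str]) -> pd.Series:
    """Per animal: expected fraction of its genome originating from ``selected``.

    Forward gene-origin pass in topological order: a selected animal's
    genome is fully explained; otherwise the fraction is the parental mean
    (unknown parents contribute 0).
    """
    sel = {str(s) for s in selected}
    order = pedigree.topological_order()
    pos = {a: k for k, a in enumerate(order)}
    e = np.zeros(len(order))
    for aid in order:
        k = pos[aid]
        if aid in sel:
            e[k] = 1.0
            continue
        s, d = pedigree.parents(aid)
        acc = 0.0
        if s != UNKNOWN:
            acc += e[pos[s]]
        if d != UNKNOWN:
            acc += e[pos[d]]
        e[k] = acc / 2.0
    return pd.Series(e, index=order)


def select_key_ancestors(
    pedigree: Pedigree,
    reference: Sequence[str] | None = None,
    n_max: int | None = None,
    min_marginal: float = 1e-6,
    cum_threshold: float | None = 0.95,
    candidates: Sequence[str] | None = None,
) -> ContributionResult:
    """Sequentially pick the ancestors that best explain the reference genes.

    Each round recomputes marginal contributions with the already selected
    ancestors blocked on the descent paths AND discounts each candidate by
    the expected fraction of its own genome the selected set already
    explains, so every reference gene is credited to exactly one pick and
    the cumulative explained fraction can never exceed 1.  The argmax is
    taken (ties to smallest id); selection stops at ``n_max`` picks, a
    marginal below ``min_marginal``, or a cumulative explained fraction of
    at least ``cum_threshold`` (None disables).  ``reference`` defaults to
    generation 1, the most recent generation.
    """
    if reference is None:
        reference = pedigree.generation_members(1)
    reference = [str(r) for r in reference]
    if not reference:
        raise ValueError("reference population is empty")
    cand = set(str(c) for c in candidates) if candidates is not None else set(pedigree.ids)

    raw = ancestor_contributions(pedigree, reference)
    selected: list[str] = []
    raws: list[float] = []
    marginals: list[float] = []
    cums: list[float] = []
    total = 0.0
    limit = n_max if n_max is not None else len(pedigree)
    while len(selected) < limit:
        if selected:
            contrib = ancestor_contributions(pedigree, reference, blocked=selected)
            contrib = contrib * (1.0 - _explained_fraction(pedigree, selected))
        else:
            contrib = raw
        contrib = contrib.drop(labels=selected)
        contrib = contrib[contrib.index.isin(cand)]
        if contrib.empty:
            break
        best = contrib.max()
        if best < min_marginal:
            break
        pick = min(contrib.index[contrib >= best - 1e-15])
        selected.append(pick)
        raws.append(float(raw[pick]))
        marginals.append(float(best))
        total += float(best)
        cums.append(total)
        if cum_threshold is not None and total >= cum_threshold:
            break
    return ContributionResult(selected, raws, marginals, cums)


# ---------------------------------------------------------------------------
# C: combined 4-step heuristic
# ---------------------------------------------------------------------------

def _per_breed_ids(obj, pedigree: Pedigree, breed: str) -> list[str]:
    """Ordered ids of one breed from a SelectionSet/ContributionResult or a breed dict."""
    if isinstance(obj, Mapping):
        inner = obj.get(breed)
        return list(inner.ids) if inner is not None else []
    return [i for i in obj.ids if pedigree.breed_of(i) == breed]


def combine_selection(
    H: SelectionSet | Mapping[str, SelectionSet],
    P1: SelectionSet | Mapping[str, SelectionSet],
    P2: ContributionResult | Mapping[str, ContributionResult],
    pedigree: Pedigree,
    targets: Mapping[str, int],
) -> SelectionSet:
    """The practical 4-step merge of the H, P1 and P2 selections.

    Per breed, animals are added in step order until the breed budget is
    met, always skipping animals without available sample material:

    1. selected by H and by at least one of P1/P2 (H rank order);
    2. selected by both P1 and P2 (P1 rank order);
    3. in H with both sire and dam among the P2 key ancestors (H order);
    4. in H with exactly one parent among the P2 key ancestors (H order).

    If the budget cannot be met after step 4 a shorter set is returned
    with a warning.
    """
    chosen: list[str] = []
    scores: list[float] = []
    steps: list[int] = []
    for breed, budget in targets.items():
        h = _per_breed_ids(H, pedigree, breed)
        p1 = _per_breed_ids(P1, pedigree, breed)
        p2 = _per_breed_ids(P2, pedigree, breed)
        p1s, p2s = set(p1), set(p2)

        def parents_in_p2(a: str) -> int:
            s, d = pedigree.parents(a)
            return int(s in p2s) + int(d in p2s)

        step_pools = [
            (1, [a for a in h if a in p1s or a in p2s]),
            (2, [a for a in p1 if a in p2s]),
            (3, [a for a in h if parents_in_p2(a) == 2]),
            (4, [a for a in h if parents_in_p2(a) == 1]),
        ]
        n_breed = 0
        for step, pool in step_pools:
            for a in pool:
                if n_breed >= budget:
                    break
                if a in chosen or not pedigree.is_available(a):
                    continue
                chosen.append(a)
                scores.append(float(step))
                steps.append(step)
                n_breed += 1
        if n_breed < budget:
            warnings.warn(
                f"combined selection for breed {breed}: only {n_breed} of {budget} "
                "animals eligible after step 4",
                stacklevel=2,
            )
    return SelectionSet("C", chosen, scores, steps)


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------

def select_random(
    candidates: Sequence[str], n_target: int, rng: np.random.Generator
) -> SelectionSet:
    """Uniform sample without replacement; deterministic per rng state."""
    candidates = [str(c) for c in candidates]
    if n_target > len(candidates):
        raise ValueError("n_target exceeds candidate count")
    picks = rng.choice(np.asarray(candidates, dtype=object), size=n_target, replace=False)
    return SelectionSet("RANDOM", [str(p) for p in picks], [0.0] * n_target)
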