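"""Short time-series model-profile clustering of WS/WW fold-change series.

With only three observed occasions per gene, free-form clustering is
underdetermined; instead, genes are assigned to a fixed catalog of integer
"model profiles" — zero-anchored step sequences whose per-step change is
bounded — by maximizing the Pearson correlation between the gene's
fold-change series and the profile's levels.  Profile significance is judged
against a time-permutation null (each gene's observed occasions shuffled,
the anchor staying at zero), and significant profiles of the two genotypes
are matched to each other by level-vector correlation, the gene overlap of
matched profiles scored with a hypergeometric tail.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix
from .de import fold_change

logger = logging.getLogger("vinestress")


@dataclass(frozen=True)
class ModelProfile:
    """Integer temporal template: levels[0] = 0, |step| <= c."""

    id: int
    levels: tuple[int, ...]


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when either vector has zero variance."""
    sx = x - x.mean()
    sy = y - y.mean()
    nx = float(np.sqrt((sx**2).sum()))
    ny = float(np.sqrt((sy**2).sum()))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float((sx * sy).sum() / (nx * ny))


def profile_distance(a: tuple[int, ...] | np.ndarray, b: tuple[int, ...] | np.ndarray) -> float:
    """1 - Pearson r of two level vectors (zero-variance vectors give r = 0)."""
    return 1.0 - _safe_pearson(np.asarray(a, float), np.asarray(b, float))


# ---------------------------------------------------------------------------
# fold-change series
# ---------------------------------------------------------------------------

def build_fc_series(
    em: ExpressionMatrix, genotype: str, genes: list[str] | None = None
) -> pd.DataFrame:
    """Zero-anchored WS - WW log2 fold-change series per gene for one genotype.

    Columns are [anchor, t0, t1, ...]; the anchor column is 0 so series and
    model-profile levels share the same length.
    """
    sub = em if genes is None else em.subset(genes=genes)
    cols = {"anchor": pd.Series(0.0, index=sub.values.index)}
    for t in sub.timepoints:
        ww = sub.samples_where(genotype=genotype, treatment="WW", timepoint=t)
        ws = sub.samples_where(genotype=genotype, treatment="WS", timepoint=t)
        if not ww or not ws:
            raise ValueError(f"missing WW/WS cell for genotype {genotype!r} at timepoint {t}")
        cols[f"t{t}"] = fold_change(sub, ww, ws)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# profile catalog
# ---------------------------------------------------------------------------

def enumerate_candidate_profiles(T: int, c: int, drop_flat: bool = True) -> list[ModelProfile]:
    """All (2c+1)^T zero-anchored step sequences; ids follow enumeration order.

    Steps are drawn from {-c..c} in lexicographic order; the all-zero (flat)
    profile is removed when ``drop_flat`` but ids stay stable.
    """
    if T < 1 or c < 1:
        raise ValueError("need T >= 1 and c >= 1")
    profiles = []
    for pid, steps in enumerate(itertools.product(range(-c, c + 1), repeat=T)):
        levels = (0, *np.cumsum(steps).tolist())
        if drop_flat and all(l == 0 for l in levels):
            continue
        profiles.append(ModelProfile(id=pid, levels=levels))
    return profiles


def select_model_profiles(candidates: list[ModelProfile], m: int) -> list[ModelProfile]:
    """Greedy max-min subset of m profiles under 1 - Pearson distance.

    Seeded with the most distant pair (ties: lexicographically smallest id
    pair), then repeatedly adds the candidate maximizing its minimum
    distance to the chosen set (ties: lowest id).  Distance-0 duplicates are
    only added once everything else is exhausted.
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    if m > len(candidates):
        raise ValueError(f"m={m} exceeds {len(candidates)} candidates")
    if m == len(candidates):
        return list(candidates)
    levels = np.array([p.levels for p in candidates], dtype=float)
    n = len(candidates)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = profile_distance(levels[i], levels[j])
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > best[0]:
                best = (dist[i, j], (i, j))
    chosen = list(best[1])
    while len(chosen) < m:
        remaining = [i for i in range(n) if i not in chosen]
        min_d = dist[np.ix_(remaining, chosen)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax takes first = lowest id on ties
        chosen.append(pick)
    return [candidates[i] for i in sorted(chosen, key=lambda i: candidates[i].id)]


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class ProfileAssignment:
    """Gene -> model profile mapping with per-profile statistics."""

    profiles: list[ModelProfile]
    assignment: dict[str, int]                      # gene -> profile id
    unassigned: set[str] = field(default_factory=set)
    counts: dict[int, int] = field(default_factory=dict)
    expected: dict[int, float] = field(default_factory=dict)
    p_values: dict[int, float] = field(default_factory=dict)
    significant: set[int] = field(default_factory=set)

    @property
    def n_assigned(self) -> int:
        return len(self.assignment)

    def genes_of(self, profile_id: int) -> set[str]:
        return {g for g, p in self.assignment.items() if p == profile_id}


def _assign_matrix(series: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Correlation of each series (rows) with each profile level vector."""
    s = series - series.mean(axis=1, keepdims=True)
    l = levels - levels.mean(axis=1, keepdims=True)
    sn = np.sqrt((s**2).sum(axis=1))
    ln = np.sqrt((l**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (s @ l.T) / np.outer(sn, ln)
    return np.where(np.isfinite(corr), corr, -np.inf)


def assign_genes(series: pd.DataFrame, profiles: list[ModelProfile]) -> ProfileAssignment:
    """Assign each gene to the profile with maximal Pearson correlation.

    Ties break to the lowest profile id.  Flat (zero-variance) series go to
    the flat profile when one is in the catalog, otherwise they stay
    unassigned (logged).
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    ordered = sorted(profiles, key=lambda p: p.id)
    levels = np.array([p.levels for p in ordered], dtype=float)
    S = series.to_numpy(dtype=float)
    corr = _assign_matrix(S, levels)
    flat_ids = [p.id for p in ordered if len(set(p.levels)) == 1]
    assignment: dict[str, int] = {}
    unassigned: set[str] = set()
    best = np.argmax(corr, axis=1)  # first max = lowest id under the sorted order
    for i, gene in enumerate(series.index):
        if S[i].std() == 0.0:
            if flat_ids:
                assignment[gene] = flat_ids[0]
            else:
                unassigned.add(gene)
            continue
        assignment[gene] = ordered[int(best[i])].id
    if unassigned:
        logger.info("%d flat series left unassigned (no flat profile)", len(unassigned))
    counts = {p.id: 0 for p in ordered}
    for pid in assignment.values():
        counts[pid] += 1
    return ProfileAssignment(profiles=ordered, assignment=assignment,
                             unassigned=unassigned, counts=counts)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def profile_significance(
    assignment: ProfileAssignment,
    series: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> ProfileAssignment:
    """Per-profile enrichment p-values under a time-permutation null.

    Null expected counts come from reassigning every gene after permuting
    its observed occasions (the anchor stays 0): exhaustively over the T!
    permutations when T! <= 5040, otherwise over ``n_perm`` sampled
    permutations (``exhaustive`` forces either route).  The per-profile
    p-value is the binomial upper tail of the observed count given the null
    assignment probability; a profile is significant iff p * m < alpha
    (Bonferroni over the m catalog profiles).
    """
    ordered = assignment.profiles
    levels = np.array([p.levels for p in ordered], dtype=float)
    S = series.to_numpy(dtype=float)
    genes = list(series.index)
    T = S.shape[1] - 1
    perms = list(itertools.permutations(range(1, T + 1)))
    if exhaustive is None:
        exhaustive = len(perms) <= 5040
    if not exhaustive:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(np.arange(1, T + 1))) for _ in range(n_perm)]
    flat_ids = [p.id for p in ordered if len(set(p.levels)) == 1]

    null_counts = {p.id: 0.0 for p in ordered}
    flat_mask = S.std(axis=1) == 0.0
    for perm in perms:
        order = (0, *perm)
        corr = _assign_matrix(S[:, order], levels)
        best = np.argmax(corr, axis=1)
        for i in range(len(genes)):
            if flat_mask[i]:
                if flat_ids:
                    null_counts[flat_ids[0]] += 1
                continue
            null_counts[ordered[int(best[i])].id] += 1
    n_assigned = assignment.n_assigned
    m = len(ordered)
    expected = {pid: cnt / len(perms) for pid, cnt in null_counts.items()}
    p_values: dict[int, float] = {}
    significant: set[int] = set()
    for p in ordered:
        obs = assignment.counts.get(p.id, 0)
        prob = min(1.0, expected[p.id] / n_assigned) if n_assigned else 0.0
        pval = float(stats.binom.sf(obs - 1, n_assigned, prob)) if n_assigned else 1.0
        p_values[p.id] = pval
        if pval * m < alpha:
            significant.add(p.id)
    assignment.expected = expected
    assignment.p_values = p_values
    assignment.significant = significant
    return assignment


# ---------------------------------------------------------------------------
# two-genotype comparison
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatch:
    profile_a: int
    profile_b: int
    correlation: float
    n_intersection: int
    p_hypergeom: float


def compare_genotype_profiles(
    assign_a: ProfileAssignment,
    assign_b: ProfileAssignment,
    universe: set[str],
) -> list[ProfileMatch]:
    """Match each significant profile of genotype A to its best partner in B.

    The partner is the significant B profile whose level vector has maximal
    Pearson correlation with A's (r = 1.00 means the same shape); the gene
    intersection of the matched profiles is scored with a hypergeometric
    upper tail over the shared universe.
    """
    sig_b = [p for p in assign_b.profiles if p.id in assign_b.significant]
    if not sig_b:
        logger.info("no significant profiles in genotype B; empty comparison")
        return []
    out: list[ProfileMatch] = []
    N = len(universe)
    for p_a in assign_a.profiles:
        if p_a.id not in assign_a.significant:
            continue
        best, best_r = None, -np.inf
        for p_b in sig_b:
            r = _safe_pearson(np.asarray(p_a.levels, float), np.asarray(p_b.levels, float))
            if r > best_r:
                best, best_r = p_b, r
        genes_a = assign_a.genes_of(p_a.id) & universe
        genes_b = assign_b.genes_of(best.id) & universe
        k = len(genes_a & genes_b)
        p = float(stats.hypergeom.sf(k - 1, N, len(genes_b), len(genes_a)))
        out.append(ProfileMatch(p_a.id, best.id, float(best_r), k, p))
    return out
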