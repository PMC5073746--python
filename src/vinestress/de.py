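"""Staged differential-expression statistics for the water-stress design.

The selection cascade mirrors the study workflow on log2 intensities:

1. permutation-based SAM over the 12 design groups (2 genotypes x 2
   treatments x 3 timepoints) at a median-FDR target;
2. one-way ANOVA over the same groups with standard Bonferroni correction,
   applied to the SAM survivors;
3. per-genotype, per-timepoint WS vs WW fold-change (and optionally Welch
   t-test) filters;
4. a treatment-only rerun (6 groups, genotype ignored) and the
   inclusion-exclusion ledger of the resulting gene sets.

Also here: direction splits, fold-change ranking, row-median normalization,
PCA loading-percentile extraction and hierarchical leaf ordering for
heat maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import AnnotationTable, ExpressionMatrix

logger = logging.getLogger("vinestress")


# ---------------------------------------------------------------------------
# group bookkeeping
# ---------------------------------------------------------------------------

def _group_indices(labels: Sequence[str]) -> list[np.ndarray]:
    """Column index arrays per class, classes in sorted label order."""
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    groups = [np.flatnonzero(labels == c) for c in classes]
    if len(groups) < 2:
        raise ValueError("need at least 2 classes")
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise ValueError(f"class {c!r} has {len(g)} sample(s); need >= 2")
    return groups


def _between_within(X: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and within-class sums of squares per gene (row)."""
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in groups:
        xk = X[:, g]
        mk = xk.mean(axis=1)
        ssb += len(g) * (mk - grand) ** 2
        ssw += ((xk - mk[:, None]) ** 2).sum(axis=1)
    return ssb, ssw


# ---------------------------------------------------------------------------
# SAM (multiclass)
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    d: pd.Series
    significant: pd.Series
    s0: float
    delta: float
    cutoff: float
    fdr_percent_est: float

    @property
    def selected(self) -> set[str]:
        return set(self.significant.index[self.significant])


def sam_scores(X: np.ndarray, groups: list[np.ndarray], s0: float) -> np.ndarray:
    """Multiclass SAM statistic d = r / (s + s0) per row.

    r is the square root of the between-class sum of squares; s is the
    pooled standard error sqrt(sum_k 1/n_k * SSW/(n-K)), the multiclass
    analogue of the two-class denominator.
    """
    n = X.shape[1]
    K = len(groups)
    inv = sum(1.0 / len(g) for g in groups)
    ssb, ssw = _between_within(X, groups)
    r = np.sqrt(ssb)
    s = np.sqrt(inv * ssw / (n - K))
    den = s + s0
    return np.where(r > 0, r / np.where(den > 0, den, 1.0), 0.0)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimizing the coefficient of variation of the spread of
    d across windows of s (percentile-scan rule)."""
    if not np.any(r > 0) or not np.any(s > 0):
        return 0.0
    candidates = np.percentile(s, np.arange(0, 101, 5))
    # ~100 equal-occupancy windows of s
    order = np.argsort(s, kind="stable")
    n_bins = min(100, max(2, len(s) // 10))
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        den = s + s0
        d = np.where(r > 0, r / np.where(den > 0, den, 1.0), 0.0)
        mads = np.array([stats.median_abs_deviation(d[b], scale="normal") for b in bins])
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_multiclass(
    em: ExpressionMatrix,
    group_labels: Sequence[str],
    n_perm: int = 100,
    fdr_percent: float = 0.1,
    s0: float | None = None,
    seed: int = 0,
) -> SamResult:
    """Permutation SAM over K classes with a median-FDR threshold rule.

    The observed ordered statistics are compared with the mean ordered
    permuted statistics; the threshold delta is the smallest value whose
    estimated median FDR (median permuted exceedance count over calls) is at
    or below ``fdr_percent``.  The multiclass d is nonnegative, so only an
    upper cut applies.
    """
    X = em.values.to_numpy()
    groups = _group_indices(group_labels)
    n = X.shape[1]
    K = len(groups)
    inv = sum(1.0 / len(g) for g in groups)
    ssb, ssw = _between_within(X, groups)
    r = np.sqrt(ssb)
    s = np.sqrt(inv * ssw / (n - K))
    if s0 is None:
        s0 = _choose_s0(r, s)
    d = sam_scores(X, groups, s0)

    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, X.shape[0]))
    for p in range(n_perm):
        perm = rng.permutation(n)
        d_perm[p] = sam_scores(X[:, perm], groups, s0)
    d_perm_sorted = np.sort(d_perm, axis=1)
    dbar = d_perm_sorted.mean(axis=0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diff = d_sorted - dbar

    significant = np.zeros(X.shape[0], dtype=bool)
    chosen_delta, chosen_cut, chosen_fdr = np.inf, np.inf, 0.0
    pos = diff[diff > 0]
    if pos.size:
        deltas = np.unique(np.quantile(pos, np.linspace(0.0, 1.0, min(200, pos.size))))
        for delta in deltas:
            idx = np.flatnonzero(diff >= delta)
            if idx.size == 0:
                continue
            cut = d_sorted[idx[0]]
            called = d >= cut
            n_called = int(called.sum())
            if n_called == 0:
                continue
            false_counts = (d_perm >= cut).sum(axis=1)
            fdr = 100.0 * np.median(false_counts) / n_called
            if fdr <= fdr_percent:
                significant = called
                chosen_delta, chosen_cut, chosen_fdr = float(delta), float(cut), float(fdr)
                break
    index = em.values.index
    return SamResult(
        d=pd.Series(d, index=index, name="sam_d"),
        significant=pd.Series(significant, index=index, name="sam_significant"),
        s0=float(s0),
        delta=chosen_delta,
        cutoff=chosen_cut,
        fdr_percent_est=chosen_fdr,
    )


# ---------------------------------------------------------------------------
# ANOVA + Bonferroni
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: pd.Series
    p: pd.Series
    p_bonf: pd.Series
    selected_mask: pd.Series

    @property
    def selected(self) -> set[str]:
        return set(self.selected_mask.index[self.selected_mask])


def anova_bonferroni(
    em: ExpressionMatrix,
    group_labels: Sequence[str],
    alpha: float = 0.01,
    genes: Iterable[str] | None = None,
) -> AnovaResult:
    """One-way F test per gene; selected iff p * n_genes_tested <= alpha.

    ``genes`` restricts the tested family (e.g. survivors of a previous
    screen); the Bonferroni factor is the number of genes actually tested.
    Degenerate rows: zero within-group variance with unequal means gives
    p = 0 (selected); with equal means the F ratio is undefined and the
    gene is not selected (logged).
    """
    sub = em if genes is None else em.subset(genes=list(genes))
    X = sub.values.to_numpy()
    groups = _group_indices(group_labels)
    n = X.shape[1]
    K = len(groups)
    ssb, ssw = _between_within(X, groups)
    msb = ssb / (K - 1)
    msw = ssw / (n - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = np.empty(X.shape[0])
    regular = msw > 0
    p[regular] = stats.f.sf(F[regular], K - 1, n - K)
    degenerate_sig = (~regular) & (msb > 0)
    degenerate_flat = (~regular) & (msb <= 0)
    F[degenerate_sig] = np.inf
    p[degenerate_sig] = 0.0
    F[degenerate_flat] = 0.0
    p[degenerate_flat] = 1.0
    if degenerate_flat.any():
        logger.info("%d gene(s) constant within and between groups; not selected",
                    int(degenerate_flat.sum()))
    n_tested = X.shape[0]
    p_bonf = np.minimum(1.0, p * n_tested)
    selected = p * n_tested <= alpha
    idx = sub.values.index
    return AnovaResult(
        F=pd.Series(F, index=idx, name="anova_F"),
        p=pd.Series(p, index=idx, name="anova_p"),
        p_bonf=pd.Series(p_bonf, index=idx, name="anova_p_bonf"),
        selected_mask=pd.Series(selected, index=idx, name="anova_selected"),
    )


# ---------------------------------------------------------------------------
# fold change and Welch t
# ---------------------------------------------------------------------------

def fold_change(
    em: ExpressionMatrix, samples_a: Sequence[str], samples_b: Sequence[str]
) -> pd.Series:
    """Per-gene log2 fold change: mean(log2 B) - mean(log2 A)."""
    if not len(samples_a) or not len(samples_b):
        raise ValueError("both contrast groups must be nonempty")
    a = em.values[list(samples_a)].mean(axis=1)
    b = em.values[list(samples_b)].mean(axis=1)
    out = b - a
    out.name = "log2fc"
    return out


def fc_select(log2fc: pd.Series, fc_threshold: float, strict: bool = False) -> set[str]:
    """Genes passing |log2fc| >= log2(fc_threshold) (or > when strict)."""
    cut = np.log2(fc_threshold)
    mask = np.abs(log2fc) > cut if strict else np.abs(log2fc) >= cut
    return set(log2fc.index[mask])


def welch_t(
    em: ExpressionMatrix, samples_a: Sequence[str], samples_b: Sequence[str]
) -> tuple[pd.Series, pd.Series]:
    """Welch (unequal-variance) t-test per gene; returns (t, p)."""
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    a = em.values[list(samples_a)].to_numpy()
    b = em.values[list(samples_b)].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    idx = em.values.index
    return pd.Series(t, index=idx, name="t"), pd.Series(p, index=idx, name="t_p")


@dataclass
class ContrastSelection:
    """WS vs WW selection at one design cell."""

    genotype: str | None
    timepoint: int
    log2fc: pd.Series
    t_p: pd.Series
    selected: set[str] = field(default_factory=set)

    @property
    def up(self) -> set[str]:
        return {g for g in self.selected if self.log2fc[g] > 0}

    @property
    def down(self) -> set[str]:
        return {g for g in self.selected if self.log2fc[g] < 0}


def ttest_fc_select(
    em: ExpressionMatrix,
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    genes: Iterable[str] | None = None,
) -> dict[tuple[str, int], ContrastSelection]:
    """Per-genotype, per-timepoint WS vs WW Welch t + fold-change filter.

    A gene is selected iff p < p_threshold and |log2fc| >= log2(fc_threshold).
    Genes with an undefined t statistic (zero variance in both groups with
    equal means) are excluded with a logged count.
    """
    sub = em if genes is None else em.subset(genes=list(genes))
    out: dict[tuple[str, int], ContrastSelection] = {}
    for genotype in sub.genotypes:
        for t in sub.timepoints:
            ww = sub.samples_where(genotype=genotype, treatment="WW", timepoint=t)
            ws = sub.samples_where(genotype=genotype, treatment="WS", timepoint=t)
            if not ww or not ws:
                continue
            fc = fold_change(sub, ww, ws)
            _, p = welch_t(sub, ww, ws)
            nan = p.isna()
            if nan.any():
                logger.info("contrast %s t%d: %d gene(s) with undefined t excluded",
                            genotype, t, int(nan.sum()))
            mask = (~nan) & (p < p_threshold) & (np.abs(fc) >= np.log2(fc_threshold))
            out[(genotype, t)] = ContrastSelection(
                genotype=genotype,
                timepoint=t,
                log2fc=fc,
                t_p=p,
                selected=set(p.index[mask]),
            )
    return out


# ---------------------------------------------------------------------------
# set algebra, direction splits, ranking
# ---------------------------------------------------------------------------

@dataclass
class GeneSetLedger:
    """Named gene sets with inclusion-exclusion bookkeeping."""

    genotype_specific: set[str]
    treatment_only: set[str]
    annotation: AnnotationTable | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        return self.genotype_specific | self.treatment_only

    @property
    def intersection(self) -> set[str]:
        return self.genotype_specific & self.treatment_only

    @property
    def annotated_union(self) -> set[str]:
        if self.annotation is None:
            return set()
        return self.annotation.annotated_subset(self.union)

    def summary(self) -> dict[str, int]:
        n_a, n_b = len(self.genotype_specific), len(self.treatment_only)
        n_both = len(self.intersection)
        out = {
            "n_genotype_specific": n_a,
            "n_treatment_only": n_b,
            "n_shared": n_both,
            "n_union": n_a + n_b - n_both,
        }
        assert out["n_union"] == len(self.union)
        if self.annotation is not None:
            out["n_annotated_union"] = len(self.annotated_union)
        return out


def ws_union_ledger(
    genotype_specific: set[str],
    treatment_only: set[str],
    annotation: AnnotationTable | None = None,
) -> GeneSetLedger:
    """Ledger of the two selection routes and their union (the WS-modulated set)."""
    return GeneSetLedger(
        genotype_specific=set(genotype_specific),
        treatment_only=set(treatment_only),
        annotation=annotation,
        provenance={
            "genotype_specific": "12-group screen + per-genotype per-timepoint FC filter",
            "treatment_only": "6-group (treatment x timepoint) screen + pooled FC filter",
        },
    )


def overlap_percent(study: set[str], reference: set[str]) -> tuple[int, float]:
    """Shared-gene count and percentage of the study set found in the reference."""
    if not study:
        raise ValueError("study set is empty")
    shared = len(study & reference)
    return shared, 100.0 * shared / len(study)


@dataclass
class DirectionSplit:
    n_up: int
    n_down: int

    @property
    def total(self) -> int:
        return self.n_up + self.n_down


def direction_split(log2fc: pd.Series, selected: Iterable[str]) -> DirectionSplit:
    """Up/down counts among selected genes (a selected gene has log2fc != 0)."""
    sel = list(selected)
    vals = log2fc.loc[sel]
    return DirectionSplit(n_up=int((vals > 0).sum()), n_down=int((vals < 0).sum()))


def rank_by_fc(
    log2fc: pd.Series,
    top_n: int = 20,
    bottom_n: int = 20,
    annotation: AnnotationTable | None = None,
    annotated_only: bool = False,
    genes: Iterable[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Top and bottom genes by log2 fold change.

    Ordering is descending log2fc with ties broken by gene id ascending;
    ``annotated_only`` drops unannotated genes before ranking.  The top list
    is returned most-induced first, the bottom list most-repressed first.
    If fewer genes are available than requested, all are returned (logged).
    """
    series = log2fc if genes is None else log2fc.loc[list(genes)]
    if annotated_only:
        if annotation is None:
            raise ValueError("annotated_only requires an annotation table")
        series = series[[annotation.is_annotated(g) for g in series.index]]
    frame = series.rename("log2fc").to_frame()
    frame["gene"] = frame.index
    frame = frame.sort_values(["log2fc", "gene"], ascending=[False, True])
    if len(frame) < top_n or len(frame) < bottom_n:
        logger.info("rank_by_fc: only %d gene(s) available", len(frame))
    top = list(frame.index[:top_n])
    bottom = list(frame.index[::-1][:bottom_n])
    return top, bottom


# ---------------------------------------------------------------------------
# normalization, PCA, hierarchical ordering
# ---------------------------------------------------------------------------

def row_median_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's median (log2 scale); output row medians are 0."""
    values = em.values.sub(em.values.median(axis=1), axis=0)
    return ExpressionMatrix(values, list(em.design))


def pca_loading_extremes(
    em: ExpressionMatrix, component: int = 1, percentile: float = 1.0
) -> tuple[set[str], set[str], float]:
    """Genes in the extreme tails of a principal-component loading vector.

    Rows are centered, the SVD taken, and genes whose loading on the chosen
    component falls below the ``percentile``-th or above the
    (100 - percentile)-th percentile are returned together with the
    component's explained-variance fraction.  The loading sign is
    canonicalized (largest-|loading| gene positive) so the extracted sets are
    invariant to the sign ambiguity of the decomposition.
    """
    if em.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = em.values.to_numpy()
    X = X - X.mean(axis=1, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    if component < 1 or component > rank:
        raise ValueError(f"component {component} exceeds matrix rank {rank}")
    load = U[:, component - 1]
    if load[np.argmax(np.abs(load))] < 0:
        load = -load
    evf = float(S[component - 1] ** 2 / (S**2).sum())
    lo = np.percentile(load, percentile)
    hi = np.percentile(load, 100.0 - percentile)
    idx = em.values.index
    low_set = set(idx[load < lo])
    high_set = set(idx[load > hi])
    return low_set, high_set, evf


def hierarchical_order(values: pd.DataFrame, distance: str = "pearson") -> list[str]:
    """Average-linkage leaf ordering of rows for heat-map rendering.

    ``pearson`` uses 1 - r as the distance; a zero-variance row's distance
    to everything is defined as 1 (logged).  ``euclidean`` is the plain
    metric.
    """
    if values.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    X = values.to_numpy(dtype=float)
    if distance == "pearson":
        with np.errstate(divide="ignore", invalid="ignore"):
            dists = pdist(X, metric="correlation")
        if np.isnan(dists).any():
            logger.info("zero-variance row(s): correlation distance set to 1")
            dists = np.nan_to_num(dists, nan=1.0)
    elif distance == "euclidean":
        dists = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(dists, method="average")
    order = hierarchy.leaves_list(Z)
    return [values.index[i] for i in order]


# ---------------------------------------------------------------------------
# the full leaf cascade
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Aggregate of the staged screens and the final ledger."""

    stats: pd.DataFrame
    contrasts: dict[tuple[str, int], ContrastSelection]
    genotype_specific: set[str]
    treatment_only: set[str]
    ledger: GeneSetLedger
    sam12: SamResult
    anova12: AnovaResult
    sam6: SamResult
    anova6: AnovaResult


def leaf_cascade(
    em: ExpressionMatrix,
    sam_fdr_percent: float = 0.1,
    anova_alpha: float = 0.01,
    fc_threshold: float = 2.0,
    n_perm: int = 100,
    seed: int = 0,
    annotation: AnnotationTable | None = None,
) -> DEResult:
    """SAM -> ANOVA -> fold-change cascade over both grouping schemes.

    Route A (genotype-specific): 12-group SAM and Bonferroni ANOVA, then a
    per-genotype per-timepoint WS vs WW FC filter on the survivors.  Route B
    (treatment-only): the same screens over 6 treatment x timepoint groups
    with genotype pooled, then a pooled per-timepoint FC filter.  The ledger
    reports both sets, their intersection and union.
    """
    labels12 = em.group_labels(("genotype", "treatment", "timepoint"))
    sam12 = sam_multiclass(em, labels12, n_perm=n_perm, fdr_percent=sam_fdr_percent, seed=seed)
    survivors12: set[str] = set()
    anova12 = None
    if sam12.selected:
        anova12 = anova_bonferroni(em, labels12, alpha=anova_alpha, genes=sorted(sam12.selected))
        survivors12 = anova12.selected

    set_a: set[str] = set()
    if survivors12:
        for genotype in em.genotypes:
            for t in em.timepoints:
                ww = em.samples_where(genotype=genotype, treatment="WW", timepoint=t)
                ws = em.samples_where(genotype=genotype, treatment="WS", timepoint=t)
                if not ww or not ws:
                    continue
                fc = fold_change(em, ww, ws)
                set_a |= fc_select(fc.loc[sorted(survivors12)], fc_threshold)

    labels6 = em.group_labels(("treatment", "timepoint"))
    sam6 = sam_multiclass(em, labels6, n_perm=n_perm, fdr_percent=sam_fdr_percent, seed=seed + 1)
    survivors6: set[str] = set()
    anova6 = None
    if sam6.selected:
        anova6 = anova_bonferroni(em, labels6, alpha=anova_alpha, genes=sorted(sam6.selected))
        survivors6 = anova6.selected

    set_b: set[str] = set()
    if survivors6:
        for t in em.timepoints:
            ww = em.samples_where(treatment="WW", timepoint=t)
            ws = em.samples_where(treatment="WS", timepoint=t)
            fc = fold_change(em, ww, ws)
            set_b |= fc_select(fc.loc[sorted(survivors6)], fc_threshold)

    contrasts = ttest_fc_select(em, fc_threshold=fc_threshold)
    ledger = ws_union_ledger(set_a, set_b, annotation)

    stats_df = pd.DataFrame({"sam_d": sam12.d, "sam_significant": sam12.significant})
    if anova12 is not None:
        stats_df = stats_df.join(
            pd.DataFrame({
                "anova_F": anova12.F,
                "anova_p_bonf": anova12.p_bonf,
                "anova_selected": anova12.selected_mask,
            })
        )
    empty_sam = SamResult(
        d=pd.Series(dtype=float), significant=pd.Series(dtype=bool),
        s0=0.0, delta=np.inf, cutoff=np.inf, fdr_percent_est=0.0,
    )
    empty_anova = AnovaResult(
        F=pd.Series(dtype=float), p=pd.Series(dtype=float),
        p_bonf=pd.Series(dtype=float), selected_mask=pd.Series(dtype=bool),
    )
    return DEResult(
        stats=stats_df,
        contrasts=contrasts,
        genotype_specific=set_a,
        treatment_only=set_b,
        ledger=ledger,
        sam12=sam12,
        anova12=anova12 if anova12 is not None else empty_anova,
        sam6=sam6,
        anova6=anova6 if anova6 is not None else empty_anova,
    )


def day27_selection(
    em: ExpressionMatrix,
    p_threshold: float = 0.08,
    fc_threshold: float = 1.7,
    timepoint: int | None = None,
) -> ContrastSelection:
    """WS vs WW at the final occasion, genotype pooled: the network input set.

    Selection is p < p_threshold and FC > fc_threshold (strict, matching the
    'FC > 1.7' convention for this set).
    """
    t = em.timepoints[-1] if timepoint is None else timepoint
    ww = em.samples_where(treatment="WW", timepoint=t)
    ws = em.samples_where(treatment="WS", timepoint=t)
    fc = fold_change(em, ww, ws)
    _, p = welch_t(em, ww, ws)
    nan = p.isna()
    mask = (~nan) & (p < p_threshold) & (np.abs(fc) > np.log2(fc_threshold))
    return ContrastSelection(
        genotype=None, timepoint=t, log2fc=fc, t_p=p, selected=set(p.index[mask])
    )
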