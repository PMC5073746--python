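"""Hypergeometric overrepresentation of functional (GO-slim style) terms.

For a study set of n genes drawn from a population of N, a term annotating
K population genes, and k study hits, the enrichment p-value is the
hypergeometric upper tail P(X >= k).  The population is the set of genes on
the array (matrix rows), not the genome.  Correction presets: none (the
plain significance-threshold convention), Bonferroni, or Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("vinestress")


def hypergeometric_enrichment(
    study: set[str],
    population: set[str],
    term_map: Mapping[str, set[str]],
    alpha: float = 0.01,
    correction: str = "none",
) -> pd.DataFrame:
    """Per-term overrepresentation table, sorted by ascending p.

    Terms are intersected with the population; empty terms are skipped.
    Columns: term, k (study hits), n (study size), K (term size in
    population), N (population size), p, p_adj, significant.
    """
    if not study:
        raise ValueError("study set is empty")
    extra = study - population
    if extra:
        raise ValueError(f"study genes outside the population: {sorted(extra)[:5]}")
    if correction not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    N = len(population)
    n = len(study)
    rows = []
    for term, members in term_map.items():
        in_pop = members & population
        K = len(in_pop)
        if K == 0:
            continue
        k = len(in_pop & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "p_adj", "significant"])
    table = pd.DataFrame(rows)
    if correction == "none":
        table["p_adj"] = table["p"]
    elif correction == "bonferroni":
        table["p_adj"] = np.minimum(1.0, table["p"] * len(table))
    else:
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p", "term"]).reset_index(drop=True)


def map_to_slim(
    term_map: Mapping[str, set[str]],
    slim_terms: set[str],
    ancestry: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Collapse a term -> gene map onto a slim vocabulary via term ancestry.

    ``ancestry`` maps each term to its direct parents; each term's genes are
    reattributed to every slim ancestor (the union over paths), a term
    already in the slim mapping to itself.  Terms with no slim ancestor are
    dropped; a cycle in the ancestry raises.
    """
    cache: dict[str, frozenset[str]] = {}

    def slim_ancestors(term: str, trail: tuple[str, ...] = ()) -> frozenset[str]:
        if term in cache:
            return cache[term]
        if term in trail:
            raise ValueError(f"cycle in term ancestry at {term!r}")
        found = set()
        if term in slim_terms:
            found.add(term)
        for parent in ancestry.get(term, ()):  # walk upward
            found |= slim_ancestors(parent, trail + (term,))
        cache[term] = frozenset(found)
        return cache[term]

    slimmed: dict[str, set[str]] = {}
    for term, genes in term_map.items():
        for anc in slim_ancestors(term):
            slimmed.setdefault(anc, set()).update(genes)
    return slimmed
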