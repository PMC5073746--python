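"""Reference evaluations of the pipeline on its synthetic study conditions.

Each function here regenerates data from the simulator, runs the relevant
pipeline stage, and measures a recovery or calibration statistic.  They back
both the acceptance test suite and the standalone acceptance script, so the
numbers are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cartography, de, stem
from .enrich import hypergeometric_enrichment
from .simulate import SimulationConfig, plant_enrichment, plant_network_structure, simulate_experiment


# ---------------------------------------------------------------------------
# set-arithmetic worked examples
# ---------------------------------------------------------------------------

def venn_union_example(n_a: int = 1188, n_b: int = 437, n_shared: int = 300) -> dict[str, int]:
    """Union ledger for two selection routes of the given sizes and overlap."""
    shared = {f"shared{i}" for i in range(n_shared)}
    set_a = {f"a{i}" for i in range(n_a - n_shared)} | shared
    set_b = {f"b{i}" for i in range(n_b - n_shared)} | shared
    return de.ws_union_ledger(set_a, set_b).summary()


def direction_split_example(n_up: int = 765, n_down: int = 471) -> de.DirectionSplit:
    """Direction split of a selection with the given planted signs."""
    import pandas as pd

    genes = [f"g{i}" for i in range(n_up + n_down)]
    fc = pd.Series(np.concatenate([np.ones(n_up), -np.ones(n_down)]), index=genes)
    return de.direction_split(fc, genes)


def overlap_percent_example(n_study: int = 269, n_shared: int = 48) -> tuple[int, float]:
    """Percentage of a study set found in a reference set."""
    study = {f"s{i}" for i in range(n_study)}
    reference = {f"s{i}" for i in range(n_shared)} | {f"r{i}" for i in range(500)}
    return de.overlap_percent(study, reference)


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

@dataclass
class NullCalibration:
    sam_flags: list[int]
    union_sizes: list[int]

    @property
    def median_union(self) -> float:
        return float(np.median(self.union_sizes))

    @property
    def sam_within_5_rate(self) -> float:
        return float(np.mean([c <= 5 for c in self.sam_flags]))


def null_calibration(n_seeds: int = 50, n_genes: int = 1000, seed: int = 0) -> NullCalibration:
    """Full cascade on pure-noise datasets: SAM flag counts and final unions."""
    sam_flags, unions = [], []
    for i in range(n_seeds):
        s = seed + i
        em, _ = simulate_experiment(
            SimulationConfig(n_genes=n_genes, de_fraction=0.0, seed=s)
        )
        res = de.leaf_cascade(em, sam_fdr_percent=0.1, n_perm=100, seed=s)
        sam_flags.append(len(res.sam12.selected))
        unions.append(len(res.ledger.union))
    return NullCalibration(sam_flags=sam_flags, union_sizes=unions)


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class SwitchRecovery:
    f1_scores: list[float]
    subset_violations: int

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))


def switch_recovery(n_seeds: int = 50, seed: int = 0) -> SwitchRecovery:
    """Planted-switch recovery over 2-4 modules and 1-5 switch nodes per run.

    Also verifies on every run that the mined switch set is contained in the
    fight-club classification (its defining superset).
    """
    f1s, violations = [], 0
    for i in range(n_seeds):
        s = seed + i
        n_modules = 2 + i % 3
        n_switch = 1 + i % 5
        em, truth = plant_network_structure(
            SimulationConfig(module_spec=[(20, 0.9)] * n_modules, n_switch=n_switch, seed=s)
        )
        graph = cartography.build_correlation_network(em, threshold=0.6)
        res = cartography.heat_cartography(graph, em, seed=s)
        pred, true = res.switch_genes, truth.switch_genes
        tp = len(pred & true)
        prec = tp / len(pred) if pred else 0.0
        rec = tp / len(true) if true else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        violations += int(not res.switch_genes <= res.fight_club)
    return SwitchRecovery(f1_scores=f1s, subset_violations=violations)


def stem_recovery(n_seeds: int = 50, seed: int = 0) -> float:
    """Fraction of seeds where the planted temporal profile is significant.

    30% of genes carry a ramp-up fold-change profile at low noise; the
    profile the planted genes land on must pass the Bonferroni-corrected
    permutation test.
    """
    hits = 0
    profiles = stem.select_model_profiles(stem.enumerate_candidate_profiles(3, 2), 30)
    for i in range(n_seeds):
        s = seed + i
        em, truth = simulate_experiment(
            SimulationConfig(n_genes=200, profile_catalog=[((0, 1, 2, 2), 60)],
                             noise_sd=0.1, genotype_lag=False, seed=s)
        )
        series = stem.build_fc_series(em, "MP")
        assignment = stem.assign_genes(series, profiles)
        stem.profile_significance(assignment, series, alpha=0.05, seed=s)
        planted_profiles = {assignment.assignment[g] for g in truth.de_genes}
        # the dominant profile of the planted genes must be significant
        dominant = max(planted_profiles,
                       key=lambda pid: sum(assignment.assignment[g] == pid
                                           for g in truth.de_genes))
        hits += int(dominant in assignment.significant)
    return hits / n_seeds


def enrichment_recovery(n_seeds: int = 100, seed: int = 0) -> float:
    """Fraction of seeds where the planted term ranks first in the table."""
    hits = 0
    for i in range(n_seeds):
        s = seed + i
        em, truth = simulate_experiment(
            SimulationConfig(n_genes=500, de_fraction=0.1, seed=s)
        )
        term_map, _ = plant_enrichment(em.gene_ids, truth.de_genes, term_size=40,
                                       overlap=30, n_background_terms=50, seed=s)
        table = hypergeometric_enrichment(truth.de_genes, set(em.gene_ids), term_map)
        hits += int(table.iloc[0]["term"] == "TERM_PLANTED")
    return hits / n_seeds
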