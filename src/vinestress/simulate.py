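"""Synthetic expression datasets with planted, recoverable structure.

The generator emulates the statistical shape of a two-cultivar water-stress
microarray study — 2 genotypes x {WW, WS} x 3 timepoints x 3 replicates of
log2 intensities — and returns ground-truth labels alongside the matrix so
every downstream stage (differential-expression cascade, profile clustering,
network cartography, enrichment) can be tested end to end without any
external data.

Planted structure:

* treatment effects: a fraction of genes receive a WS - WW log2 offset that
  follows an integer temporal profile, optionally appearing one timepoint
  later in the second genotype (the "delayed responder" cultivar);
* correlation modules: groups of genes sharing a latent profile, tuned to a
  target intra-module Pearson r;
* switch genes: nodes built with a negative loading on two modules' latent
  factors, so their correlations to those modules' members are negative and
  they bridge modules above the edge threshold;
* one enriched functional term overlapping the treatment-responsive genes
  far above hypergeometric expectation, against uniform background terms.

Noise is additive Gaussian on the log2 scale (log-normal intensities), the
usual first-order model for microarray log intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleDesign

GENOTYPES = ("MP", "SG")

#: default planted temporal profiles (levels over [anchor, t1, t2, t3]):
#: early induction, late induction, progressive repression, transient pulse
DEFAULT_PROFILE_CATALOG: list[tuple[int, ...]] = [
    (0, 2, 2, 2),
    (0, 0, 1, 2),
    (0, -1, -2, -2),
    (0, 2, 1, 0),
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-like conditions."""

    n_genes: int = 2000
    n_timepoints: int = 3
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    de_fraction: float = 0.1
    effect_size_log2: float = 2.0
    #: planted profiles as (levels, gene count); None = default catalog with
    #: the DE genes split evenly
    profile_catalog: list[tuple[tuple[int, ...], int]] | None = None
    #: shift the WS offset one timepoint later in the second genotype
    genotype_lag: bool = True
    #: (module size, intra-module Pearson r target) per planted module
    module_spec: list[tuple[int, float]] = field(default_factory=list)
    n_switch: int = 0
    #: (term size, overlap with DE genes) for the planted enriched term
    enriched_term_spec: tuple[int, int] = (40, 30)
    n_background_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be >= 0")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for size, r in self.module_spec:
            if size < 5:
                raise ValueError("module sizes must be >= 5")
            if r >= 1.0:
                raise ValueError("intra-module correlation target must be < 1")
        if self.n_timepoints < 1 or self.n_replicates < 2:
            raise ValueError("need >= 1 timepoint and >= 2 replicates")


@dataclass
class SyntheticTruth:
    """Ground-truth labels planted by the generator."""

    de_genes: set[str] = field(default_factory=set)
    profile_of: dict[str, int] = field(default_factory=dict)
    profile_levels: dict[int, tuple[int, ...]] = field(default_factory=dict)
    module_of: dict[str, int] = field(default_factory=dict)
    switch_genes: set[str] = field(default_factory=set)
    enriched_term: str | None = None
    enriched_members: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "de_genes": sorted(self.de_genes),
            "profile_of": self.profile_of,
            "profile_levels": {str(k): list(v) for k, v in self.profile_levels.items()},
            "module_of": self.module_of,
            "switch_genes": sorted(self.switch_genes),
            "enriched_term": self.enriched_term,
            "enriched_members": sorted(self.enriched_members),
        }


def _make_design(config: SimulationConfig) -> list[SampleDesign]:
    design = []
    for g in GENOTYPES:
        for trt in ("WW", "WS"):
            for t in range(config.n_timepoints):
                for r in range(1, config.n_replicates + 1):
                    design.append(
                        SampleDesign(f"{g}_{trt}_T{t}_R{r}", g, trt, t, r)
                    )
    return design


def _resolve_catalog(config: SimulationConfig) -> list[tuple[tuple[int, ...], int]]:
    if config.profile_catalog is not None:
        catalog = list(config.profile_catalog)
    else:
        n_de = int(round(config.de_fraction * config.n_genes))
        base, extra = divmod(n_de, len(DEFAULT_PROFILE_CATALOG))
        catalog = [
            (levels, base + (1 if i < extra else 0))
            for i, levels in enumerate(DEFAULT_PROFILE_CATALOG)
        ]
    for levels, _ in catalog:
        if len(levels) != config.n_timepoints + 1 or levels[0] != 0:
            raise ValueError(
                f"profile levels must have length T+1 and start at 0, got {levels}"
            )
    total = sum(n for _, n in catalog)
    if total > config.n_genes:
        raise ValueError(
            f"profile catalog asks for {total} genes but n_genes={config.n_genes}"
        )
    return catalog


def simulate_experiment(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Full factorial dataset with planted treatment x time x genotype effects.

    DE genes receive the planted WS - WW log2 offset scaled so the profile's
    peak |offset| equals ``effect_size_log2``; with ``genotype_lag`` the
    offset appears one timepoint later in the second genotype.  Non-DE genes
    share means across treatments.  Same seed, same bytes.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    catalog = _resolve_catalog(config)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.tile(baselines[:, None], (1, len(design)))

    truth = SyntheticTruth()
    gene_cursor = 0
    for pid, (levels, count) in enumerate(catalog):
        peak = max(1, max(abs(l) for l in levels))
        lev_a = np.asarray(levels, dtype=float)
        lev_b = np.concatenate([[0.0], lev_a[:-1]]) if config.genotype_lag else lev_a
        scale = config.effect_size_log2 / peak
        for _ in range(count):
            gene = genes[gene_cursor]
            gi = gene_cursor
            gene_cursor += 1
            truth.de_genes.add(gene)
            truth.profile_of[gene] = pid
            for j, s in enumerate(design):
                if s.treatment != "WS":
                    continue
                lev = lev_a if s.genotype == GENOTYPES[0] else lev_b
                values[gi, j] += scale * lev[s.timepoint + 1]
        truth.profile_levels[pid] = tuple(levels)

    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    frame = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in design])
    return ExpressionMatrix(frame, design), truth


def plant_network_structure(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Dataset slice with planted correlation modules and switch nodes.

    Module members are ``sqrt(r) * z_m + sqrt(1-r) * eps`` around a gene
    baseline, where ``z_m`` is the module's latent profile across samples,
    so the intra-module Pearson correlation targets ``r``.  Each switch node
    loads negatively on two modules' latents, ``-(z_a + z_b)/sqrt(2)``, so
    its correlation with members of both modules is about
    ``-sqrt(r_s * r / 2)`` — negative, and above a moderate |r| edge
    threshold for tight modules.
    """
    if not config.module_spec:
        raise ValueError("module_spec must be nonempty")
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n_samples = len(design)
    amplitude = 1.0  # log2-units swing of the latent profiles

    latents = rng.standard_normal((len(config.module_spec), n_samples))
    truth = SyntheticTruth()
    rows: list[np.ndarray] = []
    genes: list[str] = []

    for m, (size, r) in enumerate(config.module_spec):
        for i in range(size):
            gene = f"MOD{m:02d}_{i:03d}"
            eps = rng.standard_normal(n_samples)
            profile = np.sqrt(r) * latents[m] + np.sqrt(1.0 - r) * eps
            base = rng.normal(config.baseline_mean, config.baseline_sd)
            rows.append(base + amplitude * profile)
            genes.append(gene)
            truth.module_of[gene] = m
    for j in range(config.n_switch):
        a = j % len(config.module_spec)
        b = (j + 1) % len(config.module_spec)
        if a == b:  # single planted module: negate its latent outright
            mix = -latents[a]
        else:
            mix = -(latents[a] + latents[b]) / np.sqrt(2.0)
        r_s = float(np.mean([config.module_spec[a][1], config.module_spec[b][1]]))
        eps = rng.standard_normal(n_samples)
        profile = np.sqrt(r_s) * mix + np.sqrt(1.0 - r_s) * eps
        gene = f"SWITCH_{j:02d}"
        base = rng.normal(config.baseline_mean, config.baseline_sd)
        rows.append(base + amplitude * profile)
        genes.append(gene)
        truth.switch_genes.add(gene)

    frame = pd.DataFrame(np.vstack(rows), index=genes, columns=[s.sample_id for s in design])
    return ExpressionMatrix(frame, design), truth


def plant_enrichment(
    genes: list[str],
    de_genes: set[str],
    term_size: int,
    overlap: int,
    n_background_terms: int,
    seed: int,
    background_size: int | None = None,
) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """Term map with one planted overrepresented term plus uniform background.

    The planted term takes ``overlap`` members from the DE set and the rest
    from the non-DE pool; background terms are uniform random gene sets of
    ``background_size`` (default: ``term_size``).
    """
    if term_size <= 0:
        raise ValueError("term size must be > 0")
    if term_size > len(genes):
        raise ValueError("term size exceeds the gene universe")
    if overlap > term_size or overlap > len(de_genes):
        raise ValueError("overlap exceeds term size or DE set size")
    rng = np.random.default_rng(seed)
    de_sorted = sorted(de_genes)
    non_de = sorted(set(genes) - de_genes)
    hits = list(rng.choice(de_sorted, size=overlap, replace=False)) if overlap else []
    fillers = list(rng.choice(non_de, size=term_size - overlap, replace=False))
    planted = set(hits) | set(fillers)

    term_map: dict[str, set[str]] = {"TERM_PLANTED": planted}
    bg_size = background_size or term_size
    universe = np.asarray(genes)
    for i in range(n_background_terms):
        members = rng.choice(universe, size=min(bg_size, len(genes)), replace=False)
        term_map[f"TERM_BG{i:03d}"] = set(members)

    truth = SyntheticTruth(
        de_genes=set(de_genes),
        enriched_term="TERM_PLANTED",
        enriched_members=planted,
    )
    return term_map, truth
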