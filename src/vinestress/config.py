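"""YAML configuration: every pipeline threshold is a named key with a default.

Defaults follow the study conditions the pipeline was built around; any of
them can be overridden from a YAML file passed to the CLI or to
:func:`load_config`.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "data": {
        # expression tables are log2 intensities; set true to log2-transform
        # linear intensities at load
        "linear_scale": False,
        # calendar labels for the ordinal timepoints (days after stress onset)
        "timepoint_days": [2, 6, 27],
    },
    "simulate": {
        "n_genes": 2000,
        "n_replicates": 3,
        "n_timepoints": 3,
        "baseline_mean": 8.0,
        "baseline_sd": 1.5,
        "noise_sd": 0.25,
        "de_fraction": 0.1,
        "effect_size_log2": 2.0,
        "genotype_lag": True,
        "n_background_terms": 50,
        "term_size": 40,
        "term_overlap": 30,
    },
    "de": {
        "sam_fdr_percent": 0.1,        # median-FDR target for the SAM screen
        "sam_n_perm": 100,
        "anova_alpha": 0.01,           # Bonferroni-corrected family level
        "fc_threshold": 2.0,           # FC >= 2  <=>  |dlog2| >= 1
        "t_p_threshold": 0.01,
        "day27_p": 0.08,               # network input set: p < 0.08, FC > 1.7
        "day27_fc": 1.7,
        "rws_fc": 3.0,                 # re-watering filter: FC >= 3 or <= -3
        "rank_top_n": 20,
        "rank_bottom_n": 20,
        "pca_percentile": 1.0,
    },
    "stem": {
        "max_unit_change": 2,          # c: per-step level change bound
        "n_profiles": 30,              # m: model profiles kept
        "n_perm": 1000,
        "alpha": 0.05,                 # Bonferroni over the m profiles
        "drop_flat": True,
    },
    "network": {
        "threshold": 0.6,              # edge rule: |pearson r| >= threshold
        "p_variant": "clusterphobic",  # or "guimera"
        "k_range": [2, 10],
        "kmeans_restarts": 10,
        "hub_z": 2.5,
        # non-hub region bounds on P: R1 <= r2_lo < R2 <= r3_lo < R3 <= r4_lo < R4
        "region_bounds": {"r2_lo": 0.05, "r3_lo": 0.62, "r4_lo": 0.80},
        "hub_region_bounds": {"r6_lo": 0.30, "r7_lo": 0.75},
        "party_apcc": 0.5,             # party hub: APCC > 0.5; date: 0 < APCC <= 0.5
        "fight_club_hubs_only": False,
    },
    "enrich": {
        "alpha": 0.01,                 # leaf preset; berries used 0.05
        "correction": "none",          # none | bonferroni | bh
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with Path(path).open() as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return _merge(DEFAULTS, override)
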