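"""Shared domain containers for the water-stress transcriptome pipeline.

The experiment is a 2-genotype x 2-treatment x 3-timepoint x 3-replicate
microarray design on leaf tissue: two grapevine cultivars (an isohydric and
an anisohydric one) are grown well-watered (WW) or water-stressed (WS) and
sampled at three occasions during the stress window, with an optional
re-watered condition (RWS) as a fourth sampling occasion.  Expression values
are log2 intensities throughout.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vinestress")

TREATMENTS = ("WW", "WS", "RWS")


class FormatError(ValueError):
    """Raised when an on-disk table violates its format contract."""


@dataclass(frozen=True)
class SampleDesign:
    """One sample (array hybridization): genotype, watering regime, occasion.

    ``timepoint`` is an ordinal index 0..T-1; the mapping to calendar days
    (e.g. 2, 6, 27 days after stress imposition) lives in the label map of
    the experiment, not here.  Profile methods rank occasions rather than
    spacing them.
    """

    sample_id: str
    genotype: str
    treatment: str
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.timepoint < 0:
            raise ValueError("timepoint index must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def cell(self) -> tuple[str, str, int]:
        return (self.genotype, self.treatment, self.timepoint)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities with its sample design.

    ``values`` is a DataFrame indexed by gene id whose columns are sample
    ids, ordered exactly as ``design``.
    """

    values: pd.DataFrame
    design: list[SampleDesign]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.design]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        keys = [(s.genotype, s.treatment, s.timepoint, s.replicate) for s in self.design]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (genotype, treatment, timepoint, replicate) in design")
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns do not match design sample ids")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    # -- basic geometry ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def timepoints(self) -> list[int]:
        return sorted({s.timepoint for s in self.design})

    @property
    def genotypes(self) -> list[str]:
        return sorted({s.genotype for s in self.design})

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.design],
                "genotype": [s.genotype for s in self.design],
                "treatment": [s.treatment for s in self.design],
                "timepoint": [s.timepoint for s in self.design],
                "replicate": [s.replicate for s in self.design],
            }
        )

    # -- selection helpers ------------------------------------------------
    def samples_where(
        self,
        genotype: str | None = None,
        treatment: str | None = None,
        timepoint: int | None = None,
    ) -> list[str]:
        """Sample ids matching the given design cell (None = any)."""
        out = []
        for s in self.design:
            if genotype is not None and s.genotype != genotype:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            if timepoint is not None and s.timepoint != timepoint:
                continue
            out.append(s.sample_id)
        return out

    def group_labels(self, factors: Sequence[str] = ("genotype", "treatment", "timepoint")) -> list[str]:
        """Composite class label per sample, e.g. 12 groups for the full design."""
        df = self.design_frame()
        return [":".join(str(row[f]) for f in factors) for _, row in df.iterrows()]

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        values = self.values
        design = self.design
        if genes is not None:
            values = values.loc[list(genes)]
        if samples is not None:
            samples = list(samples)
            values = values[samples]
            by_id = {s.sample_id: s for s in self.design}
            design = [by_id[s] for s in samples]
        return ExpressionMatrix(values.copy(), list(design))

    def check_replication(self, min_replicates: int = 2) -> None:
        """Variance-based tests need >= 2 replicates in every design cell."""
        counts: dict[tuple, int] = {}
        for s in self.design:
            counts[s.cell] = counts.get(s.cell, 0) + 1
        bad = [cell for cell, n in counts.items() if n < min_replicates]
        if bad:
            raise ValueError(f"design cells with <{min_replicates} replicates: {bad}")


class AnnotationTable(Mapping):
    """gene id -> functional annotation string; unknown genes map to ''."""

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map = {k: (v or "") for k, v in (mapping or {}).items()}

    def __getitem__(self, gene: str) -> str:
        return self._map.get(gene, "")

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def is_annotated(self, gene: str) -> bool:
        return bool(self._map.get(gene, ""))

    def annotated_subset(self, genes) -> set[str]:
        return {g for g in genes if self.is_annotated(g)}
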