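import numpy as np
import pandas as pd
import pytest

from vinestress.core import ExpressionMatrix, SampleDesign


def full_design(n_timepoints: int = 3, n_replicates: int = 3,
                genotypes=("MP", "SG"), treatments=("WW", "WS")) -> list[SampleDesign]:
    design = []
    for g in genotypes:
        for trt in treatments:
            for t in range(n_timepoints):
                for r in range(1, n_replicates + 1):
                    design.append(SampleDesign(f"{g}_{trt}_T{t}_R{r}", g, trt, t, r))
    return design


def make_matrix(values: np.ndarray, design: list[SampleDesign],
                gene_ids: list[str] | None = None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=gene_ids, columns=[s.sample_id for s in design])
    return ExpressionMatrix(frame, design)


@pytest.fixture
def design36() -> list[SampleDesign]:
    return full_design()


@pytest.fixture
def null_matrix(design36) -> ExpressionMatrix:
    """100 genes of pure N(8, 0.25^2) noise over the full design."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8.0, 0.25, (100, len(design36))), design36)
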