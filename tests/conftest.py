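import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pclstx import (
    PairedContrastModel,
    SimulationConfig,
    simulate_ortholog_map,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study shared across test modules."""
    return simulate_study(SimulationConfig(n_genes=1500, seed=20))


@pytest.fixture(scope="session")
def de_results(study):
    """Fitted paired contrasts for both species of the shared study."""
    out = {}
    for sp in ("human", "mouse"):
        model = PairedContrastModel.from_counts(
            study.counts[sp], study.metadata[sp], count_filter=None
        )
        out[sp] = model.fit()
    return out


@pytest.fixture(scope="session")
def ortholog_pairs(study):
    return simulate_ortholog_map(
        study.config.n_genes, seed=study.config.seed, truth=study.truth
    )


def make_results_from_signs(signs: np.ndarray, contrast_ids, gene_ids):
    """Build a long-form results table whose sign table equals ``signs``.

    Each +1/-1 becomes (log2fc=+-1, p_adj=0.01), each 0 (log2fc=0, p_adj=1).
    """
    rows = []
    for i, g in enumerate(gene_ids):
        for j, c in enumerate(contrast_ids):
            s = signs[i, j]
            rows.append(
                {
                    "gene_id": g,
                    "contrast_id": c,
                    "log2fc": float(s),
                    "p": 0.01 if s else 1.0,
                    "p_adj": 0.01 if s else 1.0,
                    "n_pairs": 7,
                }
            )
    return pd.DataFrame(rows)
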