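import numpy as np
import pandas as pd
import pytest

from emtstrat import ExpressionMatrix, SignatureRegistry, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale synthetic config: same structure, smaller counts."""
    return SyntheticConfig(
        seed=7,
        n_malignant=4000,
        n_normal_epithelial=800,
        n_endothelial=150,
        n_perivascular=80,
        n_caf=150,
        n_immune=300,
        n_decoy_genes=20,
        n_bulk=150,
    )


def make_matrix(values, obs_ids=None, gene_ids=None, scale="log_normalized", obs_kind="cell"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        obs_ids=obs_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"G{j}" for j in range(g)],
        values=values,
        scale=scale,
        obs_kind=obs_kind,
    )


@pytest.fixture
def emt_matrix_builder():
    """Matrix over the 12 EMT genes with chosen per-cell epithelial and
    mesenchymal values."""
    from emtstrat import EMT_EPITHELIAL_GENES, EMT_MESENCHYMAL_GENES

    def build(cells: dict[str, tuple[float, float]]):
        genes = list(EMT_MESENCHYMAL_GENES) + list(EMT_EPITHELIAL_GENES)
        rows = []
        for _, (mes, epi) in cells.items():
            rows.append([mes] * 6 + [epi] * 6)
        return make_matrix(np.array(rows), obs_ids=list(cells), gene_ids=genes)

    return build


@pytest.fixture
def default_registry():
    return SignatureRegistry.with_defaults()
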