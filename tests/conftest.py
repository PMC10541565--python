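import numpy as np
import pytest

from molstage import ExpressionTensor, SampleMeta, generate_dataset, screen_genes
from molstage.scale import build_scale


def make_tensor(series_profiles, n_replicates=3, gene_ids=None, noise=0.0, seed=0):
    """Assemble an ExpressionTensor from per-series gene profiles.

    ``series_profiles`` maps (cultivar, vintage) -> array (timepoints x genes)
    of condition-mean expression; replicates repeat the mean, optionally with
    additive noise.
    """
    rng = np.random.default_rng(seed)
    meta, blocks = [], []
    n_genes = next(iter(series_profiles.values())).shape[1]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    for (cult, vint), prof in series_profiles.items():
        for t in range(prof.shape[0]):
            meta.append(SampleMeta(
                condition_id=f"{cult}_{vint}_T{t + 1:02d}",
                cultivar=cult, vintage=vint, timepoint=t + 1,
            ))
            reps = np.tile(prof[t], (n_replicates, 1))
            if noise:
                reps = reps * np.exp(rng.normal(0, noise, reps.shape))
            blocks.append(reps)
    return ExpressionTensor(np.stack(blocks), gene_ids, meta, n_replicates)


@pytest.fixture(scope="session")
def default_dataset():
    """Training-design synthetic dataset shared by the slower tests."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def built_scale(default_dataset):
    tensor, _ = default_dataset
    core, _ = screen_genes(tensor)
    artifact, model = build_scale(tensor, core)
    return artifact, model, core
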