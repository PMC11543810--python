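import numpy as np
import pytest

import cellformer as cf


@pytest.fixture(scope="session")
def separable_raw():
    """Three balanced, well-separated cell types (raw counts)."""
    cfg = cf.synthetic.PROFILES["separable"]
    return cf.simulate_counts(cfg)


@pytest.fixture(scope="session")
def separable_hvg(separable_raw):
    """Separable fixture taken through QC → normalize → HVG, labels aligned."""
    x, labels, markers, _ = separable_raw
    hvg, kept = cf.preprocess(x)
    pos = {c: i for i, c in enumerate(x.cell_ids)}
    labels = cf.encode_labels(
        [labels.labels[pos[c]] for c in hvg.cell_ids], labels.vocabulary
    )
    return hvg, labels, markers, kept


@pytest.fixture(scope="session")
def small_trained(separable_hvg):
    """A quickly trained small model on a 120-cell subset (shared by tests)."""
    hvg, labels, _, _ = separable_hvg
    rng = np.random.default_rng(7)
    idx = np.sort(rng.choice(hvg.n_cells, size=120, replace=False))
    x = hvg.dense()[idx]
    lab = labels.subset(idx)
    mc = cf.ModelConfig(d=32, n_layers=2, n_heads=2, seed=7)
    tc = cf.TrainConfig(epochs=120, seed=7)
    params, history = cf.train(x, lab, None, mc, tc)
    return x, lab, mc, tc, params, history
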