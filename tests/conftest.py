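"""Shared fixtures: one mid-sized synthetic atlas reused across modules."""

import numpy as np
import pytest

from eyeatlas.io_preprocess import normalize_log
from eyeatlas.synthetic import SyntheticConfig, generate_atlas


@pytest.fixture(scope="session")
def atlas():
    """Two-species atlas, 1000 cells/species, with its human normalized matrix."""
    cfg = SyntheticConfig(n_cells=1000, seed=11)
    matrices, truth = generate_atlas(cfg)
    normalized = normalize_log(matrices["human"])
    return {"config": cfg, "matrices": matrices, "truth": truth, "normalized": normalized}


@pytest.fixture(scope="session")
def truth_regulons(atlas):
    """Ground-truth regulons as Regulon objects (unit importance)."""
    from eyeatlas.regulons import Regulon

    truth = atlas["truth"]
    return [Regulon(tf, [(g, 1.0) for g in targets], min_targets=5)
            for tf, targets in truth.regulons.items()]
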