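"""Shared fixtures: synthetic pools and a trained classifier.

The expensive pieces (mining pseudo hairpins from CDS-like sequence,
folding the positive pool) are session-scoped and generated
programmatically — no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from premir.classifier import MirnaSVM, build_datasets
from premir.features import encode
from premir.fold import fold, parse_anatomy
from premir.prefilter import extract_pseudo
from premir.synth import hairpin_pool, make_cds_like

POS_POOL_SEED = 11
NEG_POOL_SEED = 12


def featurize(seq: str):
    structure = fold(seq)
    return encode(seq, structure, parse_anatomy(structure.dotbracket))


@pytest.fixture(scope="session")
def pos_pool():
    """~200 planted-hairpin feature vectors (multiloop folds excluded)."""
    feats = []
    for rec in hairpin_pool(240, seed=POS_POOL_SEED):
        structure = fold(rec.seq)
        anatomy = parse_anatomy(structure.dotbracket)
        if anatomy.n_hairpin_loops == 1:
            feats.append(encode(rec.seq, structure, anatomy))
    assert len(feats) >= 220
    return feats


@pytest.fixture(scope="session")
def neg_pool():
    """Pseudo-hairpin feature vectors mined from CDS-like sequence with
    the relaxed genome cascade (the fixture-scale counterpart of
    full-cascade mining over a whole CDS catalogue)."""
    cds = make_cds_like(90, 4000, seed=NEG_POOL_SEED)
    windows = extract_pseudo(cds, mode="genome", limit=240)
    assert len(windows) >= 240
    return [featurize(w.seq) for w in windows]


@pytest.fixture(scope="session")
def trained(pos_pool, neg_pool):
    """(split, results) for seed 1, reused wherever a fitted model is needed."""
    split = build_datasets(pos_pool, neg_pool, seed=1)
    results = MirnaSVM.from_split(split).fit(seed=1)
    return split, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
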