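import numpy as np
import pytest

from cavnet import CLASS_LABELS, decompose_blob, features_table, generate_blob

BLOBS_PER_CLASS = 12
POPULATION_SEED = 0


@pytest.fixture(scope="session")
def cav_population():
    """A desk-scale population of planted blobs: 12 per class, fixed seed.

    Returns (blobs, class_labels, features DataFrame, decompositions at the
    80 nm module PT).  Session-scoped because featurizing ~50 blobs is the
    most expensive fixture in the suite.
    """
    streams = np.random.SeedSequence(POPULATION_SEED).spawn(
        4 * BLOBS_PER_CLASS)
    labels = [c for c in CLASS_LABELS for _ in range(BLOBS_PER_CLASS)]
    blobs = [generate_blob(cls, np.random.default_rng(s))
             for cls, s in zip(labels, streams)]
    feats = features_table([b.molecule_positions for b in blobs])
    decomps = [decompose_blob(b.molecule_positions, 80.0) for b in blobs]
    return blobs, labels, feats, decomps
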