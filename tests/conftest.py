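import numpy as np
import pytest

from dpphqsar import curation, descriptors, synthetic


@pytest.fixture(scope="session")
def tiny_fixture():
    """40-molecule corrupted raw table with its ground-truth manifest."""
    library, pic50, params = synthetic.make_modeling_dataset(40, seed=7)
    frame, manifest = synthetic.corrupt_to_raw_table(library, pic50, seed=7, planted=params)
    return library, pic50, frame, manifest


@pytest.fixture(scope="session")
def small_modeling_data():
    """120 molecules: scaled clean descriptor matrix + planted pIC50."""
    library, pic50, params = synthetic.make_modeling_dataset(120, seed=5)
    canon = [curation.standardize_structure(s).canonical_smiles for s in library]
    m = descriptors.clean_matrix(descriptors.compute_descriptors(canon, ids=canon))
    scaled = descriptors.apply_scaler(m, descriptors.fit_scaler(m))
    return scaled, np.asarray(pic50), params
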