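"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from haruspex.model_annotation import assign_secondary_structure
from haruspex.phantoms import (build_ideal_helix, build_antiparallel_sheet,
                               build_nucleic_chain, random_phantom_spec,
                               make_phantom_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def helix12():
    return build_ideal_helix(12)


@pytest.fixture(scope="session")
def sheet2x9():
    return build_antiparallel_sheet(2, 9)


@pytest.fixture(scope="session")
def nucleic18():
    return build_nucleic_chain(18)


@pytest.fixture(scope="session")
def helix12_labels(helix12):
    return assign_secondary_structure(helix12)


@pytest.fixture(scope="session")
def phantom_segments():
    """A small phantom dataset shared across training-related tests."""
    specs = [random_phantom_spec(kind, seed=100 + i)
             for i, kind in enumerate(["helix", "sheet", "nucleotide"] * 2)]
    segments, phantoms = make_phantom_dataset(specs)
    assert len(segments) >= 4
    return segments, phantoms
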