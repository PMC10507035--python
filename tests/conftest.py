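"""Shared fixtures: ideal structures, the benchmark scenario and its spectra."""

from dataclasses import replace

import numpy as np
import pytest

from viscaselect import ExcitonParameters, FrequencyGrid, HelixSpec, build_ideal_helix
from viscaselect.frame_selection import compute_library_spectra
from viscaselect.synthetic_fixtures import _build_backbone, combine_frames, flat_vs_upright_scenario


@pytest.fixture
def params():
    return ExcitonParameters()


@pytest.fixture
def grid():
    return FrequencyGrid.default()


@pytest.fixture
def helix20():
    """Ideal 20-residue alpha-helix, axis along z."""
    return build_ideal_helix(HelixSpec(20))


@pytest.fixture
def extended_chain():
    """Fully extended 20-residue chain (phi = psi = 180)."""
    return _build_backbone(np.full(20, 180.0), np.full(20, 180.0))


@pytest.fixture
def two_strand_sheet():
    """Two hydrogen-bonded beta strands (in-register laterally displaced
    copies, a parallel-sheet-like arrangement): a chirally ordered
    cross-strand fixture that both DSSP implementations assign as strand."""
    s1 = _build_backbone(np.full(8, -139.0), np.full(8, 135.0))
    s2 = replace(
        s1,
        xyz=s1.xyz + np.array([-2.5, 4.0, 0.0]),
        chain_ids=np.array(["B"] * s1.n_atoms, dtype=object),
    )
    return combine_frames(s1, s2)


@pytest.fixture(scope="session")
def scenario():
    return flat_vs_upright_scenario(n_frames=200, seed=7)


@pytest.fixture(scope="session")
def scenario_spectra(scenario):
    return compute_library_spectra(scenario.ensemble, ExcitonParameters())
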