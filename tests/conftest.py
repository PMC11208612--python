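import numpy as np
import pytest

import spinnerpop as sp


@pytest.fixture
def rng():
    return np.random.default_rng(20240626)


@pytest.fixture
def small_design():
    return sp.StudyDesign.balanced(3, 2)


@pytest.fixture
def study_scale():
    """Study-condition design and generating truth (8x6, S=0.95, p=0.3)."""
    design = sp.study_design()
    return design, sp.study_truth(design)


@pytest.fixture
def simple_structure():
    """Smallest sensible Markovian structure (10 free parameters at 8x6)."""
    return sp.ModelStructure(s="constant", p="constant", pent="constant",
                             phi="constant", emigration="markovian",
                             psi_time=False)


def random_msord_params(rng, design, interior=True):
    """Random valid parameters; interior keeps them away from 0/1."""
    lo, hi = (0.2, 0.8) if interior else (0.0, 1.0)
    T = design.n_primary
    u = lambda size: rng.uniform(lo, hi, size)
    return sp.MSORDParams(
        S=u(T - 1),
        p=[u(J) for J in design.secondaries_per_primary],
        pent=[rng.dirichlet(np.ones(J))
              for J in design.secondaries_per_primary],
        phi=[u(max(J - 1, 0)) for J in design.secondaries_per_primary],
        psi_PE=u(T - 1), psi_EE=u(T - 1),
    )
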