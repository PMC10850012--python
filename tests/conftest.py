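import numpy as np
import pytest

from pondweb import (
    blank_ee, monoculture_fixture, polyculture_fixture, solve_missing,
)


@pytest.fixture(scope="session")
def mono_model():
    return monoculture_fixture()


@pytest.fixture(scope="session")
def poly_model():
    return polyculture_fixture()


@pytest.fixture(scope="session")
def mono_balanced(mono_model):
    """Monoculture pond re-balanced from scratch: every living EE blanked
    and recovered by the solver, detritus EEs from the pool budgets."""
    return solve_missing(blank_ee(mono_model))


@pytest.fixture(scope="session")
def poly_balanced(poly_model):
    return solve_missing(blank_ee(poly_model))


def permuted(model, order):
    """Model with groups reordered; used for order-invariance checks."""
    from pondweb import EcopathModel
    order = list(order)
    groups = [model.groups[i] for i in order]
    diet = model.diet[np.ix_(order, order)]
    return EcopathModel(groups, diet, model.period_days, model.label)
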