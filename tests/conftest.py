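import numpy as np
import pytest

from cherrydiff import model_core as mc
from cherrydiff import synthetic_data as sd
from cherrydiff.estimation import DyeCondition

#: study-scale dimensionless parameters (cherry geometry, fast red-gardenia
#: condition): A = r_inner/r_flesh, H the skin Robin factor
STUDY_A = 0.084
STUDY_H = 5.565


@pytest.fixture(scope="session")
def geom() -> mc.Geometry:
    return mc.Geometry.cherry()


@pytest.fixture(scope="session")
def study_eig() -> mc.EigenSystem:
    return mc.solve_eigenvalues(STUDY_A, STUDY_H, 220)


@pytest.fixture()
def one_condition() -> DyeCondition:
    return DyeCondition("erythrosine", 60.0, 238.0)


@pytest.fixture()
def small_design(one_condition) -> sd.StudyDesign:
    return sd.StudyDesign(conditions=(one_condition,), noise_sigma=0.0, seed=0)
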