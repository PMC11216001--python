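import importlib.util
import sys
from pathlib import Path

import numpy as np
import pytest

from careseq import default_calibration, generate_cohort

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def default_params():
    return default_calibration()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """One modest default-calibrated cohort for unit tests."""
    p = default_params.copy()
    p.n_children = 900
    return generate_cohort(p, seed=42)


@pytest.fixture(scope="session")
def full_cohort(default_params):
    """One full-size (n=3205) default cohort."""
    return generate_cohort(default_params, seed=7)


def _load_acceptance_module():
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", REPO_ROOT / "scripts" / "acceptance.py")
    mod = importlib.util.module_from_spec(spec)
    sys.modules["acceptance_script"] = mod
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def acceptance_results():
    """Full 200-replicate recovery study, computed once per session."""
    mod = _load_acceptance_module()
    return mod.run(seed=1)


def planted_truths():
    """Published values the default calibration plants in the generator."""
    return {
        "ate_lowest_or": 3.181,
        "cde_private_group_or": 3.778,
        "cde_single_professional_or": 2.420,
        "multinomial_sp_lowest_or": 0.089,
        "fully_adjusted_pg_rr": 0.832,
        "typology_prevalence_pct": {"Parents, friends & family": 35.8,
                                    "Grandparents": 32.7,
                                    "Private group childcare": 23.5,
                                    "Single professional care": 8.1},
        "raised_td_pct": 10.9,
        "sweep4_formal_pct": 92.4,
    }


@pytest.fixture(scope="session")
def truths():
    return planted_truths()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240523)
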