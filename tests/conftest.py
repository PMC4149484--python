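import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ystar.calls import SiteFilterPolicy
from ystar.clock import ClockModel
from ystar.matrices import AlleleCountMatrix, CallMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def clock():
    return ClockModel()


@pytest.fixture
def policy():
    return SiteFilterPolicy()


def make_call_matrix(patterns: dict[str, str]) -> CallMatrix:
    """Build a CallMatrix from sample -> state-string (one char per site)."""
    samples = list(patterns)
    n_sites = len(next(iter(patterns.values())))
    sites = pd.DataFrame(
        {
            "pos": np.arange(n_sites),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    states = np.array([list(patterns[s]) for s in samples], dtype="<U1")
    return CallMatrix(samples, sites, states)


def make_count_matrix(ref: dict[str, list], alt: dict[str, list]) -> AlleleCountMatrix:
    samples = list(ref)
    n_sites = len(next(iter(ref.values())))
    sites = pd.DataFrame(
        {
            "pos": np.arange(n_sites),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    r = np.array([ref[s] for s in samples])
    a = np.array([alt[s] for s in samples])
    return AlleleCountMatrix(samples, sites, r, a)
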