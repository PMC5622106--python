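import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from igfab.electrostatics import IonizableSite, SolventModel, MODEL_PKA


@pytest.fixture
def solvent():
    return SolventModel()


@pytest.fixture
def solvent_no_salt():
    return SolventModel(ionic_strength=0.0)


def make_site(stype, xyz, name=None):
    return IonizableSite(name or f"{stype}@{xyz}", stype, MODEL_PKA[stype],
                         np.asarray(xyz, dtype=float))


@pytest.fixture
def salt_bridge_sites():
    """An Asp and a Lys 4 Angstrom apart."""
    return [make_site("Asp", (0.0, 0.0, 0.0)), make_site("Lys", (4.0, 0.0, 0.0))]


def random_site_system(rng, n_sites=None, box=15.0, min_dist=3.0):
    """Random ionisable-site system in a box with a minimum separation."""
    types = list(MODEL_PKA)
    n = n_sites or int(rng.integers(2, 13))
    coords = []
    while len(coords) < n:
        c = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(c - o) >= min_dist for o in coords):
            coords.append(c)
    return [make_site(types[rng.integers(len(types))], c, name=f"s{i}")
            for i, c in enumerate(coords)]
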