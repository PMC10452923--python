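import numpy as np
import pytest

from surfagg.core import Box, Frame, Trajectory
from surfagg.synthetic import SyntheticSpec, build_peptide, make_system, plant_configuration


@pytest.fixture(scope="session")
def beta_template():
    return build_peptide("beta")


@pytest.fixture(scope="session")
def bent_template():
    return build_peptide("bent")


@pytest.fixture()
def two_peptide_system():
    return make_system(2)


def random_frame(nmol: int, rng: np.random.Generator, box_l: float = 4.0,
                 surface: bool = False) -> tuple:
    """Peptides dropped at random positions/orientations in a periodic box:
    random contact graphs for oracle comparisons."""
    from scipy.spatial.transform import Rotation

    system = make_system(nmol)
    coords = np.zeros((system.n_atoms, 3))
    tpl = build_peptide("beta")
    for p in range(nmol):
        rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        com = rng.uniform(0, box_l, 3)
        coords[system.peptide_atoms[p]] = (tpl - tpl.mean(axis=0)) @ rot.T + com
    flags = (True, True, False) if surface else (True, True, True)
    return system, Frame(time=0.0, coords=coords, box=Box((box_l,) * 3, flags))


def union_find_partition(n: int, edges) -> list:
    """Independent clustering oracle: explicit union-find over contact edges."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((tuple(sorted(g)) for g in groups.values()),
                  key=lambda c: (-len(c), c[0]))


def brute_force_min_image(a, b, lengths, periodic):
    """27-image enumeration, independent of the package's wrapping code."""
    best = np.inf
    shifts = [(-1, 0, 1) if p else (0,) for p in periodic]
    for sx in shifts[0]:
        for sy in shifts[1]:
            for sz in shifts[2]:
                img = np.asarray(b, float) + np.array([sx, sy, sz]) * np.asarray(lengths)
                best = min(best, float(np.linalg.norm(np.asarray(a, float) - img)))
    return best
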