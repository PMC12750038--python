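import numpy as np
import pytest

from ligeval.structures import Atom, Ligand
from ligeval.synthetic import make_complex, perturb_pose


@pytest.fixture
def ring_complex():
    return make_complex(seed=11, ligand_template="ring6", pocket_size=8, target_id="RING")


@pytest.fixture
def branched_complex():
    return make_complex(seed=12, ligand_template="branched", pocket_size=8, target_id="BRAN")


@pytest.fixture
def hybrid_complex():
    return make_complex(seed=13, ligand_template="hybrid", pocket_size=10, target_id="HYBR")


@pytest.fixture
def identity_prediction(ring_complex):
    return perturb_pose(ring_complex, "translate", 0.0, seed=1)


def random_ligand(rng: np.random.Generator, n_max: int = 8) -> Ligand:
    """Random connected molecule: spanning tree plus occasional extra edge."""
    n = int(rng.integers(4, n_max + 1))
    elements = rng.choice(["C", "N", "O"], size=n)
    coords = rng.normal(scale=2.0, size=(n, 3))
    bonds = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        bonds.append((j, i, 1))
    if n >= 5 and rng.random() < 0.4:  # close a ring sometimes
        existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if (int(i), int(j)) not in existing:
            bonds.append((int(i), int(j), 1))
    atoms = [Atom(e, f"{e}{k+1}", c) for k, (e, c) in enumerate(zip(elements, coords))]
    return Ligand(atoms, bonds, "rand")


def brute_force_valid_permutations(lig: Ligand) -> list[tuple[int, ...]]:
    """All element- and adjacency-preserving permutations, by exhaustive search.

    Permutations of each element class are enumerated independently and the
    assembled permutation is kept iff it maps the edge set onto itself.
    """
    import itertools

    heavy = lig.heavy_indices()
    elements = [lig.atoms[i].element.upper() for i in heavy]
    edges = set()
    pos_of = {a: p for p, a in enumerate(heavy)}
    for i, j, _ in lig.bonds:
        if i in pos_of and j in pos_of:
            a, b = pos_of[i], pos_of[j]
            edges.add((min(a, b), max(a, b)))
    classes = {}
    for p, e in enumerate(elements):
        classes.setdefault(e, []).append(p)
    keys = sorted(classes)
    valid = []
    for combo in itertools.product(
        *(itertools.permutations(classes[k]) for k in keys)
    ):
        perm = [0] * len(heavy)
        for k, images in zip(keys, combo):
            for src, dst in zip(classes[k], images):
                perm[src] = dst
        mapped = {(min(perm[a], perm[b]), max(perm[a], perm[b])) for a, b in edges}
        if mapped == edges:
            valid.append(tuple(perm))
    return sorted(valid)
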