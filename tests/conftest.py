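import numpy as np
import pandas as pd
import pytest

from cgkit.frames import ATOM_COLUMNS, Frame


def bead_cloud(coords, size_class="regular", molname="P1", resname="M1",
               role="SC", group_size=None, molid=0):
    """Minimal tagged frame from raw coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if group_size:
        resid = np.repeat(np.arange(n // group_size) + 1, group_size)
    else:
        resid = np.arange(n) + 1
    atoms = pd.DataFrame({
        "molid": np.full(n, molid), "molname": molname, "resid": resid,
        "resname": resname, "name": "B", "type": "C1",
        "size_class": size_class, "role": role, "charge": np.zeros(n),
        "mass": np.full(n, 72.0), "flags": [""] * n}, columns=ATOM_COLUMNS)
    return Frame(coords, atoms)


def brute_force_components(frame, members, eps, min_samples):
    """Independent clustering oracle: connected components of the
    entity-level threshold graph (min bead-bead distance, minimum image),
    with components smaller than min_samples treated as noise.

    Valid whenever no borderline (DBSCAN border-point) configurations exist.
    """
    import networkx as nx

    n = len(members)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    box = frame.box
    for i in range(n):
        for j in range(i + 1, n):
            d = frame.coords[members[i]][:, None, :] \
                - frame.coords[members[j]][None, :, :]
            if box is not None:
                d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=2)) <= eps:
                g.add_edge(i, j)
    labels = np.full(n, -1)
    cid = 0
    for comp in nx.connected_components(g):
        if len(comp) >= min_samples:
            for k in comp:
                labels[k] = cid
            cid += 1
    return labels


def partitions_equal(a, b):
    """Compare two label arrays as partitions (noise must match exactly)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
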