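"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations — breadth-first
flood fill for 3-D labelling, literal all-pairs loops for the neighbour
box rule — kept separate from the implementation so the tests compare two
independent routes to the same answer.
"""

from collections import deque

import numpy as np
import pytest

from astral import synthetic
from astral.event_catalog import EventTable, generate_metadata


@pytest.fixture(scope="session")
def boundary_fixtures():
    return synthetic.make_boundary_fixtures()


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """BFS connected components, 26-neighbourhood, labels in scan order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = [
        (dt, dy, dx)
        for dt in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dt, dy, dx) != (0, 0, 0)
    ]
    current = 0
    for seed in np.ndindex(mask.shape):
        if not mask[seed] or labels[seed]:
            continue
        current += 1
        queue = deque([seed])
        labels[seed] = current
        while queue:
            t, y, x = queue.popleft()
            for dt, dy, dx in offsets:
                n = (t + dt, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not labels[n]:
                        labels[n] = current
                        queue.append(n)
    return labels


@pytest.fixture(scope="session")
def flood_fill_oracle():
    return flood_fill_label


def brute_force_neighbours(table: EventTable, tol_xy: float, tol_t: float):
    """Literal all-pairs padded-box test; returns ordered id pairs."""
    pairs = set()
    for e in table.records:
        ct, cy, cx = e.centroid
        ht = max(abs(v[0] - ct) for v in e.voxels) + tol_t
        hy = max(abs(v[1] - cy) for v in e.voxels) + tol_xy
        hx = max(abs(v[2] - cx) for v in e.voxels) + tol_xy
        for f in table.records:
            if f.id == e.id:
                continue
            for t, y, x in f.voxels:
                if abs(t - ct) <= ht and abs(y - cy) <= hy and abs(x - cx) <= hx:
                    pairs.add((e.id, f.id))
                    break
    return pairs


@pytest.fixture(scope="session")
def neighbour_oracle():
    return brute_force_neighbours


def table_from_voxel_sets(voxel_sets, shape=None, intensity=1.0):
    """Build an EventTable from explicit voxel lists over a uniform stack."""
    voxel_sets = [np.asarray(v) for v in voxel_sets]
    if shape is None:
        top = np.max([v.max(axis=0) for v in voxel_sets], axis=0) + 1
        shape = tuple(int(x) for x in np.maximum(top, 2))
    stack = np.full(shape, float(intensity))
    return generate_metadata({i + 1: v for i, v in enumerate(voxel_sets)}, stack)


@pytest.fixture(scope="session")
def make_table():
    return table_from_voxel_sets


def random_events(rng, n_events, shape=(40, 120, 120), max_voxels=6):
    """Random small voxel clusters, pairwise disjoint, as an EventTable."""
    sets = []
    occupied = set()
    while len(sets) < n_events:
        t0 = rng.integers(0, shape[0] - 3)
        y0 = rng.integers(0, shape[1] - 3)
        x0 = rng.integers(0, shape[2] - 3)
        k = rng.integers(1, max_voxels + 1)
        vox = {(t0, y0, x0)}
        while len(vox) < k:
            t, y, x = next(iter(vox))
            cand = (
                min(t0 + rng.integers(0, 3), shape[0] - 1),
                min(y0 + rng.integers(0, 3), shape[1] - 1),
                min(x0 + rng.integers(0, 3), shape[2] - 1),
            )
            vox.add(cand)
        if vox & occupied:
            continue
        occupied |= vox
        sets.append(np.array(sorted(vox)))
    return table_from_voxel_sets(sets, shape=shape)


@pytest.fixture(scope="session")
def make_random_events():
    return random_events


@pytest.fixture(scope="session")
def recovery_run():
    """One fixed-seed end-to-end run on the planted recovery scene."""
    from astral import Config
    from astral.pipeline import run_pipeline

    spec = synthetic.recovery_scene(seed=1)
    stack, truth = synthetic.generate_stack(spec)
    result = run_pipeline(stack, Config(n_cells=20))
    return spec, stack, truth, result
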