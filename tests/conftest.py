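"""Shared fixtures and builders for the corflow test suite."""

from __future__ import annotations

import numpy as np
import pytest

from corflow.geometry import BranchGeometry, CoronaryTree, MyocardiumMask


def straight_branch(
    branch_id: str = "LAD",
    label: str = "LAD",
    length: float = 100.0,
    radius: float = 1.5,
    n_pts: int = 11,
    origin=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
    parent_id: str | None = None,
    attach_index: int | None = None,
    radii=None,
) -> BranchGeometry:
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = np.linspace(0.0, length, n_pts)
    points = origin + t[:, None] * direction
    r = np.full(n_pts, radius) if radii is None else np.asarray(radii, dtype=float)
    return BranchGeometry(
        branch_id=branch_id,
        parent_id=parent_id,
        attach_index=attach_index,
        label=label,
        points=points,
        radii=r,
    )


def single_branch_tree(**kwargs) -> CoronaryTree:
    label = kwargs.get("label", "LAD")
    kwargs.setdefault("branch_id", label)
    b = straight_branch(**kwargs)
    return CoronaryTree(artery_label=label, branches={b.branch_id: b})


def random_tree(rng: np.random.Generator, n_branches: int = 8, label: str = "LAD") -> CoronaryTree:
    """A random valid tree: branches attach at random parent indices."""
    branches = {}
    n0 = rng.integers(4, 9)
    root = straight_branch(
        branch_id=label, label=label, length=float(rng.uniform(40, 80)), n_pts=int(n0),
        radii=rng.uniform(1.0, 2.5, int(n0)),
    )
    branches[root.branch_id] = root
    ids = [root.branch_id]
    for k in range(n_branches - 1):
        parent_id = ids[rng.integers(0, len(ids))]
        parent = branches[parent_id]
        attach = int(rng.integers(1, parent.n_points))
        n = int(rng.integers(3, 7))
        start = parent.points[attach]
        direction = rng.normal(size=3)
        b = straight_branch(
            branch_id=f"{label}.{k}",
            label="SIDE",
            length=float(rng.uniform(15, 40)),
            n_pts=n,
            origin=start + direction / np.linalg.norm(direction) * 0.5,
            direction=direction,
            parent_id=parent_id,
            attach_index=attach,
            radii=rng.uniform(0.4, 1.8, n),
        )
        branches[b.branch_id] = b
        ids.append(b.branch_id)
    return CoronaryTree(artery_label=label, branches=branches)


def box_mask(shape=(6, 6, 6), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> MyocardiumMask:
    voxels = np.ones(shape, dtype=bool)
    return MyocardiumMask(voxels=voxels, spacing=np.asarray(spacing), origin=np.asarray(origin))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
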