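"""Synthetic spatial transcriptomics tissues.

The generator emulates a layered cortical tissue: cells sit on a pixel
lattice segmented into four parallel bands (or six stripes mapped to two
alternating domains), each layer has its own multinomial cell-type
composition with the dominance order rotating across layers, and counts come
from a gamma-Poisson ("splat-type") simulator with group-specific
multiplicative differential-expression factors and log-normal library sizes.
Single-cell tissues can be aggregated to square-grid subspots and 3x3-merged
spots, and a cell-split variant redistributes the counts of a random subset
of cells to their nearest neighbors to mimic the count sharing of spot-level
platforms.

Cell-type composition scenarios (proportions by dominance rank):

=========  ==========================  ==========================
scenario   ranks                       note
=========  ==========================  ==========================
S1         70 / 10 / 10 / 10           one dominant type
S2         45 / 45 / 5 / 5             two equal dominants
S3         60 / 30 / 5 / 5             two unequal dominants
S4         35 / 30 / 30 / 5            three major types
stripe1    60 / 40                     two-domain stripes
stripe2    60 / 30 / 5 / 5             two-domain stripes
stripe3    60 / 20 / 20                two-domain stripes
=========  ==========================  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SyntheticTissue",
    "SCENARIOS",
    "make_layered_tissue",
    "assign_cell_types",
    "simulate_counts_splatlike",
    "attach_counts",
    "aggregate_to_spots",
    "cell_split",
]

Layout = Literal["bands4", "stripes6"]

# dominance order of the four cell types in each of the four layers
LAYER_TYPE_ORDERS = ((1, 2, 3, 4), (2, 3, 4, 1), (3, 4, 1, 2), (4, 1, 2, 3))
# the stripe layouts have two domains
STRIPE_TYPE_ORDERS = ((1, 2, 3, 4), (2, 3, 4, 1))

#: proportions by dominance rank for each scenario
SCENARIOS: dict[str, tuple[float, ...]] = {
    "S1": (0.70, 0.10, 0.10, 0.10),
    "S2": (0.45, 0.45, 0.05, 0.05),
    "S3": (0.60, 0.30, 0.05, 0.05),
    "S4": (0.35, 0.30, 0.30, 0.05),
    "stripe1": (0.60, 0.40, 0.0, 0.0),
    "stripe2": (0.60, 0.30, 0.05, 0.05),
    "stripe3": (0.60, 0.20, 0.20, 0.0),
}

# splat-type distribution constants
GENE_MEAN_SHAPE = 0.6
GENE_MEAN_RATE = 0.3
DE_FACTOR_LOC = 0.1
DE_FACTOR_SCALE = 0.4
LIBSIZE_LOC = 11.0
LIBSIZE_SCALE = 0.2


@dataclass
class SyntheticTissue:
    """Cells on a lattice with layers, types, counts and aggregation maps."""

    cell_coords: np.ndarray  # n_cells x 2, pixel units
    layer_labels: np.ndarray  # per-cell domain label, 1-based
    lattice: tuple[int, int]  # (width, height) of the pixel lattice
    seed: int
    cell_types: np.ndarray | None = None  # per-cell group 1..4
    counts: np.ndarray | None = None  # genes x cells integer matrix
    subspot_coords: np.ndarray | None = None
    subspot_labels: np.ndarray | None = None
    subspot_counts: np.ndarray | None = None
    subspot_map: np.ndarray | None = None  # cell -> subspot index
    spot_coords: np.ndarray | None = None
    spot_labels: np.ndarray | None = None
    spot_counts: np.ndarray | None = None
    spot_map: np.ndarray | None = None  # subspot -> spot index

    @property
    def n_cells(self) -> int:
        return self.cell_coords.shape[0]


def make_layered_tissue(
    n_cells: int,
    lattice: tuple[int, int] = (110, 98),
    layout: Layout = "bands4",
    seed: int = 0,
) -> SyntheticTissue:
    """Sample cell positions on the lattice and label them by region.

    ``bands4`` splits the lattice into four equal-height horizontal bands
    labeled 1-4; ``stripes6`` splits it into six equal-width vertical stripes
    alternately assigned to domains 1 and 2.
    """
    width, height = lattice
    if n_cells > width * height:
        raise ValueError("n_cells exceeds the number of lattice sites")
    rng = np.random.default_rng(seed)
    flat = rng.choice(width * height, size=n_cells, replace=False)
    coords = np.column_stack([flat % width, flat // width]).astype(float)
    if layout == "bands4":
        labels = np.minimum((coords[:, 1] / (height / 4)).astype(int), 3) + 1
    elif layout == "stripes6":
        stripe = np.minimum((coords[:, 0] / (width / 6)).astype(int), 5)
        labels = (stripe % 2) + 1  # odd stripes (1st, 3rd, 5th) -> domain 1
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SyntheticTissue(
        cell_coords=coords, layer_labels=labels, lattice=lattice, seed=seed
    )


def composition_for(scenario: str, layer: int) -> np.ndarray:
    """Cell-type probability vector (over types 1..4) for one layer."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    props = SCENARIOS[scenario]
    orders = STRIPE_TYPE_ORDERS if scenario.startswith("stripe") else LAYER_TYPE_ORDERS
    order = orders[layer - 1]
    comp = np.zeros(4)
    for rank, cell_type in enumerate(order):
        comp[cell_type - 1] = props[rank]
    return comp


def assign_cell_types(
    tissue: SyntheticTissue, scenario: str = "S1", seed: int = 0
) -> SyntheticTissue:
    """Draw each cell's type from its layer's multinomial composition."""
    rng = np.random.default_rng(seed)
    types = np.empty(tissue.n_cells, dtype=int)
    for layer in np.unique(tissue.layer_labels):
        mask = tissue.layer_labels == layer
        comp = composition_for(scenario, int(layer))
        types[mask] = rng.choice(4, size=mask.sum(), p=comp) + 1
    return replace(tissue, cell_types=types)


def simulate_counts_splatlike(
    n_genes: int,
    n_cells: int,
    n_groups: int = 4,
    de_prob: float = 0.5,
    group_prob: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-Poisson counts with group-specific DE factors.

    Gene base means are gamma distributed; for every group a ``de_prob``
    fraction of genes receives a log-normal multiplicative factor (inverted
    with probability 1/2 for down-regulation); cells draw log-normal library
    sizes and Poisson counts from the group's normalized expression profile.
    Returns ``(counts, groups)`` with counts genes x cells and groups 1-based.
    """
    if abs(sum(group_prob) - 1.0) > 1e-8:
        raise ValueError("group_prob must sum to 1")
    rng = np.random.default_rng(seed)
    base_mean = rng.gamma(GENE_MEAN_SHAPE, 1.0 / GENE_MEAN_RATE, size=n_genes)
    factors = np.ones((n_genes, n_groups))
    for g in range(n_groups):
        is_de = rng.random(n_genes) < de_prob
        f = rng.lognormal(DE_FACTOR_LOC, DE_FACTOR_SCALE, size=n_genes)
        down = rng.random(n_genes) < 0.5
        f = np.where(down, 1.0 / f, f)
        factors[is_de, g] = f[is_de]
    profiles = base_mean[:, None] * factors
    profiles = profiles / profiles.sum(axis=0, keepdims=True)  # per-group proportions
    if groups is None:
        groups = rng.choice(n_groups, size=n_cells, p=np.asarray(group_prob)) + 1
    else:
        groups = np.asarray(groups, dtype=int)
        if groups.size != n_cells:
            raise ValueError("groups length must equal n_cells")
    libsize = rng.lognormal(LIBSIZE_LOC, LIBSIZE_SCALE, size=n_cells)
    lam = profiles[:, groups - 1] * libsize[None, :]
    counts = rng.poisson(lam).astype(np.int64)
    return counts, groups


def attach_counts(
    tissue: SyntheticTissue, n_genes: int = 5000, seed: int = 0, de_prob: float = 0.5
) -> SyntheticTissue:
    """Simulate counts for the tissue's cells using their assigned types."""
    if tissue.cell_types is None:
        raise ValueError("assign cell types before attaching counts")
    counts, _ = simulate_counts_splatlike(
        n_genes, tissue.n_cells, de_prob=de_prob, seed=seed, groups=tissue.cell_types
    )
    return replace(tissue, counts=counts)


def _majority(values: np.ndarray) -> int:
    labels, counts = np.unique(values, return_counts=True)
    return int(labels[np.argmax(counts)])


def aggregate_to_spots(tissue: SyntheticTissue, grid_edge: float) -> SyntheticTissue:
    """Bin cells into square subspots and merge 3x3 subspot blocks into spots.

    Counts are summed per subspot and per spot (total counts are conserved);
    truth labels are the majority cell label, and a spot's coordinate is the
    center of its central subspot. Spots without any cell are dropped along
    with their subspots.
    """
    if grid_edge <= 0:
        raise ValueError("grid_edge must be positive")
    width, height = tissue.lattice
    if grid_edge > min(width, height):
        raise ValueError("grid larger than the tissue")
    if tissue.counts is None:
        raise ValueError("attach counts before aggregation")
    ix = (tissue.cell_coords[:, 0] / grid_edge).astype(int)
    iy = (tissue.cell_coords[:, 1] / grid_edge).astype(int)
    nx = int(np.ceil(width / grid_edge))
    ny = int(np.ceil(height / grid_edge))
    n_sx, n_sy = int(np.ceil(nx / 3)), int(np.ceil(ny / 3))
    spot_of_cell = (ix // 3) + n_sx * (iy // 3)
    occupied_spots = np.unique(spot_of_cell)
    spot_index = {s: i for i, s in enumerate(occupied_spots)}
    n_spots = occupied_spots.size

    # enumerate the 9 subspots of every occupied spot
    subspot_coords, spot_map = [], []
    sub_key_to_idx: dict[tuple[int, int], int] = {}
    for i, s in enumerate(occupied_spots):
        sx, sy = int(s % n_sx), int(s // n_sx)
        for dy in range(3):
            for dx in range(3):
                gx, gy = 3 * sx + dx, 3 * sy + dy
                sub_key_to_idx[(gx, gy)] = len(subspot_coords)
                subspot_coords.append(((gx + 0.5) * grid_edge, (gy + 0.5) * grid_edge))
                spot_map.append(i)
    subspot_coords = np.asarray(subspot_coords)
    spot_map = np.asarray(spot_map, dtype=int)
    n_sub = subspot_coords.shape[0]

    subspot_of_cell = np.array([sub_key_to_idx[(x, y)] for x, y in zip(ix, iy)])
    n_genes = tissue.counts.shape[0]
    subspot_counts = np.zeros((n_genes, n_sub), dtype=np.int64)
    np.add.at(subspot_counts.T, subspot_of_cell, tissue.counts.T)
    spot_counts = np.zeros((n_genes, n_spots), dtype=np.int64)
    np.add.at(spot_counts.T, spot_map, subspot_counts.T)

    subspot_labels = np.zeros(n_sub, dtype=int)
    for j in range(n_sub):
        members = subspot_of_cell == j
        if members.any():
            subspot_labels[j] = _majority(tissue.layer_labels[members])
    cell_spot = np.array([spot_index[s] for s in spot_of_cell])
    spot_labels = np.array(
        [_majority(tissue.layer_labels[cell_spot == i]) for i in range(n_spots)]
    )
    # spot coordinate = center of the central subspot of the 3x3 block
    spot_coords = np.array(
        [
            (
                (3 * (s % n_sx) + 1 + 0.5) * grid_edge,
                (3 * (s // n_sx) + 1 + 0.5) * grid_edge,
            )
            for s in occupied_spots
        ]
    )
    return replace(
        tissue,
        subspot_coords=subspot_coords,
        subspot_labels=subspot_labels,
        subspot_counts=subspot_counts,
        subspot_map=subspot_of_cell,
        spot_coords=spot_coords,
        spot_labels=spot_labels,
        spot_counts=spot_counts,
        spot_map=spot_map,
    )


def cell_split(
    tissue: SyntheticTissue, n_split: int = 2500, seed: int = 0
) -> SyntheticTissue:
    """Split cells and share their counts with their nearest neighbors.

    ``n_split`` randomly chosen cells are removed; each one's counts are
    divided among its four nearest surviving cells with uniform-Dirichlet
    weights, drawing per-gene multinomial splits so totals are conserved
    exactly while counts stay integral.
    """
    if tissue.counts is None:
        raise ValueError("attach counts before splitting cells")
    n = tissue.n_cells
    if not 0 < n_split < n:
        raise ValueError("n_split must be in (0, n_cells)")
    rng = np.random.default_rng(seed)
    split_idx = rng.choice(n, size=n_split, replace=False)
    survivors = np.setdiff1d(np.arange(n), split_idx)
    tree = cKDTree(tissue.cell_coords[survivors])
    _, nn = tree.query(tissue.cell_coords[split_idx], k=4)
    counts = tissue.counts.copy()
    for cell, neighbors in zip(split_idx, nn):
        weights = rng.dirichlet(np.ones(4))
        shares = rng.multinomial(counts[:, cell], weights)  # genes x 4
        for part, surv in zip(shares.T, survivors[neighbors]):
            counts[:, surv] += part
    return replace(
        tissue,
        cell_coords=tissue.cell_coords[survivors],
        layer_labels=tissue.layer_labels[survivors],
        cell_types=None if tissue.cell_types is None else tissue.cell_types[survivors],
        counts=counts[:, survivors],
    )
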