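"""Build a synthetic layered tissue from scratch.

Shows each stage of the generator: band geometry, per-layer multinomial
cell-type draws (scenario S1: one 70% dominant type whose identity rotates
across layers), gamma-Poisson counts with 50% differentially expressed
genes, aggregation to subspots/spots, and the cell-split variant that
shares counts among neighboring cells while conserving the total exactly.
"""

import numpy as np

from spatialpca.simulate import (
    aggregate_to_spots,
    assign_cell_types,
    attach_counts,
    cell_split,
    composition_for,
    make_layered_tissue,
)

tissue = make_layered_tissue(5000, lattice=(110, 98), layout="bands4", seed=7)
tissue = assign_cell_types(tissue, scenario="S1", seed=8)
print("layer sizes:", np.bincount(tissue.layer_labels)[1:].tolist())
for layer in (1, 2):
    comp = composition_for("S1", layer)
    emp = [float(np.mean(tissue.cell_types[tissue.layer_labels == layer] == t + 1))
           for t in range(4)]
    print(f"layer {layer}: target {comp.tolist()} empirical {np.round(emp, 3).tolist()}")

tissue = attach_counts(tissue, n_genes=500, seed=9)
total = tissue.counts.sum()
print(f"counts: {tissue.counts.shape[0]} genes x {tissue.counts.shape[1]} cells, "
      f"total {total}")

split = cell_split(tissue, n_split=1250, seed=10)
print(f"cell split: {tissue.n_cells} -> {split.n_cells} pseudo-cells, "
      f"total conserved: {split.counts.sum() == total}")

spots = aggregate_to_spots(tissue, grid_edge=3.0)
print(f"aggregated: {spots.subspot_coords.shape[0]} subspots -> "
      f"{spots.spot_coords.shape[0]} spots, total conserved: "
      f"{spots.spot_counts.sum() == total}")
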