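"""Train one 20x20 hexagonal SOM and render its component planes.

Trains on one preprocessed synthetic database, reports the quantization
error before and after training, shows the worked hex-geometry example
(units 2 and 22 are lattice neighbors despite labels 20 apart), and
writes one colored map per time sample plus a gene-location map.
"""

from pathlib import Path

import somcoex as sx
from somcoex import viz

spec = sx.SyntheticSpec(rng_seed=7)
datasets, catalog, _ = sx.generate(spec)
clean, _, _ = sx.preprocess_dataset(datasets[0], catalog)

model = sx.train(clean, sx.TrainingConfig(rng_seed=7))
print(f"trained on {clean.n_genes} genes x {clean.n_samples} samples")
print(f"epochs: {len(model.qe_history) - 1}  "
      f"(rule: ceil(10 * 400 / {clean.n_genes}))")
print(f"quantization error: {model.qe_history[0]:.4f} -> {model.qe_history[-1]:.4f}")

grid = model.grid
print(f"unit_distance(2, 22) = {sx.unit_distance(grid, 2, 22)}  "
      "(adjacent rows, half a column apart)")

table = sx.assign_bmus(model, clean)
occupied = len({u for u in table.assignments.values()})
print(f"occupied units: {occupied} / {grid.n_units} "
      f"({grid.n_units - occupied} empty)")

out = Path("scratch_example_out")
viz.render_component_planes(model, clean.sample_times, clean.phase_labels, out)
viz.render_gene_map(table, grid, out_path=out / "gene_map.png")
print(f"wrote {clean.n_samples} component planes and a gene map to {out}/")

# The quantization error (mean gene-to-BMU distance) drops as the map
# adapts; blue->red planes show each unit's expression fraction at one
# sampling time, so a cluster's peak phase is visible as the sample where
# its map region turns red.
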