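"""Cross-database gene-pair consistency and quartile-fence outliers.

Trains one map per database (the fifth database is perturbed so its
gene profiles are independent of the others), computes every gene
pair's unit distance in each database, and flags pairs whose distance
in one database falls outside the Tukey fences built from the pair's
other distances.  A perturbed database should collect by far the most
outlier pairs - the method's signal that an experiment disagrees with
its peers.
"""

import somcoex as sx
from somcoex import consistency as cons

spec = sx.SyntheticSpec(rng_seed=7, perturbed_database=4)
datasets, catalog, truth = sx.generate(spec)

grid = sx.HexGrid()
tables = []
for i, ds in enumerate(datasets):
    clean, _, _ = sx.preprocess_dataset(ds, catalog)
    model = sx.train(clean, sx.TrainingConfig(rng_seed=70 + i))
    tables.append(cons.assign_bmus(model, clean))

report = cons.outlier_report(tables, grid)
print(f"gene pairs analyzed: {report.total_pairs}")
print("outlier pairs per database (db5 was perturbed):")
for name, count in report.per_database_outlier_counts.items():
    print(f"  {name}: {count}")

# pair lists over the four unperturbed databases (the perturbed one would
# rightly break any "in every database" statement)
unperturbed = tables[:4]
close = cons.consistent_pairs(unperturbed, grid, radius_threshold=3.0)
far = cons.opposite_pairs(unperturbed, grid, far_threshold=grid.diameter() / 2)
print(f"consistently close pairs (<= 3 units everywhere): {len(close)}")
print(f"consistently far pairs (>= half the map everywhere): {len(far)}")
a, b = truth.anti_phase_pairs[0]
print(f"planted anti-phase pair {a}/{b} among far pairs: "
      f"{tuple(sorted((a, b))) in set(far)}")

# Consistently close pairs are candidate co-regulation relationships;
# consistently far pairs suggest opposite (negative) regulation; the
# per-database counts identify the experiment whose conditions distorted
# gene behavior.
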