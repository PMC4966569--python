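"""Border-aligned occupancy/GC profiles and the per-barrier depletion Z-test.

Simulates statistically positioned nucleosome dyads around the barriers,
aggregates the normalized dyad density and GC content against the barrier
borders, and classifies every barrier by the occupancy Z-test.
"""

import numpy as np

from niebtools import (SyntheticTruth, aggregate, classify_catalog,
                       generate_genomes, group_summary, simulate_dyads,
                       simulate_mappability, smooth)

truth = SyntheticTruth()
lengths = {"chr1": 2_000_000}
genome, catalog = generate_genomes(truth, lengths, seed=2)
rng = np.random.default_rng(3)
tags = simulate_dyads(truth, catalog, lengths, coverage=0.2, rng=rng)
mappability = simulate_mappability(truth, lengths, rng)

values = {c: np.where(mappability[c], tags[c].astype(float), np.nan)
          for c in lengths}
density = smooth(aggregate(values, catalog, 600, normalize=True), 10)
print("normalized dyad density: inside barrier "
      f"{np.nanmean(density.mean[(density.offsets >= -50) & (density.offsets < 0)]):.2f}, "
      f"first flanking peak {np.nanmax(density.mean[(density.offsets > 0) & (density.offsets <= 120)]):.2f} "
      f"at +{density.offsets[np.nanargmax(np.where((density.offsets > 0) & (density.offsets <= 120), density.mean, -np.inf))]} bp")

gc = aggregate({c: g.gc_indicator() for c, g in genome.items()}, catalog, 600)
print(f"GC content: {np.nanmean(gc.mean[(gc.offsets >= -60) & (gc.offsets <= -15)]):.3f} "
      f"inside vs {np.nanmean(gc.mean[(gc.offsets > 0) & (gc.offsets <= 300)]):.3f} "
      "in the 300-bp flanks")

summary = group_summary(classify_catalog(catalog, tags, mappability))
print("Z-test groups: "
      + ", ".join(f"{g}={summary[g]:.1%}" for g in ("G1", "G2", "G3"))
      + f", excluded={summary['excluded']:.1%}")
print("G1 barriers are significantly tag-depleted relative to their 300-bp "
      "flanks at the one-sided 5 % level (z > 1.645); the depletion and the "
      "~74-bp flanking dyad peak are the statistical-positioning signature.")
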