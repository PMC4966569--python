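"""Background-corrected selection ratio S with its bootstrap neutral null.

Injects a 1.5x interspecies excess of strong-to-weak (C/G -> A/T)
substitutions inside barriers, tabulates position-resolved divergence and
polymorphism rates, and tests the windowed S profile against the
95 % bootstrap confidence band built from the centers of large (>800 bp)
inter-barrier regions.
"""

import numpy as np

from niebtools import (SelectionEffect, SyntheticTruth, background_rates,
                       bootstrap_null, build_window_counts,
                       detect_isolated_substitutions, generate_genomes,
                       internieb_regions, simulate_divergence, tabulate_rates,
                       windowed_pair_selection)
from niebtools.divergence import CLASS_NAMES, attach_intraspecies_events

truth = SyntheticTruth(selection=(SelectionEffect("SW", "inside", 1.5, "inter"),))
lengths = {f"chr{i}": 4_000_000 for i in range(1, 6)}   # 20 Mb for CI power
genome, catalog = generate_genomes(truth, lengths, seed=4)
sim = simulate_divergence(truth, genome, catalog, np.random.default_rng(5))

sites = {}
for chrom, cols in sim.columns.items():
    st = detect_isolated_substitutions(cols)
    attach_intraspecies_events(st, sim.variants[sim.variants["chrom"] == chrom])
    sites[chrom] = st

regions = internieb_regions(catalog)
bg = background_rates(sites, regions)
rates = tabulate_rates(sites, catalog, max_offset=1000)
windows = windowed_pair_selection(rates, bg, window=10)
null = bootstrap_null(build_window_counts(sites, regions), bg, reps=2000,
                      rng=np.random.default_rng(6))

sw = windows[windows["pair"] == "SW"]
inside = sw[(sw["offset"] < 0) & (sw["offset"] >= -30)]["S"].mean()
distal = sw[sw["offset"] > 600]["S"].mean()
hi = null.ci_high[CLASS_NAMES.index("SW")]
print(f"S(S->W) inside barriers: {inside:.2f}  (bootstrap 97.5% limit {hi:.2f})")
print(f"S(S->W) beyond 600 bp:  {distal:.2f}")
print("S > 1 above the limit marks an excess of fixed interspecies change "
      "over polymorphism (positive selection) localized to the barriers; "
      "distal windows stay inside the neutral band.")
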