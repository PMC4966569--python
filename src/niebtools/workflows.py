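"""End-to-end study workflows on synthetic data.

Each function regenerates its inputs from a seed, runs the corresponding
analysis stage(s), and returns the measured quantities. These are the entry
points the calibration/recovery checks and the reproduction script use.
"""

from __future__ import annotations

import numpy as np

from . import divergence as dv
from .catalog import fit_exponential_tail, internieb_regions
from .simulate import (SelectionEffect, SyntheticTruth, generate_genomes,
                       simulate_divergence)
from .ztest import ZTestInput, ztest_classify


def ztest_calibration(seed: int, n_barriers: int = 100_000, n1: int = 153,
                      n2: int = 600, null: str = "normal",
                      lam: float = 2.0) -> dict:
    """Empirical G1/G2 probabilities of the occupancy Z-test under an iid null.

    Per-site signals are drawn iid both inside the barrier (n1 sites, the
    mean barrier width) and in the pooled 300-bp flanks (n2 sites), so any
    classification away from G3 is a false positive; the analytic design
    probability per side is P(z > 1.645) = 5 %. ``null='normal'`` samples
    iid standard-normal site values (the test's asymptotic regime, where the
    5 % size holds to Monte Carlo accuracy); ``null='poisson'`` samples iid
    Poisson(lam) tag counts, where the plug-in standard deviations and the
    Poisson mean-variance coupling make the realized size slightly
    asymmetric (about 0.053 / 0.048 per side at these window sizes).
    """
    rng = np.random.default_rng(seed)
    groups = {"G1": 0, "G2": 0, "G3": 0, "excluded": 0}
    chunk = 20_000
    done = 0
    while done < n_barriers:
        k = min(chunk, n_barriers - done)
        if null == "poisson":
            inside = rng.poisson(lam, size=(k, n1)).astype(np.float64)
            flanks = rng.poisson(lam, size=(k, n2)).astype(np.float64)
        elif null == "normal":
            inside = rng.normal(size=(k, n1))
            flanks = rng.normal(size=(k, n2))
        else:
            raise ValueError(f"unknown null {null!r}")
        m1, s1 = inside.mean(axis=1), inside.std(axis=1)
        m2, s2 = flanks.mean(axis=1), flanks.std(axis=1)
        for i in range(k):
            res = ztest_classify(ZTestInput(m1[i], s1[i], n1, m2[i], s2[i], n2))
            groups[res.group] += 1
        done += k
    n = sum(groups[g] for g in ("G1", "G2", "G3"))
    return {"p_g1": groups["G1"] / n, "p_g2": groups["G2"] / n,
            "n": n, "analytic": 0.05}


def _build_sites(sim, maf_min: float = 0.01) -> dict[str, dv.SiteTable]:
    sites = {}
    for chrom, cols in sim.columns.items():
        st = dv.detect_isolated_substitutions(cols)
        sub = sim.variants[sim.variants["chrom"] == chrom]
        dv.attach_intraspecies_events(st, sub, maf_min=maf_min)
        sites[chrom] = st
    return sites


def _divergence_setup(truth: SyntheticTruth, lengths: dict[str, int], seed: int):
    """Generate genome + divergence data and assemble site tables/regions."""
    genome, catalog = generate_genomes(truth, lengths, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    sim = simulate_divergence(truth, genome, catalog, rng)
    sites = _build_sites(sim)
    regions = internieb_regions(catalog)
    return genome, catalog, sites, regions


def neutral_bootstrap_coverage(seed: int, n_chroms: int = 5,
                               chrom_mb: float = 1.0, reps: int = 10_000,
                               n_eval: int = 2_000) -> dict:
    """Per-side exceedance of the 95 % bootstrap limits for S under neutrality.

    A neutral synthetic run (default 5 Mb at barrier rate 1/1541) provides
    the large (>800 bp) inter-barrier regions; the bootstrap null uses
    ``reps`` repetitions of one random 10-bp window per region. ``n_eval``
    fresh draws per change pair from the same law (independent RNG stream)
    estimate the fraction of independent neutral windows whose S exceeds the
    97.5th-percentile limit; by design that fraction is 0.025 per side.
    """
    truth = SyntheticTruth()
    lengths = {f"chr{i + 1}": int(chrom_mb * 1e6) for i in range(n_chroms)}
    genome, catalog, sites, regions = _divergence_setup(truth, lengths, seed)
    bg = dv.background_rates(sites, regions)
    wc = dv.build_window_counts(sites, regions)
    rng_boot = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    null = dv.bootstrap_null(wc, bg, reps=reps, rng=rng_boot)
    rng_eval = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    draws = dv._draw_pair_s(wc, bg, n_eval, rng_eval)
    above = 0
    below = 0
    n_def = 0
    for p in range(6):
        col = draws[:, p]
        col = col[~np.isnan(col)]
        above += int((col > null.ci_high[p]).sum())
        below += int((col < null.ci_low[p]).sum())
        n_def += len(col)
    return {"exceedance_upper": above / n_def, "exceedance_lower": below / n_def,
            "n": n_def, "n_large_regions": wc.n_regions,
            "design_probability": (1 - null.ci) / 2}


def spacing_recovery(seed: int, n_chroms: int = 5, chrom_mb: float = 1.0) -> dict:
    """Recover the exponential spacing mean of a Poisson-placed catalog."""
    truth = SyntheticTruth()
    lengths = {f"chr{i + 1}": int(chrom_mb * 1e6) for i in range(n_chroms)}
    genome, catalog = generate_genomes(truth, lengths, seed)
    ds = internieb_regions(catalog)["d"].to_numpy()
    fit = fit_exponential_tail(ds, d_min=0)
    return {"fitted_mean": fit.mean, "true_mean": 1.0 / truth.barrier_rate,
            "n": fit.n, "se": fit.mean / np.sqrt(fit.n)}


def selection_recovery(seed: int, n_chroms: int = 8, chrom_mb: float = 5.0,
                       factor: float = 1.5, reps: int = 10_000,
                       max_offset: int = 1000) -> dict:
    """Detect an injected barrier-localized S->W interspecies excess.

    The generator multiplies interspecies S->W intensities by ``factor``
    inside barriers only. The pipeline must report windowed S above the
    bootstrap upper limit at barrier offsets for the S->W pairs, and S
    within the limits at distal offsets (>600 bp from any border). The run
    size (default 40 Mb) gives each 10-bp window enough events for the
    paper-sized effect to be resolvable against the neutral band.
    """
    truth = SyntheticTruth(
        selection=(SelectionEffect("SW", "inside", factor, "inter"),))
    lengths = {f"chr{i + 1}": int(chrom_mb * 1e6) for i in range(n_chroms)}
    genome, catalog, sites, regions = _divergence_setup(truth, lengths, seed)
    rates = dv.tabulate_rates(sites, catalog, max_offset=max_offset)
    bg = dv.background_rates(sites, regions)
    wc = dv.build_window_counts(sites, regions)
    rng_boot = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    null = dv.bootstrap_null(wc, bg, reps=reps, rng=rng_boot)
    windows = dv.windowed_pair_selection(rates, bg, window=10)

    # evaluate on the pooled S->W class (largest counts) and its member pairs
    sw_pairs = ["SW", "GA/CT", "CA/GT"]
    out = {"ci_high": {}, "mean_s_inside": {}, "mean_s_distal": {},
           "inside_above_ci": {}, "distal_above_ci_frac": {}}
    for pair in sw_pairs:
        p_idx = dv.CLASS_NAMES.index(pair)
        sub = windows[windows["pair"] == pair]
        inside = sub[(sub["offset"] < 0) & (sub["offset"] >= -30)]["S"].dropna()
        distal = sub[sub["offset"] > 600]["S"].dropna()
        hi = float(null.ci_high[p_idx])
        out["ci_high"][pair] = hi
        out["mean_s_inside"][pair] = float(inside.mean())
        out["mean_s_distal"][pair] = float(distal.mean())
        out["inside_above_ci"][pair] = bool(inside.mean() > hi)
        out["distal_above_ci_frac"][pair] = float((distal > hi).mean())
    out["true_factor"] = factor
    return out
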