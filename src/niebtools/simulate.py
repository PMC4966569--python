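"""Synthetic genomes with nucleosome-excluding barriers, dyad maps, and
divergence data with known ground truth.

The generator emulates the statistical structure of the real inputs: AT-rich
barriers placed by a Poisson process with poly(dA:dT) edges, oscillating GC
flanks, statistically positioned nucleosomes (an equilibrium 1D hard-rod /
Tonks gas between barriers, which reproduces boundary-confined ordering with
the target repeat length), neutral or position-dependently selected
substitution and SNP processes with CpG hypermutability, and patchy
mappability. Every output is reproducible bit-exact from (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import NiebCatalog
from .core import GenomeSequence, IntervalSet, MappabilityTrack, TagTrack
from .profiles import border_offsets

#: change-class shorthand: weak = A/T, strong = C/G
CHANGE_CLASSES = {
    "SW": frozenset({(1, 0), (1, 3), (2, 0), (2, 3)}),
    "WS": frozenset({(0, 1), (0, 2), (3, 1), (3, 2)}),
    "WW": frozenset({(0, 3), (3, 0)}),
    "SS": frozenset({(1, 2), (2, 1)}),
}
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


@dataclass(frozen=True)
class SelectionEffect:
    """A position-dependent multiplier on substitution intensities.

    ``change_class`` is one of SW / WS / WW / SS, ``region`` either 'inside'
    (all barrier-interior offsets) or 'flank' (the first 300 bp outside),
    ``lineage`` 'inter' (fixed substitutions) or 'intra' (polymorphisms).
    """

    change_class: str
    region: str
    factor: float
    lineage: str = "inter"


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a synthetic run.

    Defaults are the study conditions the analyses assume: exponential
    barrier spacing with mean 1541 bp, barrier widths in [36, 450] with mean
    about 153 bp, barrier GC 26.5 % against 42.5 % flanks over a 37.9 %
    background, a 147-bp nucleosome footprint packing at a 153-bp repeat
    length, human-scale neutral substitution intensities (about 0.5 % per
    site on the human lineage, transition-biased, CpG-hypermutable) and SNP
    density, and a few percent of unmappable sequence.
    """

    # barrier placement and composition
    barrier_rate: float = 1.0 / 1541.0     # per bp; mean interdistance 1541 bp
    width_min: int = 36
    width_max: int = 450
    width_mean: float = 153.0
    width_shape: float = 3.0               # gamma shape of the width law
    barrier_gc: float = 0.265
    flank_gc: float = 0.425
    background_gc: float = 0.379
    flank_span: int = 300                  # bp over which flank GC holds
    flank_taper: int = 300                 # bp of linear return to background
    gc_osc_amp: float = 0.05               # flank GC oscillation amplitude
    poly_edge_min: int = 5                 # poly(dA:dT) run lengths at edges
    poly_edge_max: int = 10
    # nucleosome positioning
    footprint: int = 147                   # bp of DNA per nucleosome
    nrl: float = 153.0                     # target repeat length (footprint + gap)
    interior_leakage: float = 0.15         # relative tag rate inside barriers
    # divergence processes
    transition_rate: float = 0.0032        # interspecies, per site per change
    transversion_rate: float = 0.0008
    cpg_multiplier: float = 10.0
    outgroup_noise: float = 0.002          # per outgroup branch, per site
    snp_transition_rate: float = 0.0024    # polymorphism intensities
    snp_transversion_rate: float = 0.0006
    af_alpha: float = 0.4                  # Beta law of derived-allele frequency
    af_beta: float = 4.0                   # (substantial mass below the 1 % MAF cut)
    selection: tuple[SelectionEffect, ...] = ()
    # mappability
    map_gap_fraction: float = 0.03
    map_gap_mean: float = 150.0

    def __post_init__(self) -> None:
        if self.barrier_rate < 0:
            raise ValueError("barrier rate must be >= 0")
        if self.barrier_rate * self.width_mean >= 1.0:
            raise ValueError("barriers would tile the genome (rate * width >= 1)")

    def rate_matrix(self, snp: bool = False) -> np.ndarray:
        ts = self.snp_transition_rate if snp else self.transition_rate
        tv = self.snp_transversion_rate if snp else self.transversion_rate
        m = np.full((4, 4), tv)
        np.fill_diagonal(m, 0.0)
        for x, y in _TRANSITIONS:
            m[x, y] = ts
        return m


# ---------------------------------------------------------------------------
# Genome and barrier catalog


def _sample_widths(truth: SyntheticTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    scale = truth.width_mean / truth.width_shape
    widths = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.gamma(truth.width_shape, scale, size=2 * (n - filled) + 8)
        draw = draw[(draw >= truth.width_min) & (draw <= truth.width_max)]
        take = min(len(draw), n - filled)
        widths[filled:filled + take] = draw[:take].astype(np.int64)
        filled += take
    return widths


def place_barriers(truth: SyntheticTruth, length: int, chrom: str,
                   rng: np.random.Generator) -> NiebCatalog:
    """Barriers with exponential border-to-border gaps (rate ``barrier_rate``)
    and truncated-gamma widths; placement is sequential, so overlaps never
    occur and interdistances are exactly exponential."""
    starts, ends = [], []
    if truth.barrier_rate > 0:
        mean_gap = 1.0 / truth.barrier_rate
        pos = rng.exponential(mean_gap)
        while True:
            w = int(_sample_widths(truth, 1, rng)[0])
            if pos + w >= length:
                break
            starts.append(int(pos))
            ends.append(int(pos) + w)
            pos = ends[-1] + rng.exponential(mean_gap)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    if len(df) == 0:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return NiebCatalog(IntervalSet(df), truth.width_min, truth.width_max)


def _gc_target(truth: SyntheticTruth, catalog: NiebCatalog, chrom: str,
               length: int) -> np.ndarray:
    gc = np.full(length, truth.background_gc)
    starts, ends = catalog.intervals.per_chrom(chrom)
    reach = truth.flank_span + truth.flank_taper
    off, _ = border_offsets(starts, ends, length, reach)
    inside = off < 0
    gc[inside] = truth.barrier_gc
    flank = off > 0
    o = off[flank].astype(float)
    level = np.where(
        o <= truth.flank_span, truth.flank_gc,
        truth.flank_gc + (truth.background_gc - truth.flank_gc)
        * (o - truth.flank_span) / truth.flank_taper)
    osc = truth.gc_osc_amp * np.cos(2 * np.pi * (o - truth.nrl / 2) / truth.nrl)
    osc *= np.exp(-o / (3 * truth.nrl))    # positioning decays away from the border
    gc[flank] = np.clip(level + osc, 0.05, 0.95)
    return gc


def generate_genome(truth: SyntheticTruth, length: int, chrom: str = "chr1",
                    rng: np.random.Generator | None = None,
                    ) -> tuple[GenomeSequence, NiebCatalog]:
    """One synthetic chromosome plus its truth-aligned barrier catalog.

    Bases are drawn iid from the position-dependent GC target (low inside
    barriers, elevated and oscillating over the flanks); poly(A) / poly(T)
    runs are planted at the 5' / 3' barrier edges.
    """
    if rng is None:
        rng = np.random.default_rng()
    catalog = place_barriers(truth, length, chrom, rng)
    gc = _gc_target(truth, catalog, chrom, length)
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    codes = np.where(is_gc, np.where(pick == 0, 1, 2),   # C or G
                     np.where(pick == 0, 0, 3)).astype(np.uint8)  # A or T
    starts, ends = catalog.intervals.per_chrom(chrom)
    if len(starts):
        runs = rng.integers(truth.poly_edge_min, truth.poly_edge_max + 1,
                            size=2 * len(starts))
        for i, (s, e) in enumerate(zip(starts, ends)):
            k5 = min(int(runs[2 * i]), e - s)
            k3 = min(int(runs[2 * i + 1]), e - s)
            codes[s:s + k5] = 0              # poly(A) at the 5' edge
            codes[e - k3:e] = 3              # poly(T) at the 3' edge
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    seq = lut[codes].tobytes().decode("ascii")
    return GenomeSequence(chrom, seq), catalog


def generate_genomes(truth: SyntheticTruth, lengths: dict[str, int],
                     seed: int) -> tuple[dict[str, GenomeSequence], NiebCatalog]:
    """Multi-chromosome convenience wrapper; bit-exact for a fixed seed."""
    rng = np.random.default_rng(seed)
    genome = {}
    frames = []
    for chrom, length in lengths.items():
        rec, cat = generate_genome(truth, length, chrom, rng)
        genome[chrom] = rec
        frames.append(cat.intervals.df)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end"])
    return genome, NiebCatalog(IntervalSet(df), truth.width_min, truth.width_max)


# ---------------------------------------------------------------------------
# Statistically positioned dyads (equilibrium 1D hard rods)


def _tonks_log_weights(L: float, a: float, beta_p: float) -> np.ndarray:
    """Log grand-canonical weights of N hard rods of length a in a box of
    length L at fugacity z = beta_p * exp(beta_p * a)."""
    n_max = int(L // a)
    n = np.arange(n_max + 1)
    free = L - n * a
    log_z = np.log(beta_p) + beta_p * a
    from scipy.special import gammaln
    with np.errstate(divide="ignore"):
        lw = n * log_z + n * np.log(np.maximum(free, 1e-300)) - gammaln(n + 1)
    lw[free < 0] = -np.inf
    return lw


def _sample_tonks_dyads(L: int, a: int, beta_p: float, n_configs: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Dyad positions (rod centers) of ``n_configs`` independent equilibrium
    configurations of hard rods in [0, L); exact sampling via the
    grand-canonical N distribution and uniform gap placement."""
    if L < a:
        return np.empty(0, dtype=np.int64)
    lw = _tonks_log_weights(float(L), float(a), beta_p)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    ns = rng.choice(len(w), size=n_configs, p=w)
    out = []
    for n in ns:
        if n == 0:
            continue
        free = L - n * a
        u = np.sort(rng.random(n)) * free
        centers = u + a * np.arange(n) + a / 2.0
        out.append(centers.astype(np.int64))
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)


def simulate_dyads(truth: SyntheticTruth, catalog: NiebCatalog,
                   lengths: dict[str, int], coverage: float = 0.2,
                   rng: np.random.Generator | None = None,
                   respect_barriers: bool = True) -> TagTrack:
    """MNase-like dyad tags from statistically positioned nucleosomes.

    Nucleosome footprints (147 bp) fill every inter-barrier region as an
    equilibrium hard-rod gas whose pressure is set by the target repeat
    length (mean gap = nrl - footprint), giving the damped positioning
    oscillation away from each barrier with the first dyad peak near
    border + footprint/2. Dyads from independent configurations are thinned
    to ``coverage`` expected tags per bp; a uniform leakage process at
    ``interior_leakage`` times the flank rate adds tags inside barriers.
    With ``respect_barriers=False`` the rods ignore barriers entirely (a
    flat-density null).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng()
    a = truth.footprint
    beta_p = 1.0 / (truth.nrl - truth.footprint)
    n_configs = max(1, int(np.ceil(coverage * truth.nrl)))
    thin = coverage * truth.nrl / n_configs
    track = TagTrack.zeros(lengths)
    for chrom, length in lengths.items():
        if respect_barriers:
            starts, ends = catalog.intervals.per_chrom(chrom)
            reg_lo = np.concatenate([[0], ends])
            reg_hi = np.concatenate([starts, [length]])
        else:
            reg_lo, reg_hi = np.array([0]), np.array([length])
        positions = []
        for lo, hi in zip(reg_lo, reg_hi):
            if hi - lo < a:
                continue
            dyads = _sample_tonks_dyads(int(hi - lo), a, beta_p, n_configs, rng)
            if len(dyads):
                keep = rng.random(len(dyads)) < thin
                positions.append(dyads[keep] + lo)
        if respect_barriers and truth.interior_leakage > 0:
            starts, ends = catalog.intervals.per_chrom(chrom)
            rate = truth.interior_leakage * coverage
            for s, e in zip(starts, ends):
                k = rng.poisson(rate * (e - s))
                if k:
                    positions.append(rng.integers(s, e, size=k))
        if positions:
            track.add_positions(chrom, np.concatenate(positions))
    return track


# ---------------------------------------------------------------------------
# Divergence simulation


@dataclass
class SimulatedDivergence:
    """Alignment columns, SNP table and realized-event bookkeeping."""

    columns: dict[str, dict[str, np.ndarray]]
    variants: pd.DataFrame
    n_inter_events: int
    n_snps: int


def _selection_multiplier(truth: SyntheticTruth, offsets: np.ndarray,
                          lineage: str, flank_span: int = 300) -> list:
    """Active selection effects as (site_mask, change_set, factor) triples."""
    triples = []
    for eff in truth.selection:
        if eff.lineage != lineage:
            continue
        if eff.region == "inside":
            mask = offsets < 0
        elif eff.region == "flank":
            mask = (offsets > 0) & (offsets <= flank_span)
        else:
            raise ValueError(f"unknown selection region {eff.region!r}")
        triples.append((mask, CHANGE_CLASSES[eff.change_class], eff.factor))
    return triples


def _mutate(anc: np.ndarray, base_matrix: np.ndarray, cpg_c: np.ndarray,
            cpg_g: np.ndarray, cpg_mult: float, sel_triples: list,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw at most one change per site with per-site intensity
    base_matrix[anc, Y] scaled by CpG and selection multipliers.
    Returns (positions, new bases)."""
    pos_out, base_out = [], []
    for x in range(4):
        idx = np.flatnonzero(anc == x)
        if len(idx) == 0:
            continue
        r = np.tile(base_matrix[x].astype(np.float64), (len(idx), 1))
        if x == 1 and cpg_mult != 1.0:            # C of a CpG: boosted C->T
            r[cpg_c[idx], 3] *= cpg_mult
        if x == 2 and cpg_mult != 1.0:            # G of a CpG: boosted G->A
            r[cpg_g[idx], 0] *= cpg_mult
        for mask, changes, factor in sel_triples:
            ys = [y for (cx, y) in changes if cx == x]
            if ys:
                sub = mask[idx]
                for y in ys:
                    r[sub, y] *= factor
        total = r.sum(axis=1)
        u = rng.random(len(idx))
        hit = u < total
        if not hit.any():
            continue
        rh = r[hit]
        cum = np.cumsum(rh, axis=1)
        u2 = rng.random(hit.sum()) * total[hit]
        y = (u2[:, None] >= cum).sum(axis=1)
        pos_out.append(idx[hit])
        base_out.append(y.astype(np.uint8))
    if not pos_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    pos = np.concatenate(pos_out)
    order = np.argsort(pos)
    return pos[order], np.concatenate(base_out)[order]


def simulate_divergence(truth: SyntheticTruth, genome: dict[str, GenomeSequence],
                        catalog: NiebCatalog,
                        rng: np.random.Generator | None = None,
                        ) -> SimulatedDivergence:
    """Four-species alignment columns and a SNP table over a synthetic genome.

    The generated sequence is the ancestral genome; chimp, orangutan and
    macaque are independent noisy copies (``outgroup_noise`` per site, small
    enough that flank-identity filtering keeps most sites); the human copy
    mutates at neutral intensities scaled by CpG and selection multipliers.
    SNPs arise at sites the human lineage did not substitute; the ancestral
    allele keeps frequency 1 - f with the derived frequency f drawn from the
    configured Beta law (so a share of SNPs falls below the 1 % MAF cut).
    """
    if rng is None:
        rng = np.random.default_rng()
    columns: dict[str, dict[str, np.ndarray]] = {}
    var_rows = []
    n_inter = 0
    n_snps = 0
    inter_m = truth.rate_matrix(snp=False)
    snp_m = truth.rate_matrix(snp=True)
    bases = np.array(list("ACGTN"))
    for chrom, rec in genome.items():
        anc = rec.codes
        L = len(anc)
        cpg_c = np.zeros(L, dtype=bool)
        cpg_g = np.zeros(L, dtype=bool)
        cpg_c[:-1] = (anc[:-1] == 1) & (anc[1:] == 2)
        cpg_g[1:] = cpg_c[:-1]
        outg = {}
        for sp in ("c", "o", "m"):
            copy = anc.copy()
            hit = rng.random(L) < truth.outgroup_noise
            k = int(hit.sum())
            copy[hit] = (copy[hit] + rng.integers(1, 4, size=k)) % 4
            outg[sp] = copy
        starts, ends = catalog.intervals.per_chrom(chrom)
        off, _ = border_offsets(starts, ends, L, max(300, truth.width_max))
        human = anc.copy()
        pos, newb = _mutate(anc, inter_m, cpg_c, cpg_g, truth.cpg_multiplier,
                            _selection_multiplier(truth, off, "inter"), rng)
        human[pos] = newb
        n_inter += len(pos)
        columns[chrom] = {"h": human, "c": outg["c"], "o": outg["o"], "m": outg["m"]}
        # polymorphisms on unsubstituted sites
        anc_for_snp = anc.copy()
        anc_for_snp[pos] = 4    # exclude inter-substituted sites from the SNP draw
        spos, sder = _mutate(np.where(anc_for_snp < 4, anc_for_snp, 4).astype(np.uint8),
                             snp_m, cpg_c, cpg_g, truth.cpg_multiplier,
                             _selection_multiplier(truth, off, "intra"), rng)
        freqs = rng.beta(truth.af_alpha, truth.af_beta, size=len(spos))
        for p, y, f in zip(spos, sder, freqs):
            var_rows.append((chrom, int(p), bases[anc[p]], bases[y], float(f)))
        n_snps += len(spos)
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt", "af"])
    return SimulatedDivergence(columns, variants, n_inter, n_snps)


# ---------------------------------------------------------------------------
# Mappability


def simulate_mappability(truth: SyntheticTruth, lengths: dict[str, int],
                         rng: np.random.Generator | None = None) -> MappabilityTrack:
    """Patchy mappability from an alternating renewal process: exponential
    mappable runs and unmappable gaps with the configured gap fraction."""
    if rng is None:
        rng = np.random.default_rng()
    f = truth.map_gap_fraction
    tracks = {}
    for chrom, length in lengths.items():
        if f <= 0:
            tracks[chrom] = np.ones(length, dtype=bool)
            continue
        run_mean = truth.map_gap_mean * (1 - f) / f
        arr = np.ones(length, dtype=bool)
        pos = 0
        mappable = rng.random() > f
        while pos < length:
            span = rng.exponential(run_mean if mappable else truth.map_gap_mean)
            span = max(1, int(span))
            if not mappable:
                arr[pos:pos + span] = False
            pos += span
            mappable = not mappable
        tracks[chrom] = arr
    return MappabilityTrack(tracks)
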