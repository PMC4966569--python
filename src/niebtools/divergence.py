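"""Interspecies/intraspecies divergence rates and the selection ratio.

Substitutions are tabulated in the human lineage since the human-chimpanzee
split, using orangutan and macaque as outgroups: at a site the ancestral base
is the base shared by the three non-human species (configurable to chimp plus
at least one outgroup), and only isolated events are used - the two
neighbouring sites must be identical across all four species. CpG sites
(hypermutable via deamination) are flagged from the four-species dinucleotide
patterns and excluded from C/G-ancestral rate computations. Per-position
rates follow

    dInter(X->Y) = InterDiff(X->Y) / ancestralBase(X)
    dIntra(X->Y) = IntraDiff(X->Y) / ancestralBase(X)

and the background-corrected selection ratio is

    S(X->Y) = (dInter / backgroundInter) / (dIntra / backgroundIntra),

with backgrounds averaged over the central +-300 bp of inter-barrier regions
wider than 800 bp (no preferential nucleosome positioning there). S > 1
indicates an excess of fixed interspecies change (positive selection), S < 1
an excess of polymorphism (purifying selection). The neutral null for S is a
bootstrap: each replicate pools one random 10-bp window per large region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import NiebCatalog
from .core import BASE_CODES, COMPLEMENT, encode_sequence
from .profiles import SIDE_FIVE, border_offsets

logger = logging.getLogger(__name__)

#: the 12 base changes grouped into reverse-complement pairs, in the panel
#: order of the selection figures
CHANGE_PAIRS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((2, 0), (1, 3)),   # G->A / C->T
    ((0, 2), (3, 1)),   # A->G / T->C
    ((1, 0), (2, 3)),   # C->A / G->T
    ((3, 2), (0, 1)),   # T->G / A->C
    ((3, 0), (0, 3)),   # T->A / A->T
    ((1, 2), (2, 1)),   # C->G / G->C
)
PAIR_NAMES = ("GA/CT", "AG/TC", "CA/GT", "TG/AC", "TA/AT", "CG/GC")
#: ancestral-base class of each pair: True = strong (C/G) ancestral
PAIR_ANCESTRAL_S = (True, False, True, False, False, True)
#: lumped GC-changing classes: pooled pairs (sharing eligible sites) and
#: whether the ancestral base is strong
CLASS_POOLS = {"SW": ((0, 2), True), "WS": ((1, 3), False)}
#: all selection classes reported by the windowed/bootstrap machinery
CLASS_NAMES = PAIR_NAMES + ("SW", "WS")

_PAIR_OF_CHANGE = {}
for _i, (_a, _b) in enumerate(CHANGE_PAIRS):
    _PAIR_OF_CHANGE[_a] = _i
    _PAIR_OF_CHANGE[_b] = _i


def complement_change(x: int, y: int) -> tuple[int, int]:
    """Map a base change to its reverse-complement partner (G->A to C->T)."""
    return int(COMPLEMENT[x]), int(COMPLEMENT[y])


# ---------------------------------------------------------------------------
# Alignment columns and event detection


@dataclass
class SiteTable:
    """Per-chromosome site-level divergence data on a contiguous coordinate axis.

    ``anc`` holds the reconstructed ancestral base code (4 = undefined),
    ``human`` the human base, ``flank`` the chimp base (used for sequence
    context; at eligible sites the flanks are identical across species so any
    species serves). ``eligible`` marks sites usable as rate denominators
    (defined ancestral base, non-N human base, flank identity on both sides).
    Intraspecies events live in the parallel arrays ``intra_pos`` /
    ``intra_y`` (ancestral allele implied by ``anc``).
    """

    anc: np.ndarray
    human: np.ndarray
    flank: np.ndarray
    eligible: np.ndarray
    cpg: np.ndarray
    intra_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    intra_y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))

    def __len__(self) -> int:
        return len(self.anc)

    @property
    def events(self) -> np.ndarray:
        """Isolated interspecies substitution mask (human differs from ancestral)."""
        return self.eligible & (self.human != self.anc)


def columns_from_frame(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Encode an alignment-column frame (pos, h, c, o, m) into code arrays on
    a dense 0..max(pos) axis; absent positions become N."""
    length = int(df["pos"].max()) + 1
    out = {}
    for sp in "hcom":
        arr = np.full(length, 4, dtype=np.uint8)
        arr[df["pos"].to_numpy()] = encode_sequence("".join(df[sp]))
        out[sp] = arr
    return out


def detect_isolated_substitutions(columns: dict[str, np.ndarray],
                                  ancestral_rule: str = "unanimity") -> SiteTable:
    """Build the site table from four-species alignment columns.

    ``columns`` maps species keys h/c/o/m to uint8 code arrays (4 = N or gap).
    The ancestral base requires chimp == orangutan == macaque under the
    default 'unanimity' rule, or chimp agreeing with at least one outgroup
    under 'chimp_plus_one'. A site is eligible iff the ancestral base is
    defined, the human base is called, and both neighbouring columns are
    identical (and called) across all four species; events are eligible sites
    where human differs from ancestral. CpG flags are attached separately.
    """
    h, c, o, m = columns["h"], columns["c"], columns["o"], columns["m"]
    if ancestral_rule == "unanimity":
        anc_ok = (c == o) & (o == m) & (c < 4)
        anc = np.where(anc_ok, c, 4).astype(np.uint8)
    elif ancestral_rule == "chimp_plus_one":
        anc_ok = (c < 4) & ((c == o) | (c == m))
        anc = np.where(anc_ok, c, 4).astype(np.uint8)
    else:
        raise ValueError(f"unknown ancestral rule {ancestral_rule!r}")
    identical = (h == c) & (c == o) & (o == m) & (h < 4)
    flank_ok = np.zeros(len(h), dtype=bool)
    if len(h) >= 3:
        flank_ok[1:-1] = identical[:-2] & identical[2:]
    eligible = (anc < 4) & (h < 4) & flank_ok
    cpg = detect_cpg_sites(columns)
    return SiteTable(anc=anc, human=h, flank=c.copy(), eligible=eligible, cpg=cpg)


def detect_cpg_sites(columns: dict[str, np.ndarray],
                     strand_symmetric: bool = True) -> np.ndarray:
    """Flag CpG sites from the human/chimp/orangutan/macaque dinucleotides.

    Position i is the C of a CpG when the (i, i+1) pattern across the four
    species matches NG/CG/CG/CG, CG/NG/CG/CG, CN/CG/CG/CG or CG/CN/CG/CG
    (N = any base): three species carry an intact CpG and the fourth may have
    lost either half. With ``strand_symmetric`` (default) the G at i+1 of any
    matched pattern is flagged too, so reverse-complement-pooled G-ancestral
    rates get the same exclusion.
    """
    h, c, o, m = columns["h"], columns["c"], columns["o"], columns["m"]
    C, G = BASE_CODES["C"], BASE_CODES["G"]
    L = len(h)
    flag = np.zeros(L, dtype=bool)
    if L < 2:
        return flag
    hC, hG = h[:-1] == C, h[1:] == G
    cC, cG = c[:-1] == C, c[1:] == G
    oCG = (o[:-1] == C) & (o[1:] == G)
    mCG = (m[:-1] == C) & (m[1:] == G)
    p1 = hG & cC & cG & oCG & mCG            # NG/CG/CG/CG
    p2 = hC & hG & cG & oCG & mCG            # CG/NG/CG/CG
    p3 = hC & cC & cG & oCG & mCG            # CN/CG/CG/CG
    p4 = hC & hG & cC & oCG & mCG            # CG/CN/CG/CG
    is_c = p1 | p2 | p3 | p4
    flag[:-1] = is_c
    if strand_symmetric:
        flag[1:] |= is_c
    return flag


def attach_intraspecies_events(sites: SiteTable, variants: pd.DataFrame,
                               maf_min: float = 0.01) -> tuple[int, int]:
    """Attach SNP-derived intraspecies events to a site table (in place).

    For each variant the ancestral allele is the observed allele matching the
    reconstructed ancestral base (falling back to the chimp base where that is
    undefined); every other observed allele with frequency > ``maf_min``
    contributes one X->Y polymorphism. Sites with no allele matching the
    ancestral base, or that fail the eligibility criterion, are excluded.
    Returns (events attached, variants excluded).
    """
    if len(variants) == 0:
        sites.intra_pos = np.empty(0, dtype=np.int64)
        sites.intra_y = np.empty(0, dtype=np.uint8)
        return 0, 0
    pos = variants["pos"].to_numpy(dtype=np.int64)
    ref = encode_sequence("".join(variants["ref"]))
    alt = encode_sequence("".join(variants["alt"]))
    af = variants["af"].to_numpy(dtype=float)
    # total ALT frequency per position, for the REF allele's own frequency
    alt_total = pd.Series(af).groupby(pd.Series(pos)).transform("sum").to_numpy()
    ref_freq = 1.0 - alt_total

    anc = sites.anc[pos]
    fallback = sites.flank[pos]
    anc = np.where(anc < 4, anc, fallback)
    ok = (anc < 4) & sites.eligible[pos]
    ev_pos, ev_y = [], []
    n_excluded = 0
    anc_is_ref = ok & (anc == ref)
    anc_is_alt = ok & (anc == alt)
    use = anc_is_ref & (af > maf_min)
    ev_pos.append(pos[use])
    ev_y.append(alt[use])
    use = anc_is_alt & (ref_freq > maf_min)
    ev_pos.append(pos[use])
    ev_y.append(ref[use])
    n_excluded = int((ok & ~(anc_is_ref | anc_is_alt)).sum() + (~ok).sum())
    sites.intra_pos = np.concatenate(ev_pos)
    sites.intra_y = np.concatenate(ev_y).astype(np.uint8)
    if n_excluded:
        logger.info("intraspecies: excluded %d variant rows", n_excluded)
    return len(sites.intra_pos), n_excluded


# ---------------------------------------------------------------------------
# Rate tabulation around barriers


@dataclass
class RateProfile:
    """Per-offset, per-change counts around barrier borders.

    ``eligible[o, X]`` counts ancestral-X sites at offset index o;
    ``inter[o, X, Y]`` and ``intra[o, X, Y]`` count events. Offsets follow
    the border convention (negative inside); reverse-complement pooling is
    applied, so a 5'-side G->A event is stored as C->T. ``cpg_excluded``
    records whether flagged CpG sites were dropped (they are for selection
    analyses; equilibrium-GC rates keep them).
    """

    offsets: np.ndarray
    eligible: np.ndarray     # (O, 4)
    inter: np.ndarray        # (O, 4, 4)
    intra: np.ndarray        # (O, 4, 4)
    cpg_excluded: bool = True

    def d_inter(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.eligible[:, :, None] > 0,
                            self.inter / self.eligible[:, :, None], np.nan)

    def d_intra(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.eligible[:, :, None] > 0,
                            self.intra / self.eligible[:, :, None], np.nan)

    def pair_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Lump the 12 changes into the 6 reverse-complement pairs.
        Returns (eligible, inter, intra) with trailing axis of length 6."""
        O = len(self.offsets)
        elig = np.zeros((O, 6))
        inter = np.zeros((O, 6))
        intra = np.zeros((O, 6))
        for p, (a, b) in enumerate(CHANGE_PAIRS):
            elig[:, p] = self.eligible[:, a[0]] + self.eligible[:, b[0]]
            inter[:, p] = self.inter[:, a[0], a[1]] + self.inter[:, b[0], b[1]]
            intra[:, p] = self.intra[:, a[0], a[1]] + self.intra[:, b[0], b[1]]
        return elig, inter, intra


def _use_mask(sites: SiteTable, exclude_cpg: bool) -> np.ndarray:
    use = sites.eligible
    if exclude_cpg:
        use = use & ~sites.cpg
    return use


def tabulate_rates(sites_by_chrom: dict[str, SiteTable], catalog: NiebCatalog,
                   max_offset: int, exclude_cpg: bool = True) -> RateProfile:
    """Tabulate per-offset eligible-site and event counts around barriers.

    Sites governed by a 5' border are reverse-complement mapped before
    pooling (the right-of-3'-border profile averaged with the complement of
    the left-of-5'-border profile). CpG-flagged sites are excluded when
    ``exclude_cpg`` (this only touches C/G-ancestral counts).
    """
    n_bins = 2 * max_offset + 1
    eligible = np.zeros((n_bins, 4), dtype=np.int64)
    inter = np.zeros((n_bins, 4, 4), dtype=np.int64)
    intra = np.zeros((n_bins, 4, 4), dtype=np.int64)
    for chrom, sites in sites_by_chrom.items():
        starts, ends = catalog.intervals.per_chrom(chrom)
        off, side = border_offsets(starts, ends, len(sites), max_offset)
        use = _use_mask(sites, exclude_cpg) & (off != 0)
        idx = np.flatnonzero(use)
        o = off[idx] + max_offset
        anc = sites.anc[idx].astype(np.int64)
        flip = side[idx] == SIDE_FIVE
        anc = np.where(flip, COMPLEMENT[anc], anc)
        np.add.at(eligible, (o, anc), 1)

        ev = idx[sites.human[idx] != sites.anc[idx]]
        if len(ev):
            oe = off[ev] + max_offset
            x = sites.anc[ev].astype(np.int64)
            y = sites.human[ev].astype(np.int64)
            f = side[ev] == SIDE_FIVE
            x = np.where(f, COMPLEMENT[x], x)
            y = np.where(f, COMPLEMENT[y], y)
            np.add.at(inter, (oe, x, y), 1)

        ip, iy = sites.intra_pos, sites.intra_y
        if len(ip):
            keep = use[ip]
            p = ip[keep]
            o2 = off[p] + max_offset
            x = sites.anc[p].astype(np.int64)
            y = iy[keep].astype(np.int64)
            f = side[p] == SIDE_FIVE
            x = np.where(f, COMPLEMENT[x], x)
            y = np.where(f, COMPLEMENT[y], y)
            np.add.at(intra, (o2, x, y), 1)
    return RateProfile(np.arange(-max_offset, max_offset + 1), eligible, inter,
                       intra, cpg_excluded=exclude_cpg)


# ---------------------------------------------------------------------------
# Background rates and selection ratio


@dataclass
class BackgroundRates:
    """Pooled counts over the central +-300 bp of large (>800 bp)
    inter-barrier regions, the neutral-divergence proxy."""

    eligible: np.ndarray     # (4,)
    inter: np.ndarray        # (4, 4)
    intra: np.ndarray        # (4, 4)

    def rate_inter(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.eligible[:, None] > 0,
                            self.inter / self.eligible[:, None], np.nan)

    def rate_intra(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.eligible[:, None] > 0,
                            self.intra / self.eligible[:, None], np.nan)

    def pair_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Background (inter, intra) rates for the 6 change pairs."""
        bi = np.zeros(6)
        bt = np.zeros(6)
        for p, (a, b) in enumerate(CHANGE_PAIRS):
            e = self.eligible[a[0]] + self.eligible[b[0]]
            bi[p] = (self.inter[a] + self.inter[b]) / e if e else np.nan
            bt[p] = (self.intra[a] + self.intra[b]) / e if e else np.nan
        return bi, bt

    def class_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Background rates for all reported classes: the 6 pairs plus the
        pooled SW and WS classes (pooled pairs share their eligible sites, so
        the pooled rate is the sum of the member-pair rates)."""
        bi, bt = self.pair_rates()
        extra_i, extra_t = [], []
        for name in ("SW", "WS"):
            pools, _ = CLASS_POOLS[name]
            extra_i.append(np.nansum([bi[p] for p in pools]))
            extra_t.append(np.nansum([bt[p] for p in pools]))
        return np.concatenate([bi, extra_i]), np.concatenate([bt, extra_t])


def _central_spans(regions: pd.DataFrame, l_min: int,
                   center_halfwidth: int) -> pd.DataFrame:
    large = regions[regions["d"] > l_min]
    if len(large) == 0:
        raise ValueError(f"no inter-barrier regions wider than {l_min} bp")
    mid = (large["start"] + large["end"]) // 2
    lo = np.maximum(mid - center_halfwidth, large["start"])
    hi = np.minimum(mid + center_halfwidth, large["end"])
    return pd.DataFrame({"chrom": large["chrom"], "start": lo, "end": hi})


def background_rates(sites_by_chrom: dict[str, SiteTable], regions: pd.DataFrame,
                     l_min: int = 800, center_halfwidth: int = 300,
                     exclude_cpg: bool = True) -> BackgroundRates:
    """Neutral-proxy rates from the centers of large inter-barrier regions.

    Pools counts over positions within ``center_halfwidth`` of the midpoint
    of every region wider than ``l_min``, clipped to the region; errors when
    no region qualifies.
    """
    spans = _central_spans(regions, l_min, center_halfwidth)
    eligible = np.zeros(4, dtype=np.int64)
    inter = np.zeros((4, 4), dtype=np.int64)
    intra = np.zeros((4, 4), dtype=np.int64)
    for chrom, sub in spans.groupby("chrom", sort=False):
        sites = sites_by_chrom[chrom]
        mask = np.zeros(len(sites), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            mask[s:e] = True
        use = _use_mask(sites, exclude_cpg) & mask
        idx = np.flatnonzero(use)
        np.add.at(eligible, sites.anc[idx].astype(np.int64), 1)
        ev = idx[sites.human[idx] != sites.anc[idx]]
        np.add.at(inter, (sites.anc[ev].astype(np.int64),
                          sites.human[ev].astype(np.int64)), 1)
        ip, iy = sites.intra_pos, sites.intra_y
        if len(ip):
            keep = use[ip]
            np.add.at(intra, (sites.anc[ip[keep]].astype(np.int64),
                              iy[keep].astype(np.int64)), 1)
    return BackgroundRates(eligible, inter, intra)


def selection_ratio(rates: RateProfile, background: BackgroundRates) -> np.ndarray:
    """Per-offset, per-change selection ratio S (Eq. above), shape (O, 4, 4).

    Undefined values propagate as NaN: zero intraspecies rate or zero/
    undefined background gives NaN, never infinity.
    """
    d_inter = rates.d_inter()
    d_intra = rates.d_intra()
    bg_i = background.rate_inter()
    bg_t = background.rate_intra()
    with np.errstate(invalid="ignore", divide="ignore"):
        num = d_inter / bg_i[None]
        den = d_intra / bg_t[None]
        s = np.where((den > 0) & np.isfinite(den) & np.isfinite(num), num / den, np.nan)
    return s


def _extend_classes(e: np.ndarray, ei: np.ndarray, et: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append pooled SW/WS columns to per-pair count vectors/matrices.
    Pooled pairs share eligible sites, so eligibility is not doubled."""
    cols_e, cols_i, cols_t = [e], [ei], [et]
    for name in ("SW", "WS"):
        (p1, p2), _ = CLASS_POOLS[name]
        cols_e.append(e[..., p1:p1 + 1])
        cols_i.append(ei[..., p1:p1 + 1] + ei[..., p2:p2 + 1])
        cols_t.append(et[..., p1:p1 + 1] + et[..., p2:p2 + 1])
    return (np.concatenate(cols_e, axis=-1), np.concatenate(cols_i, axis=-1),
            np.concatenate(cols_t, axis=-1))


def windowed_pair_selection(rates: RateProfile, background: BackgroundRates,
                            window: int = 10) -> pd.DataFrame:
    """Selection ratio per change class in non-overlapping offset windows.

    Counts are pooled within each window (aligned outward from the border:
    offsets [1, w], [w+1, 2w], ... and [-w, -1], [-2w, -w-1], ...) before the
    ratio is formed. Classes are the 6 reverse-complement pairs plus the
    pooled SW and WS (GC-changing) classes. Returns a long frame with window
    center offset, class name, S, and the pooled counts.
    """
    elig, inter, intra = _extend_classes(*rates.pair_counts())
    bi, bt = background.class_rates()
    offs = rates.offsets
    win_id = np.where(offs > 0, (offs - 1) // window,
                      np.where(offs < 0, -1 - (-offs - 1) // window, 0))
    valid = offs != 0
    rows = []
    for w in np.unique(win_id[valid]):
        sel = valid & (win_id == w)
        center = float(offs[sel].mean())
        e = elig[sel].sum(axis=0)
        ei = inter[sel].sum(axis=0)
        et = intra[sel].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            di = np.where(e > 0, ei / e, np.nan)
            dt = np.where(e > 0, et / e, np.nan)
            s = np.where((dt > 0) & (bt > 0) & (bi > 0),
                         (di / bi) / (dt / bt), np.nan)
        for p, name in enumerate(CLASS_NAMES):
            rows.append((center, name, s[p], int(e[p]), int(ei[p]), int(et[p])))
    return pd.DataFrame(rows, columns=["offset", "pair", "S", "eligible",
                                       "inter", "intra"])


# ---------------------------------------------------------------------------
# Equilibrium GC


def equilibrium_gc(rate_matrix: np.ndarray) -> float | np.ndarray:
    """Stationary GC fraction of a 4x4 substitution rate matrix (or a stack).

    Off-diagonal entries are per-unit-time rates X->Y; the diagonal is set so
    rows sum to zero (a continuous-time generator). Returns pi(G) + pi(C) of
    the stationary vector, or NaN for reducible/degenerate matrices.
    """
    rm = np.asarray(rate_matrix, dtype=float)
    if rm.ndim == 3:
        return np.array([equilibrium_gc(m) for m in rm])
    if rm.shape != (4, 4):
        raise ValueError("rate matrix must be 4x4")
    if np.isnan(rm).any():
        return np.nan
    q = rm.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if np.linalg.matrix_rank(q) < 3:
        return np.nan    # reducible or degenerate: no unique stationary law
    a = np.vstack([q.T, np.ones(4)])
    b = np.concatenate([np.zeros(4), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if not np.all(pi > -1e-9) or not np.isclose(pi.sum(), 1.0):
        return np.nan
    resid = np.abs(q.T @ pi).max()
    if resid > 1e-10 * max(1.0, np.abs(q).max()):
        return np.nan    # reducible or inconsistent: no unique stationary law
    return float(pi[1] + pi[2])


def equilibrium_gc_profile(rates: RateProfile, window: int = 10) -> pd.DataFrame:
    """Per-offset-window equilibrium GC from CpG-inclusive interspecies rates.

    Counts are pooled in non-overlapping windows (as in
    :func:`windowed_pair_selection`) before the stationary vector is taken.
    """
    if rates.cpg_excluded:
        raise ValueError("equilibrium GC needs CpG-inclusive rates "
                         "(tabulate with exclude_cpg=False)")
    offs = rates.offsets
    win_id = np.where(offs > 0, (offs - 1) // window,
                      np.where(offs < 0, -1 - (-offs - 1) // window, 0))
    valid = offs != 0
    rows = []
    for w in np.unique(win_id[valid]):
        sel = valid & (win_id == w)
        e = rates.eligible[sel].sum(axis=0)
        ev = rates.inter[sel].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(e[:, None] > 0, ev / e[:, None], np.nan)
        rows.append((float(offs[sel].mean()), equilibrium_gc(m)))
    return pd.DataFrame(rows, columns=["offset", "gc_eq"])


# ---------------------------------------------------------------------------
# Bootstrap neutral null


@dataclass
class WindowCounts:
    """Per-(large-region, 10-bp-window) pair-level counts for the bootstrap.

    ``elig`` has a trailing axis of 2 ancestral classes (0 = weak A/T,
    1 = strong C/G); ``inter`` / ``intra`` have a trailing axis of 6 pairs.
    """

    inter: np.ndarray      # (R, W, 6)
    intra: np.ndarray      # (R, W, 6)
    elig: np.ndarray       # (R, W, 2)

    @property
    def n_regions(self) -> int:
        return self.inter.shape[0]

    @property
    def n_windows(self) -> int:
        return self.inter.shape[1]


def build_window_counts(sites_by_chrom: dict[str, SiteTable], regions: pd.DataFrame,
                        l_min: int = 800, center_halfwidth: int = 300,
                        window: int = 10, exclude_cpg: bool = True) -> WindowCounts:
    """Count events and eligible sites per 10-bp window of the central span of
    every large inter-barrier region (the raw material of the bootstrap)."""
    spans = _central_spans(regions, l_min, center_halfwidth)
    n_windows = (2 * center_halfwidth) // window
    R = len(spans)
    inter = np.zeros((R, n_windows, 6), dtype=np.int32)
    intra = np.zeros((R, n_windows, 6), dtype=np.int32)
    elig = np.zeros((R, n_windows, 2), dtype=np.int32)
    spans = spans.reset_index(drop=True)
    pair_of = np.full((4, 4), -1, dtype=np.int64)
    for p, (a, b) in enumerate(CHANGE_PAIRS):
        pair_of[a] = p
        pair_of[b] = p
    is_strong = np.array([0, 1, 1, 0], dtype=np.int64)

    for chrom, sub in spans.groupby("chrom", sort=False):
        sites = sites_by_chrom[chrom]
        L = len(sites)
        rid = np.full(L, -1, dtype=np.int64)
        wid = np.zeros(L, dtype=np.int64)
        for r, s, e in zip(sub.index, sub["start"], sub["end"]):
            rid[s:e] = r
            w = (np.arange(e - s)) // window
            wid[s:e] = np.minimum(w, n_windows - 1)
        use = _use_mask(sites, exclude_cpg) & (rid >= 0)
        idx = np.flatnonzero(use)
        np.add.at(elig, (rid[idx], wid[idx], is_strong[sites.anc[idx]]), 1)
        ev = idx[sites.human[idx] != sites.anc[idx]]
        p = pair_of[sites.anc[ev], sites.human[ev]]
        np.add.at(inter, (rid[ev], wid[ev], p), 1)
        ip, iy = sites.intra_pos, sites.intra_y
        if len(ip):
            keep = use[ip]
            pp = ip[keep]
            p2 = pair_of[sites.anc[pp], iy[keep]]
            np.add.at(intra, (rid[pp], wid[pp], p2), 1)
    return WindowCounts(inter, intra, elig)


def _draw_pair_s(wc: WindowCounts, background: BackgroundRates, n_draws: int,
                 rng: np.random.Generator, chunk: int = 500) -> np.ndarray:
    """Draw ``n_draws`` realizations of the class-level S under the neutral
    resampling law: one random window per region, counts pooled, ratio formed
    against the fixed backgrounds. Returns (n_draws, len(CLASS_NAMES));
    undefined S is NaN."""
    bi, bt = background.class_rates()
    R, W = wc.n_regions, wc.n_windows
    anc_cls = np.array(PAIR_ANCESTRAL_S, dtype=np.int64)
    out = np.empty((n_draws, len(CLASS_NAMES)))
    reg_idx = np.arange(R)
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        w = rng.integers(0, W, size=(k, R))
        sums = {}
        for name, arr, depth in (("inter", wc.inter, 6), ("intra", wc.intra, 6),
                                 ("elig", wc.elig, 2)):
            s = np.empty((k, depth))
            for d in range(depth):
                s[:, d] = arr[:, :, d][reg_idx[None, :], w].sum(axis=1)
            sums[name] = s
        e, ei, et = _extend_classes(sums["elig"][:, anc_cls], sums["inter"],
                                    sums["intra"])
        with np.errstate(invalid="ignore", divide="ignore"):
            di = np.where(e > 0, ei / e, np.nan)
            dt = np.where(e > 0, et / e, np.nan)
            s = np.where((dt > 0) & (bt[None] > 0) & (bi[None] > 0),
                         (di / bi[None]) / (dt / bt[None]), np.nan)
        out[done:done + k] = s
        done += k
    return out


@dataclass
class BootstrapNull:
    """Bootstrap S distribution under neutrality: per-pair samples and CI."""

    samples: np.ndarray      # (reps, 6)
    ci_low: np.ndarray       # (6,)
    ci_high: np.ndarray      # (6,)
    ci: float

    def p_value(self, s_obs: float, pair: int, side: str = "above") -> float:
        """Empirical tail probability of an observed S against the null
        histogram (no multiple-test correction: non-overlapping 10-bp windows
        are independent observations)."""
        col = self.samples[:, pair]
        col = col[~np.isnan(col)]
        if side == "above":
            return float((col >= s_obs).mean())
        return float((col <= s_obs).mean())


def bootstrap_null(wc: WindowCounts, background: BackgroundRates,
                   reps: int = 10000, ci: float = 0.95,
                   rng: np.random.Generator | None = None) -> BootstrapNull:
    """Build the neutral null for S by window resampling.

    Each replicate selects one random ``window``-bp window in the central
    span of every large inter-barrier region, pools the counts, and computes
    the pair-level S against the fixed backgrounds; the CI is the 2.5/97.5
    percentile band (for ci = 0.95) of the replicate distribution.
    """
    if reps < 100:
        import warnings
        warnings.warn(f"bootstrap with only {reps} repetitions", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng()
    samples = _draw_pair_s(wc, background, reps, rng)
    alpha = (1.0 - ci) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanpercentile(samples, 100 * alpha, axis=0)
        hi = np.nanpercentile(samples, 100 * (1 - alpha), axis=0)
    return BootstrapNull(samples, lo, hi, ci)


# ---------------------------------------------------------------------------
# Context-dependent rates


@dataclass
class ContextSpec:
    """A context-restricted change class on the ancestral sequence, e.g.
    tTt -> tAt (left = {T}, x = T, y = A, right = {T}) or sTs -> sAs with
    s in {C, G}. Sets may overlap between specs."""

    name: str
    left: frozenset[int]
    x: int
    y: int
    right: frozenset[int]

    @classmethod
    def parse(cls, text: str) -> "ContextSpec":
        """Parse 'tTt>tAt' style notation; lowercase = context, uppercase =
        changing base. 's' = {c,g}, 'w' = {a,t}, '!a' = all but a, etc."""
        lhs, rhs = text.split(">")
        def ctx(tok: str) -> frozenset[int]:
            if tok.startswith("!"):
                return frozenset(range(4)) - frozenset([BASE_CODES[tok[1].upper()]])
            if tok == "s":
                return frozenset([1, 2])
            if tok == "w":
                return frozenset([0, 3])
            return frozenset([BASE_CODES[tok.upper()]])
        toks = _tokenize_context(lhs)
        toks_r = _tokenize_context(rhs)
        return cls(text, ctx(toks[0]), BASE_CODES[toks[1].upper()],
                   BASE_CODES[toks_r[1].upper()], ctx(toks[2]))

    def revcomp(self) -> "ContextSpec":
        comp = lambda s: frozenset(int(COMPLEMENT[b]) for b in s)
        return ContextSpec(self.name + "(rc)", comp(self.right),
                           int(COMPLEMENT[self.x]), int(COMPLEMENT[self.y]),
                           comp(self.left))


def _tokenize_context(word: str) -> list[str]:
    toks = []
    i = 0
    while i < len(word):
        if word[i] == "!":
            toks.append(word[i:i + 2])
            i += 2
        else:
            toks.append(word[i])
            i += 1
    if len(toks) != 3:
        raise ValueError(f"context {word!r} must have left, base, right tokens")
    return toks


def _context_masks(sites: SiteTable, spec: ContextSpec) -> tuple[np.ndarray, np.ndarray]:
    """(eligible, event) masks for one context spec; context is matched on
    the ancestral sequence via the (identical) flanking columns."""
    L = len(sites)
    left_ok = np.zeros(L, dtype=bool)
    right_ok = np.zeros(L, dtype=bool)
    fl = sites.flank
    for b in spec.left:
        left_ok[1:] |= fl[:-1] == b
    for b in spec.right:
        right_ok[:-1] |= fl[1:] == b
    elig = sites.eligible & (sites.anc == spec.x) & left_ok & right_ok
    event = elig & (sites.human == spec.y)
    return elig, event


@dataclass
class ContextRateProfile:
    name: str
    offsets: np.ndarray
    eligible: np.ndarray
    inter: np.ndarray
    intra: np.ndarray
    bg_inter: float = np.nan
    bg_intra: float = np.nan

    def selection_windows(self, window: int = 30) -> pd.DataFrame:
        win_id = np.where(self.offsets > 0, (self.offsets - 1) // window,
                          np.where(self.offsets < 0,
                                   -1 - (-self.offsets - 1) // window, 0))
        valid = self.offsets != 0
        rows = []
        for w in np.unique(win_id[valid]):
            sel = valid & (win_id == w)
            e = self.eligible[sel].sum()
            ei = self.inter[sel].sum()
            et = self.intra[sel].sum()
            s = np.nan
            if e > 0 and et > 0 and self.bg_inter > 0 and self.bg_intra > 0:
                s = ((ei / e) / self.bg_inter) / ((et / e) / self.bg_intra)
            rows.append((float(self.offsets[sel].mean()), s, int(e), int(ei), int(et)))
        return pd.DataFrame(rows, columns=["offset", "S", "eligible", "inter", "intra"])


def context_rates(sites_by_chrom: dict[str, SiteTable], catalog: NiebCatalog,
                  specs: list[ContextSpec | str], max_offset: int,
                  regions: pd.DataFrame | None = None, l_min: int = 800,
                  center_halfwidth: int = 300) -> dict[str, ContextRateProfile]:
    """Per-offset rates of context-restricted changes (poly(dA:dT) evolution).

    Context classes are matched on the ancestral sequence; at 5'-border sites
    the reverse-complement spec is matched instead so both borders pool onto
    one strand. Overlapping context classes are allowed. When ``regions`` is
    given, background rates over large-region centers are attached so
    ``selection_windows`` can report context-level S.
    """
    specs = [ContextSpec.parse(s) if isinstance(s, str) else s for s in specs]
    n_bins = 2 * max_offset + 1
    out = {}
    for spec in specs:
        rc = spec.revcomp()
        eligible = np.zeros(n_bins, dtype=np.int64)
        inter = np.zeros(n_bins, dtype=np.int64)
        intra = np.zeros(n_bins, dtype=np.int64)
        bg = np.zeros(4, dtype=np.int64)    # elig, inter, intra, (unused)
        for chrom, sites in sites_by_chrom.items():
            starts, ends = catalog.intervals.per_chrom(chrom)
            off, side = border_offsets(starts, ends, len(sites), max_offset)
            el_f, ev_f = _context_masks(sites, spec)
            el_r, ev_r = _context_masks(sites, rc)
            not_cpg = ~sites.cpg
            five = side == SIDE_FIVE
            el = np.where(five, el_r, el_f) & (off != 0) & not_cpg
            ev = np.where(five, ev_r, ev_f) & (off != 0) & not_cpg
            idx = np.flatnonzero(el)
            np.add.at(eligible, off[idx] + max_offset, 1)
            np.add.at(inter, off[np.flatnonzero(ev)] + max_offset, 1)
            ip, iy = sites.intra_pos, sites.intra_y
            if len(ip):
                el_at = np.where(five[ip], el_r[ip], el_f[ip]) & (off[ip] != 0) & not_cpg[ip]
                y_want = np.where(five[ip], rc.y, spec.y).astype(np.uint8)
                hit = el_at & (iy == y_want)
                np.add.at(intra, off[ip[hit]] + max_offset, 1)
            if regions is not None:
                sub = _central_spans(regions[regions["chrom"] == chrom],
                                     l_min, center_halfwidth) \
                    if (regions["chrom"] == chrom).any() else None
                if sub is not None and len(sub):
                    mask = np.zeros(len(sites), dtype=bool)
                    for s0, e0 in zip(sub["start"], sub["end"]):
                        mask[s0:e0] = True
                    m = mask & not_cpg
                    bg[0] += int((el_f & m).sum() + (el_r & m).sum())
                    bg[1] += int((ev_f & m).sum() + (ev_r & m).sum())
                    if len(ip):
                        in_bg = m[ip]
                        bg[2] += int((el_f[ip] & in_bg & (iy == spec.y)).sum()
                                     + (el_r[ip] & in_bg & (iy == rc.y)).sum())
        prof = ContextRateProfile(spec.name, np.arange(-max_offset, max_offset + 1),
                                  eligible, inter, intra)
        if regions is not None and bg[0] > 0:
            prof.bg_inter = bg[1] / bg[0]
            prof.bg_intra = bg[2] / bg[0]
        out[spec.name] = prof
    return out
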