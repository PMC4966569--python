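"""Border-aligned averaging of per-base statistics around barriers.

The offset convention follows the figures of the analysis: negative offsets
are inside a barrier (offset -k is the k-th base in from the nearer border,
ties to the 5' border), positive offsets are flank positions measured from
the nearer barrier border. Flank sites between two barriers belong to the
nearer one, so no site is double-counted and sites inside a neighbouring
barrier never enter flank averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import NiebCatalog
from .core import GenomeSequence

#: side codes for border_offsets
SIDE_NONE, SIDE_FIVE, SIDE_THREE = 0, 1, 2


def border_offsets(starts: np.ndarray, ends: np.ndarray, length: int,
                   max_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-base offset to the nearest barrier border, and which border it is.

    Returns ``(offset, side)`` arrays of length ``length``. ``offset`` is a
    signed int32: -k for the k-th base inside a barrier counting from the
    nearer border, +k for the k-th flank base outside, 0 for unassigned sites
    (no barrier on the chromosome, or farther than ``max_offset`` from any
    border). ``side`` is SIDE_FIVE when the governing border is a barrier
    start (these sites are reverse-complement-pooled for strand-asymmetric
    statistics) and SIDE_THREE for a barrier end; ties go to the 5' border.
    """
    offset = np.zeros(length, dtype=np.int32)
    side = np.zeros(length, dtype=np.uint8)
    n = len(starts)
    if n == 0:
        return offset, side

    def fill_inside(s: int, e: int) -> None:
        w = e - s
        nl = (w + 1) // 2          # left half, ties to the 5' border
        kl = min(nl, max_offset)
        offset[s:s + kl] = -np.arange(1, kl + 1)
        side[s:s + kl] = SIDE_FIVE
        nr = w - nl
        kr = min(nr, max_offset)
        if kr > 0:
            offset[e - kr:e] = -np.arange(kr, 0, -1)
            side[e - kr:e] = SIDE_THREE

    def fill_right_flank(e: int, n3: int) -> None:
        # flank of a 3' border: positions e .. e+n3-1, offsets 1..n3
        k = min(n3, max_offset)
        offset[e:e + k] = np.arange(1, k + 1)
        side[e:e + k] = SIDE_THREE

    def fill_left_flank(s: int, n5: int) -> None:
        # flank of a 5' border: positions s-n5 .. s-1, offsets n5..1
        k = min(n5, max_offset)
        offset[s - k:s] = np.arange(k, 0, -1)
        side[s - k:s] = SIDE_FIVE

    fill_left_flank(int(starts[0]), int(starts[0]))
    for i in range(n):
        fill_inside(int(starts[i]), int(ends[i]))
        if i + 1 < n:
            g = int(starts[i + 1]) - int(ends[i])
            n3 = g // 2            # ties (odd g midpoint) go to the 5' side
            fill_right_flank(int(ends[i]), n3)
            fill_left_flank(int(starts[i + 1]), g - n3)
    fill_right_flank(int(ends[-1]), length - int(ends[-1]))
    return offset, side


@dataclass
class BorderAlignedProfile:
    """Per-offset mean of a statistic around barrier borders.

    ``offsets`` is a contiguous 1-bp axis from -max_offset to +max_offset
    (offset 0 is unused and carries count 0); ``mean`` is NaN wherever
    ``count`` is 0. ``count`` is the effective number of contributing
    (mappable, non-N) sites. ``window`` records applied smoothing.
    """

    offsets: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    window: int = 1
    label: str | None = None

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.mean) == len(self.count)):
            raise ValueError("axis/mean/count length mismatch")

    def at(self, offset: int) -> float:
        i = int(np.searchsorted(self.offsets, offset))
        if i >= len(self.offsets) or self.offsets[i] != offset:
            raise KeyError(offset)
        return float(self.mean[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.mean,
                             "count": self.count})


def aggregate(values: dict[str, np.ndarray], catalog: NiebCatalog, max_offset: int,
              valid: dict[str, np.ndarray] | None = None,
              normalize: bool = False, label: str | None = None) -> BorderAlignedProfile:
    """Border-aligned mean of a per-base statistic.

    ``values`` maps chromosome to a float array (NaN marks undefined sites,
    e.g. N bases); ``valid`` optionally restricts to mappable sites. With
    ``normalize`` the profile is divided by the genome average of the
    statistic over all valid sites (error when that average is zero).
    Conservation: sum(mean * count) over offsets equals the statistic total
    over contributing sites.
    """
    n_bins = 2 * max_offset + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    g_sum, g_n = 0.0, 0
    for chrom, vals in values.items():
        vals = np.asarray(vals, dtype=float)
        ok = ~np.isnan(vals)
        if valid is not None and chrom in valid:
            ok &= np.asarray(valid[chrom], dtype=bool)
        g_sum += float(vals[ok].sum())
        g_n += int(ok.sum())
        starts, ends = catalog.intervals.per_chrom(chrom)
        off, _ = border_offsets(starts, ends, len(vals), max_offset)
        use = ok & (off != 0)
        idx = off[use] + max_offset
        sums += np.bincount(idx, weights=vals[use], minlength=n_bins)
        counts += np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    if normalize:
        if g_n == 0 or g_sum == 0:
            raise ValueError("cannot normalize: zero genome average")
        mean = mean / (g_sum / g_n)
    return BorderAlignedProfile(np.arange(-max_offset, max_offset + 1), mean,
                                counts, label=label)


def symmetrize(left: BorderAlignedProfile, right: BorderAlignedProfile,
               mode: str = "average") -> BorderAlignedProfile:
    """Pool the 5'-border profile with the 3'-border profile.

    Both profiles must share the axis. The result is the per-offset average
    weighted by effective counts, so one-sided data passes through unchanged.
    For base-change statistics use mode='revcomp_average' after mapping the
    left profile's change type to its complement (G->A pools with C->T);
    the mapping itself is the caller's bookkeeping (see
    :func:`niebtools.divergence.complement_change`), the arithmetic here is
    identical.
    """
    if mode not in ("average", "revcomp_average"):
        raise ValueError(f"unknown mode {mode!r}")
    if not np.array_equal(left.offsets, right.offsets):
        raise ValueError("profiles are on different offset axes")
    count = left.count + right.count
    num = (np.nan_to_num(left.mean) * left.count
           + np.nan_to_num(right.mean) * right.count)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, num / count, np.nan)
    return BorderAlignedProfile(left.offsets.copy(), mean, count,
                                window=left.window, label=right.label or left.label)


def smooth(profile: BorderAlignedProfile, window: int) -> BorderAlignedProfile:
    """Centered moving average weighted by effective counts.

    The window shrinks at the axis ends. Even windows extend one extra base
    toward negative offsets (numpy 'same' convolution convention); the
    figure-style windows are 10 and 30 bp.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return replace(profile, mean=profile.mean.copy(), count=profile.count.copy())
    kern = np.ones(window)
    num = np.convolve(np.nan_to_num(profile.mean) * profile.count, kern, mode="same")
    den = np.convolve(profile.count, kern, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(den > 0, num / den, np.nan)
    return BorderAlignedProfile(profile.offsets.copy(), mean, profile.count.copy(),
                                window=window, label=profile.label)


# ---------------------------------------------------------------------------
# Heat maps over inter-barrier regions


def _smear_coverage(length: int, loci: np.ndarray, tags: np.ndarray) -> np.ndarray:
    """Nucleosome coverage within one region: each locus with c observed tags
    contributes a centered segment of length 2c; coverage is the union."""
    depth = np.zeros(length + 1, dtype=np.int32)
    lo = np.clip(loci - tags, 0, length)
    hi = np.clip(loci + tags, 0, length)
    np.add.at(depth, lo, 1)
    np.add.at(depth, hi, -1)
    return (np.cumsum(depth[:-1]) > 0).astype(float)


@dataclass
class HeatMap:
    """Width-ordered heat map: rows are means over ``group_size`` consecutive
    inter-barrier regions (smallest at the top), columns are offsets from the
    region center, values clipped to [0, 1]."""

    values: np.ndarray              # (n_rows, n_cols), NaN outside regions
    col_offsets: np.ndarray
    group_size: int

    def to_png(self, path: str, cmap: str = "Blues") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(self.values, aspect="auto", cmap=cmap, vmin=0, vmax=1,
                  extent=[self.col_offsets[0], self.col_offsets[-1],
                          self.values.shape[0], 0])
        ax.set_xlabel("distance to inter-region center (bp)")
        ax.set_ylabel("region group (smallest widths first)")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_heatmap(per_region_values, regions: pd.DataFrame, group_size: int = 200,
                  display_width: int = 1600) -> HeatMap:
    """Heat map of a per-base signal over center-aligned inter-barrier regions.

    ``per_region_values`` is a callable (chrom, start, end) -> float array of
    length end-start with values in [0, 1] (e.g. smeared nucleosome coverage
    or a GC indicator). Regions are sorted by width; each row is the NaN-mean
    over ``group_size`` consecutive regions (a final partial group forms the
    last row; fewer regions than ``group_size`` give a single row). Only the
    central ``display_width`` bp of regions larger than that are shown.
    """
    regions = regions.sort_values("d", kind="mergesort").reset_index(drop=True)
    half = display_width // 2
    cols = np.arange(-half, half + 1)
    n_rows = max(1, int(np.ceil(len(regions) / group_size)))
    out = np.full((n_rows, len(cols)), np.nan)
    row_sum = np.zeros(len(cols))
    row_n = np.zeros(len(cols))
    row = 0
    in_row = 0
    for rec in regions.itertuples(index=False):
        vals = np.asarray(per_region_values(rec.chrom, rec.start, rec.end), dtype=float)
        d = rec.end - rec.start
        center = d // 2
        lo = max(0, center - half)
        hi = min(d, center + half + 1)
        ci0 = (lo - center) + half
        seg = vals[lo:hi]
        ok = ~np.isnan(seg)
        row_sum[ci0:ci0 + len(seg)][ok] += seg[ok]
        row_n[ci0:ci0 + len(seg)][ok] += 1
        in_row += 1
        if in_row == group_size:
            with np.errstate(invalid="ignore"):
                out[row] = np.where(row_n > 0, row_sum / row_n, np.nan)
            row += 1
            in_row = 0
            row_sum[:] = 0.0
            row_n[:] = 0.0
    if in_row:
        with np.errstate(invalid="ignore"):
            out[row] = np.where(row_n > 0, row_sum / row_n, np.nan)
    return HeatMap(np.clip(out, 0.0, 1.0), cols, group_size)


def tag_heatmap(track, regions: pd.DataFrame, group_size: int = 200,
                display_width: int = 1600, smear: bool = True) -> HeatMap:
    """Nucleosome-density heat map from a dyad TagTrack with the tag-smearing
    rule (segments of length twice the tag count)."""

    def values(chrom, start, end):
        counts = track[chrom][start:end]
        if not smear:
            return np.clip(counts, 0, 1).astype(float)
        loci = np.flatnonzero(counts)
        return _smear_coverage(end - start, loci, counts[loci])

    return build_heatmap(values, regions, group_size, display_width)


# ---------------------------------------------------------------------------
# Polynucleotide tracks and gene-anchored profiles


def polynucleotide_coverage(codes: np.ndarray, base_code: int, k: int) -> np.ndarray:
    """Boolean per-base vector: position lies inside a homopolymer run of
    ``base_code`` of length >= k (equivalently, covered by at least one
    occurrence of the k-mer)."""
    is_b = codes == base_code
    padded = np.concatenate([[False], is_b, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = np.zeros(len(codes), dtype=bool)
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= k:
            out[s:e] = True
    return out


def polynucleotide_profile(genome: dict[str, GenomeSequence], catalog: NiebCatalog,
                           max_offset: int, ks: tuple[int, ...] = (3, 5, 7),
                           masked: bool = True) -> dict[str, BorderAlignedProfile]:
    """Border-aligned coverage of poly(A) and poly(T) tracks (fraction of
    sites covered by at least one A^k or T^k occurrence), repeat-masked by
    default."""
    out = {}
    for k in ks:
        for base, code in (("A", 0), ("T", 3)):
            values = {}
            for chrom, rec in genome.items():
                codes = rec.codes
                cov = polynucleotide_coverage(codes, code, k).astype(float)
                cov[codes == 4] = np.nan
                if masked and rec.mask is not None:
                    cov[rec.mask] = np.nan
                values[chrom] = cov
            name = base * k
            out[name] = aggregate(values, catalog, max_offset, label=name)
    return out


def tss_profile(values: dict[str, np.ndarray], genes: pd.DataFrame, max_offset: int,
                anchor: str = "tss",
                class_col: str | None = None) -> dict[str, pd.DataFrame]:
    """Gene-anchored profiles of a per-base statistic with orientation applied.

    ``genes`` needs chrom / start / end / strand (+ optional class column).
    The anchor is the TSS (gene start on +, end on -) or TTS; offsets run 5'
    to 3' in gene orientation. Unstranded genes are excluded. Returns one
    frame (offset, value, n) per class ('all' when no class column given).
    """
    offsets = np.arange(-max_offset, max_offset + 1)
    genes = genes[genes["strand"].isin(["+", "-"])]
    groups = genes.groupby(class_col) if class_col else [("all", genes)]
    out = {}
    for cls, sub in groups:
        total = np.zeros(len(offsets))
        n = np.zeros(len(offsets))
        for rec in sub.itertuples(index=False):
            vals = values[rec.chrom]
            length = len(vals)
            if anchor == "tss":
                a = rec.start if rec.strand == "+" else rec.end - 1
            elif anchor == "tts":
                a = rec.end - 1 if rec.strand == "+" else rec.start
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            pos = a + offsets if rec.strand == "+" else a - offsets
            ok = (pos >= 0) & (pos < length)
            v = vals[np.clip(pos, 0, length - 1)]
            ok &= ~np.isnan(v)
            total[ok] += v[ok]
            n[ok] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, total / n, np.nan)
        out[str(cls)] = pd.DataFrame({"offset": offsets, "value": mean,
                                      "n": n.astype(int)})
    return out
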