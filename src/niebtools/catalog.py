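"""Barrier (NIEB) catalog management and spacing statistics.

A NIEB catalog is a sorted, non-overlapping set of strand-less genomic
intervals predicted to exclude nucleosomes. This module provides width
filtering, border-to-border interdistances, the exponential spacing fit, the
quantized short-spacing comb, nucleosome-class assignment of inter-barrier
regions, genome coverage accounting, 100-kb window stratification and
feature-anchored barrier-coverage profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntervalSet

logger = logging.getLogger(__name__)

#: default comb of quantized interdistances: d = offset + period * k
COMB_OFFSET = 117
COMB_PERIOD = 153
#: interdistance above which nucleosome positioning turns fuzzy
D_CRYSTAL = 800


@dataclass
class NiebCatalog:
    """A width-bounded barrier catalog (sorted, non-overlapping intervals)."""

    intervals: IntervalSet
    min_width: int = 36
    max_width: int = 450

    def __post_init__(self) -> None:
        df = self.intervals.df
        for chrom in self.intervals.chroms:
            starts, ends = self.intervals.per_chrom(chrom)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping barriers in catalog")

    def __len__(self) -> int:
        return len(self.intervals)

    def widths(self) -> np.ndarray:
        return self.intervals.widths()

    def width_stats(self) -> dict[str, float]:
        w = self.widths()
        return {"n": len(w), "min": float(w.min()), "max": float(w.max()),
                "mean": float(w.mean())}


def filter_widths(catalog: NiebCatalog | IntervalSet, min_width: int = 36,
                  max_width: int = 450) -> NiebCatalog:
    """Retain barriers with min_width <= width <= max_width (the raw physical
    model emits some very large barriers with non-negligible occupancy, which
    are discarded). Discard counts are logged."""
    intervals = catalog.intervals if isinstance(catalog, NiebCatalog) else catalog
    w = intervals.widths()
    keep = (w >= min_width) & (w <= max_width)
    n_small = int((w < min_width).sum())
    n_large = int((w > max_width).sum())
    if n_small or n_large:
        logger.info("filter_widths: discarded %d (< %d bp) and %d (> %d bp) barriers",
                    n_small, min_width, n_large, max_width)
    return NiebCatalog(IntervalSet(intervals.df[keep]), min_width, max_width)


def internieb_regions(catalog: NiebCatalog,
                      sequenced_mask: dict[str, np.ndarray] | None = None,
                      max_n_run: int = 100) -> pd.DataFrame:
    """Gaps between consecutive barriers on the same chromosome.

    Returns a frame with chrom / start / end / d (= end - start, border to
    border). Gaps containing at least one unsequenced (N) run longer than
    ``max_n_run`` bp are dropped (non-fully-sequenced gaps), with the dropped
    count logged.
    """
    rows = []
    n_dropped = 0
    for chrom in catalog.intervals.chroms:
        starts, ends = catalog.intervals.per_chrom(chrom)
        if len(starts) < 2:
            continue
        gap_s, gap_e = ends[:-1], starts[1:]
        keep = np.ones(len(gap_s), dtype=bool)
        if sequenced_mask is not None and chrom in sequenced_mask:
            unseq = ~np.asarray(sequenced_mask[chrom], dtype=bool)
            # run-length encode unsequenced stretches once per chromosome
            padded = np.concatenate([[False], unseq, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            run_s, run_e = edges[::2], edges[1::2]
            long_runs = (run_e - run_s) > max_n_run
            run_s, run_e = run_s[long_runs], run_e[long_runs]
            if len(run_s):
                # a gap is dropped if any long run intersects it
                lo = np.searchsorted(run_e, gap_s, side="right")
                hi = np.searchsorted(run_s, gap_e, side="left")
                keep = hi <= lo
        n_dropped += int((~keep).sum())
        for s, e in zip(gap_s[keep], gap_e[keep]):
            rows.append((chrom, int(s), int(e), int(e - s)))
    if n_dropped:
        logger.info("internieb_regions: dropped %d non-fully-sequenced gaps", n_dropped)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "d"])


def interdistances(catalog: NiebCatalog,
                   sequenced_mask: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Border-to-border interdistances between successive barriers."""
    return internieb_regions(catalog, sequenced_mask)["d"].to_numpy()


@dataclass
class SpacingFit:
    """Exponential fit of the interdistance tail plus the short-range comb."""

    mean: float                      # exponential mean interdistance (bp)
    d_min: float                     # truncation point of the fit
    n: int                           # sample size used
    degenerate: bool = False         # all values identical
    peak_offset: int | None = None   # comb offset o of d = o + p*k
    peak_period: int | None = None


def fit_exponential_tail(ds: np.ndarray, d_min: float = 0.0) -> SpacingFit:
    """Maximum-likelihood exponential mean of the truncated interdistance sample.

    By memorylessness, the MLE of the exponential mean given d >= d_min is
    mean(d - d_min); with d_min = 0 this is the sample mean. Fewer than 100
    values triggers a warning (the fit is still returned); a constant sample
    is flagged degenerate.
    """
    ds = np.asarray(ds, dtype=float)
    tail = ds[ds >= d_min]
    if len(tail) == 0:
        raise ValueError("no interdistances above d_min")
    if len(tail) < 100:
        warnings.warn(f"exponential fit on only {len(tail)} interdistances",
                      stacklevel=2)
    mean = float(np.mean(tail - d_min))
    return SpacingFit(mean=mean, d_min=d_min, n=len(tail),
                      degenerate=bool(np.all(tail == tail[0])))


def detect_quantized_peaks(ds: np.ndarray, d_max: int = 1000,
                           offset_grid: np.ndarray | None = None,
                           period_grid: np.ndarray | None = None,
                           n_teeth: int = 5, smooth: int = 3,
                           baseline_window: int = 75,
                           min_contrast: float = 0.15) -> tuple[int, int] | None:
    """Locate the comb of quantized small interdistances (d = offset + period*k).

    The 1-bp histogram below ``d_max`` is lightly smoothed, divided by a
    broadly smoothed baseline (removing the exponential trend), and the comb
    score of a candidate (offset, period) is the mean of this trend-normalized
    histogram over the teeth offset + k*period, k = 0..n_teeth-1. The grid
    maximum is returned unless its contrast over the baseline is below
    ``min_contrast`` or below 5 counting standard errors of the tooth mass
    (flat, purely exponential, or too-sparse histograms give a null result).
    If the true period lies outside the grid the best in-grid comb is still
    returned.
    """
    ds = np.asarray(ds)
    ds = ds[(ds > 0) & (ds < d_max)]
    if len(ds) == 0:
        return None
    hist = np.bincount(ds.astype(np.int64), minlength=d_max).astype(float)
    kern = np.ones(smooth) / smooth
    hist_s = np.convolve(hist, kern, mode="same")
    base = np.convolve(hist, np.ones(baseline_window) / baseline_window, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(base > 0, hist_s / base, np.nan)
    if offset_grid is None:
        offset_grid = np.arange(80, 161)
    if period_grid is None:
        period_grid = np.arange(120, 201)
    best, best_score, best_teeth = None, -np.inf, None
    for p in period_grid:
        ks = np.arange(n_teeth) * p
        valid_offsets = offset_grid[offset_grid + ks[-1] < d_max]
        if len(valid_offsets) == 0:
            continue
        teeth = valid_offsets[:, None] + ks[None, :]
        with np.errstate(invalid="ignore"):
            scores = np.nanmean(ratio[teeth], axis=1)
        if np.all(np.isnan(scores)):
            continue
        i = int(np.nanargmax(scores))
        if scores[i] > best_score:
            best_score, best = scores[i], (int(valid_offsets[i]), int(p))
            best_teeth = teeth[i]
    if best is None or not np.isfinite(best_score):
        return None
    # Poisson counting error of the mean tooth ratio: each tooth averages
    # ``smooth`` 1-bp bins whose expected count is the local baseline
    expected = np.nansum(base[best_teeth]) * smooth
    rel_se = 1.0 / np.sqrt(expected) if expected > 0 else np.inf
    if best_score < 1.0 + max(min_contrast, 5.0 * rel_se):
        return None
    return best


def classify_internieb(d: np.ndarray | float, period: int = COMB_PERIOD,
                       offset: int = COMB_OFFSET, n_max: int = 5,
                       d_crystal: int = D_CRYSTAL) -> np.ndarray:
    """Nucleosome-count class of an inter-barrier region of width d.

    Regions up to ``d_crystal`` carry a crystal-like array of n regularly
    spaced nucleosomes; n is the nearest comb tooth, n = round((d - offset) /
    period) + 1 clipped to [1, n_max]. Wider regions are 'fuzzy' (coded 0).
    """
    d = np.asarray(d)
    n = np.rint((d - offset) / period).astype(int) + 1
    n = np.clip(n, 1, n_max)
    return np.where(d > d_crystal, 0, n)


@dataclass
class CoverageAccounting:
    barrier_bp: int
    crystal_bp: int
    flanking_bp: int
    sequenced_bp: int
    flank_span: int

    @property
    def total_bp(self) -> int:
        return self.barrier_bp + self.crystal_bp + self.flanking_bp

    def percentages(self) -> dict[str, float]:
        f = 100.0 / self.sequenced_bp
        return {"barriers": self.barrier_bp * f, "crystal": self.crystal_bp * f,
                "flanking": self.flanking_bp * f, "total": self.total_bp * f}


def coverage_accounting(catalog: NiebCatalog, regions: pd.DataFrame,
                        sequenced_bp: int, flank_span: int = 270,
                        n_max: int = 5, d_crystal: int = D_CRYSTAL) -> CoverageAccounting:
    """Genome coverage of the three intrinsic-chromatin components.

    Components: (i) barrier bp; (ii) bp of inter-barrier regions carrying a
    crystal-like array (class n <= n_max); (iii) the two well-positioned
    flanking nucleosomes on each side of the large (d > d_crystal) regions,
    2 * flank_span bp per region. The components are disjoint by construction
    provided 2 * flank_span <= d_crystal; percentages are relative to the
    sequenced genome length.
    """
    if 2 * flank_span > d_crystal:
        raise AssertionError("flanking spans would overlap within a large region")
    barrier_bp = int(catalog.widths().sum())
    if len(regions):
        classes = classify_internieb(regions["d"].to_numpy(), n_max=n_max,
                                     d_crystal=d_crystal)
        crystal_bp = int(regions["d"].to_numpy()[classes > 0].sum())
        n_large = int((classes == 0).sum())
    else:
        crystal_bp, n_large = 0, 0
    acc = CoverageAccounting(barrier_bp, crystal_bp, n_large * 2 * flank_span,
                             sequenced_bp, flank_span)
    if acc.total_bp > sequenced_bp:
        raise AssertionError("coverage components exceed sequenced genome length")
    return acc


# ---------------------------------------------------------------------------
# 100-kb window stratification

GC_CLASS_CUTS = (0.38, 0.42, 0.47, 0.52)
GC_CLASS_NAMES = ("L1", "L2", "H1", "H2", "H3")
MRT_CUTS = (0.36, 0.69)
MRT_NAMES = ("early", "medium", "late")
DNASE_CUTS = (14.3, 29.3)       # reads/kb
RECOMB_CUTS = (0.378, 1.681)    # cM/Mb
TERCILE_NAMES = ("low", "medium", "high")


def _classify(values: np.ndarray, cuts, names) -> np.ndarray:
    out = np.array([None] * len(values), dtype=object)
    ok = ~pd.isna(values)
    idx = np.searchsorted(np.asarray(cuts), values[ok].astype(float), side="right")
    out[ok] = np.asarray(names, dtype=object)[idx]
    return out


def window_stratification(catalog: NiebCatalog, windows: pd.DataFrame,
                          quantile_thresholds: bool = False) -> pd.DataFrame:
    """Classify 100-kb windows and attach barrier density and coverage.

    ``windows`` needs columns chrom / start / end and any of the covariates
    gc (fraction), mrt (0-1), dnase (reads/kb), recomb (cM/Mb). GC classes are
    the isochore strata L1..H3 at cuts 38/42/47/52 %; MRT splits at 0.36/0.69;
    DNase and recombination use the fixed default thresholds (or 30/40/30
    quantiles when ``quantile_thresholds``). A window missing a covariate gets
    no class for that stratification. Density is barriers/kb (counted by
    barrier midpoint); coverage is the percent of the window covered by
    barriers.
    """
    win = windows.copy().reset_index(drop=True)
    widths_kb = (win["end"] - win["start"]).to_numpy() / 1000.0
    counts = np.zeros(len(win))
    cov_bp = np.zeros(len(win))
    for chrom, sub in win.groupby("chrom", sort=False):
        starts, ends = catalog.intervals.per_chrom(chrom)
        if len(starts) == 0:
            continue
        mids = (starts + ends) // 2
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        order = np.argsort(ws)
        lo = np.searchsorted(mids, ws[order])
        hi = np.searchsorted(mids, we[order])
        counts[sub.index.to_numpy()[order]] = hi - lo
        # barrier bp per window: clip each barrier into every window it touches
        for j, irow in zip(range(len(sub)), sub.index):
            a, b = ws[j], we[j]
            i0 = np.searchsorted(ends, a, side="right")
            i1 = np.searchsorted(starts, b, side="left")
            if i1 > i0:
                cov_bp[irow] = np.minimum(ends[i0:i1], b).sum() - np.maximum(starts[i0:i1], a).sum()
    win["nieb_density"] = counts / widths_kb
    win["nieb_coverage_pct"] = 100.0 * cov_bp / (widths_kb * 1000.0)

    if "gc" in win:
        win["gc_class"] = _classify(win["gc"].to_numpy(), GC_CLASS_CUTS, GC_CLASS_NAMES)
    if "mrt" in win:
        win["mrt_class"] = _classify(win["mrt"].to_numpy(), MRT_CUTS, MRT_NAMES)
    for col, cuts in (("dnase", DNASE_CUTS), ("recomb", RECOMB_CUTS)):
        if col in win:
            vals = win[col].to_numpy(dtype=float)
            use = np.nanquantile(vals, [0.3, 0.7]) if quantile_thresholds else cuts
            win[f"{col}_class"] = _classify(vals, use, TERCILE_NAMES)
    return win


def class_summary(windows: pd.DataFrame, class_col: str) -> pd.DataFrame:
    """Per-class mean barrier density and coverage over classified windows."""
    sub = windows[~pd.isna(windows[class_col])]
    return (sub.groupby(class_col)
            .agg(n_windows=("nieb_density", "size"),
                 density=("nieb_density", "mean"),
                 coverage_pct=("nieb_coverage_pct", "mean"))
            .reset_index())


def feature_overlap_profile(catalog: NiebCatalog, features: IntervalSet,
                            max_offset: int, lengths: dict[str, int],
                            anchor: str = "midpoint") -> pd.DataFrame:
    """Mean barrier coverage as a function of distance to feature anchors.

    ``anchor`` is 'midpoint' or 'start'. Offsets outside the chromosome are
    excluded per anchor. Returns a frame with offset / coverage / n columns.
    """
    offsets = np.arange(-max_offset, max_offset + 1)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets))
    for chrom, length in lengths.items():
        starts, ends = features.per_chrom(chrom)
        if len(starts) == 0:
            continue
        anchors = (starts + ends) // 2 if anchor == "midpoint" else starts
        cov = catalog.intervals.coverage_mask(chrom, length)
        for chunk in np.array_split(anchors, max(1, len(anchors) // 2048)):
            pos = chunk[:, None] + offsets[None, :]
            ok = (pos >= 0) & (pos < length)
            vals = np.where(ok, cov[np.clip(pos, 0, length - 1)], 0)
            total += vals.sum(axis=0)
            n += ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        coverage = np.where(n > 0, total / n, np.nan)
    return pd.DataFrame({"offset": offsets, "coverage": coverage, "n": n.astype(int)})
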