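"""Per-barrier nucleosome-occupancy Z-test and group summaries.

Each barrier's per-site dyad tag level is compared with its two 300-bp
flanking windows: z = (m2 - m1) / sqrt(s1^2/n1 + s2^2/n2), where (m1, s1, n1)
are the mean, SD and count of tags per mappable site inside the barrier and
(m2, s2, n2) the same over the two flanks pooled. Under the no-difference
null z is approximately standard normal, so z > 1.645 flags significant
depletion at the 5 % level (group G1), z < -1.645 significant enrichment
(G2), and the rest is G3. Barriers with n1 or n2 <= 30 are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import NiebCatalog
from .core import MappabilityTrack, TagTrack

Z_THRESHOLD = 1.645    # one-sided 5 % point of the standard normal
MIN_SITES = 30         # n1 and n2 must exceed this
FLANK_SPAN = 300       # bp per flanking window, one on each side


@dataclass
class ZTestInput:
    """Summary statistics for one barrier: inside (1) vs pooled flanks (2).
    SDs are population-form (denominator n)."""

    m1: float
    s1: float
    n1: int
    m2: float
    s2: float
    n2: int


@dataclass
class ZTestResult:
    z: float               # NaN when undefined
    group: str             # G1 / G2 / G3 / excluded


def ztest_classify(inp: ZTestInput, threshold: float = Z_THRESHOLD,
                   min_sites: int = MIN_SITES) -> ZTestResult:
    """Classify one barrier from its summary statistics.

    Excluded when min(n1, n2) <= min_sites. Both variances zero with equal
    means gives an undefined z, conventionally G3 (no evidence either way).
    z is scale-invariant: rescaling all per-site tag values by c > 0 rescales
    means and SDs alike and leaves the classification unchanged.
    """
    if min(inp.n1, inp.n2) <= min_sites:
        return ZTestResult(np.nan, "excluded")
    se2 = inp.s1 ** 2 / inp.n1 + inp.s2 ** 2 / inp.n2
    if se2 == 0.0:
        if inp.m1 == inp.m2:
            return ZTestResult(np.nan, "G3")
        z = np.inf if inp.m2 > inp.m1 else -np.inf
    else:
        z = (inp.m2 - inp.m1) / np.sqrt(se2)
    if z > threshold:
        group = "G1"
    elif z < -threshold:
        group = "G2"
    else:
        group = "G3"
    return ZTestResult(float(z), group)


def _window_stats(cum_t, cum_t2, cum_n, lo, hi):
    """Mean/SD/count of tags per mappable site on [lo, hi) from cumsums."""
    n = cum_n[hi] - cum_n[lo]
    t = cum_t[hi] - cum_t[lo]
    t2 = cum_t2[hi] - cum_t2[lo]
    if n == 0:
        return 0.0, 0.0, 0
    m = t / n
    var = max(t2 / n - m * m, 0.0)
    return m, float(np.sqrt(var)), int(n)


def classify_catalog(catalog: NiebCatalog, tags: TagTrack,
                     mappability: MappabilityTrack | None = None,
                     flank_span: int = FLANK_SPAN,
                     threshold: float = Z_THRESHOLD,
                     min_sites: int = MIN_SITES) -> pd.DataFrame:
    """Run the Z-test over every barrier in the catalog.

    Flank windows span ``flank_span`` bp on each side, truncated at the
    neighbouring barrier borders and chromosome ends (truncation can push n2
    below the site minimum, excluding the barrier). Only mappable sites enter
    the means and SDs; zero-tag mappable sites count. Returns a frame with
    chrom / start / end / z / group.
    """
    rows = []
    for chrom in catalog.intervals.chroms:
        starts, ends = catalog.intervals.per_chrom(chrom)
        t = tags[chrom].astype(np.float64)
        mp = (mappability[chrom] if mappability is not None
              else np.ones(len(t), dtype=bool))
        tm = np.where(mp, t, 0.0)
        cum_t = np.concatenate([[0.0], np.cumsum(tm)])
        cum_t2 = np.concatenate([[0.0], np.cumsum(tm * tm)])
        cum_n = np.concatenate([[0], np.cumsum(mp.astype(np.int64))])
        length = len(t)
        for i, (s, e) in enumerate(zip(starts, ends)):
            m1, s1, n1 = _window_stats(cum_t, cum_t2, cum_n, s, e)
            # left flank truncated at the previous barrier / chromosome start
            lf_lo = max(s - flank_span, 0, ends[i - 1] if i > 0 else 0)
            # right flank truncated at the next barrier / chromosome end
            rf_hi = min(e + flank_span, length,
                        starts[i + 1] if i + 1 < len(starts) else length)
            nL = cum_n[s] - cum_n[lf_lo]
            nR = cum_n[rf_hi] - cum_n[e]
            n2 = int(nL + nR)
            tsum = (cum_t[s] - cum_t[lf_lo]) + (cum_t[rf_hi] - cum_t[e])
            t2sum = (cum_t2[s] - cum_t2[lf_lo]) + (cum_t2[rf_hi] - cum_t2[e])
            if n2 > 0:
                m2 = tsum / n2
                s2 = float(np.sqrt(max(t2sum / n2 - m2 * m2, 0.0)))
            else:
                m2, s2 = 0.0, 0.0
            res = ztest_classify(ZTestInput(m1, s1, n1, m2, s2, n2),
                                 threshold, min_sites)
            rows.append((chrom, int(s), int(e), res.z, res.group))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "z", "group"])


def group_summary(results: pd.DataFrame) -> dict[str, float]:
    """Fractions of mappable (non-excluded) barriers per group, plus the
    excluded fraction of the whole catalog. G1+G2+G3 fractions sum to 1."""
    n_total = len(results)
    tested = results[results["group"] != "excluded"]
    n_tested = len(tested)
    out = {g: (float((tested["group"] == g).sum()) / n_tested if n_tested else np.nan)
           for g in ("G1", "G2", "G3")}
    out["excluded"] = float((n_total - n_tested) / n_total) if n_total else np.nan
    out["n_tested"] = n_tested
    return out


def welch_one_sided(mean_a: float, sd_a: float, n_a: int,
                    mean_b: float, sd_b: float, n_b: int) -> float:
    """One-sided Welch unequal-variance test, normal approximation.

    Returns the p-value for the alternative mean_a > mean_b; equal summaries
    give p = 0.5.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("zero counts")
    se = np.sqrt(sd_a ** 2 / n_a + sd_b ** 2 / n_b)
    if se == 0.0:
        return 0.5 if mean_a == mean_b else (0.0 if mean_a > mean_b else 1.0)
    return float(stats.norm.sf((mean_a - mean_b) / se))
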