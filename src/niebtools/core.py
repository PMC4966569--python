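"""Core genomic containers and small derived quantities.

Coordinates are 0-based, half-open everywhere; any 1-based input format is
converted at the reader boundary. Bases are coded A=0, C=1, G=2, T=3 and
N (or gap) = 4; code arrays are ``uint8``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: base -> integer code
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}
#: integer code -> base
CODE_BASES = np.array(list("ACGTN"))
#: complement of each code (N stays N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a base string into the uint8 code alphabet (case-insensitive)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(CODE_BASES[np.asarray(codes)])


@dataclass
class GenomeSequence:
    """One chromosome: uppercase sequence over {A,C,G,T,N} plus optional repeat mask.

    ``mask[i] is True`` means position ``i`` is repeat-masked (by convention read
    from lowercase FASTA letters).
    """

    chrom: str
    seq: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.chrom}: invalid symbols {sorted(bad)!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != len(self.seq):
                raise ValueError("mask length differs from sequence length")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.seq)

    def gc_indicator(self, masked: bool = False) -> np.ndarray:
        """Per-base GC indicator; NaN at N bases (excluded from all denominators)
        and, when ``masked``, at repeat-masked bases."""
        c = self.codes
        out = np.where(c == 4, np.nan, ((c == 1) | (c == 2)).astype(float))
        if masked and self.mask is not None:
            out = np.where(self.mask, np.nan, out)
        return out


class IntervalSet:
    """Sorted genomic intervals in 0-based half-open coordinates.

    Thin wrapper around a DataFrame with columns chrom/start/end (+ optional
    name). After :meth:`merge`, no two records on one chromosome overlap.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"IntervalSet needs columns {sorted(required)}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"record {bad}: start >= end")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_arrays(cls, chrom, starts, ends, names=None) -> "IntervalSet":
        data = {"chrom": chrom, "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64)}
        if names is not None:
            data["name"] = names
        return cls(pd.DataFrame(data))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return len(a) == len(b) and bool((a.values == b.values).all())

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        return int(self.widths().sum())

    def merge(self) -> "IntervalSet":
        """Union of overlapping or adjacent intervals, per chromosome."""
        rows = []
        for chrom in self.chroms:
            starts, ends = self.per_chrom(chrom)
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def coverage_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base vector: covered by at least one interval."""
        out = np.zeros(length, dtype=bool)
        for s, e in zip(*self.per_chrom(chrom)):
            out[max(0, s):min(length, e)] = True
        return out


class TagTrack:
    """Per-chromosome dense dyad tag counts (non-negative integers)."""

    def __init__(self, counts: dict[str, np.ndarray]):
        self.counts = {c: np.asarray(v, dtype=np.int32) for c, v in counts.items()}
        for c, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"{c}: negative tag counts")

    @classmethod
    def zeros(cls, lengths: dict[str, int]) -> "TagTrack":
        return cls({c: np.zeros(n, dtype=np.int32) for c, n in lengths.items()})

    def add_positions(self, chrom: str, positions: np.ndarray) -> int:
        """Increment counts at ``positions``; off-chromosome positions are dropped
        and their number returned."""
        arr = self.counts[chrom]
        positions = np.asarray(positions, dtype=np.int64)
        ok = (positions >= 0) & (positions < len(arr))
        np.add.at(arr, positions[ok], 1)
        dropped = int((~ok).sum())
        if dropped:
            logger.info("%s: dropped %d off-chromosome dyads", chrom, dropped)
        return dropped

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.counts[chrom]


class MappabilityTrack:
    """Per-chromosome boolean per-base vector; True = uniquely mappable."""

    def __init__(self, mappable: dict[str, np.ndarray]):
        self.mappable = {c: np.asarray(v, dtype=bool) for c, v in mappable.items()}

    @classmethod
    def ones(cls, lengths: dict[str, int]) -> "MappabilityTrack":
        return cls({c: np.ones(n, dtype=bool) for c, n in lengths.items()})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.mappable[chrom]


@dataclass
class MarkerSet:
    """Genetic-map markers: per chromosome, (bp position, genetic position in cM),
    sorted by physical position with non-decreasing genetic position."""

    markers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, chrom: str, positions, cm) -> None:
        df = pd.DataFrame({"pos": np.asarray(positions, dtype=np.int64),
                           "cm": np.asarray(cm, dtype=float)}).sort_values("pos")
        if (np.diff(df["cm"].to_numpy()) < 0).any():
            raise ValueError(f"{chrom}: genetic positions decrease with physical position")
        self.markers[chrom] = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Small derived quantities


def assign_dyads(reads: pd.DataFrame, lengths: dict[str, int], shift: int = 70) -> TagTrack:
    """Build a dyad TagTrack from sequenced-read 5' positions.

    A + strand read at p scores one tag at p+shift; a - strand read scores one
    tag at p-shift (the read 5' end sits one read-length upstream of the dyad).
    Shifted positions falling off the chromosome are dropped (count logged).
    Expects columns chrom / pos / strand with strand in {+,-}.
    """
    strands = set(reads["strand"])
    if not strands <= {"+", "-"}:
        raise ValueError(f"invalid strand values {strands - {'+', '-'}}")
    track = TagTrack.zeros(lengths)
    for chrom, sub in reads.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        sign = np.where(sub["strand"].to_numpy() == "+", 1, -1)
        track.add_positions(chrom, pos + sign * shift)
    return track


def rpkm(C: float, N: float, L: float) -> float:
    """Reads per kilobase of exon model per million mapped reads,
    R = 1e9 * C / (N * L). C = exon-overlapping reads, N = total mapped
    reads, L = total exon length (bp). C = 0 gives 0; non-positive N or L
    is undefined."""
    if N <= 0 or L <= 0:
        raise ValueError("RPKM undefined for non-positive N or L")
    if C < 0:
        raise ValueError("negative read count")
    return 1e9 * C / (N * L)


@dataclass
class ExpressionRecord:
    gene_id: str
    C: float
    N: float
    L: float

    @property
    def R(self) -> float:
        return rpkm(self.C, self.N, self.L)


def crossover_rate(window: tuple[str, int, int], markers: MarkerSet,
                   min_markers: int = 5) -> float | None:
    """Crossover rate of a genomic window in cM/Mb.

    Uses the two most distant markers inside the half-open window: genetic
    distance (cM) divided by physical distance (Mb). Returns None (undefined)
    when fewer than ``min_markers`` markers fall in the window or the extreme
    markers coincide physically.
    """
    chrom, start, end = window
    df = markers.markers.get(chrom)
    if df is None:
        return None
    sub = df[(df["pos"] >= start) & (df["pos"] < end)]
    if len(sub) < min_markers:
        return None
    lo, hi = sub.iloc[0], sub.iloc[-1]
    dist_bp = hi["pos"] - lo["pos"]
    if dist_bp == 0:
        return None
    return float((hi["cm"] - lo["cm"]) / (dist_bp / 1e6))


def build_intergenes(genes: IntervalSet, lengths: dict[str, int],
                     margin: int = 2000) -> IntervalSet:
    """Intervals between merged genes, shrunk by ``margin`` bp on each side.

    Gaps of width <= 2*margin vanish. With margin 0 this is the complement of
    the gene set within each chromosome.
    """
    merged = genes.merge()
    rows = []
    for chrom, length in lengths.items():
        starts, ends = merged.per_chrom(chrom)
        gaps_s = np.concatenate([[0], ends])
        gaps_e = np.concatenate([starts, [length]])
        for s, e in zip(gaps_s, gaps_e):
            # only gap ends that abut a gene are trimmed; chromosome ends are not
            lo = s + margin if s > 0 else 0
            hi = e - margin if e < length else length
            if hi > lo:
                rows.append((chrom, int(lo), int(hi)))
    if not rows:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
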