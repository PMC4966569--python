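"""Readers and writers for the on-disk formats.

BED (3+ columns), FASTA (lowercase = repeat-masked, configurable), bedGraph
for per-base scores, TSV for marker sets / expression tables / alignment
columns, and minimal VCF (CHROM, POS, REF, ALT, AF info) for variants.
All coordinates become 0-based half-open at this boundary (VCF POS is
1-based on disk).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .core import GenomeSequence, IntervalSet, MarkerSet, MappabilityTrack


class BedParseError(ValueError):
    pass


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read a 3+ column BED file. Malformed lines raise with their line number;
    inverted intervals (start >= end) are rejected."""
    chroms, starts, ends, names = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else None)
    if any(n is not None for n in names):
        return IntervalSet.from_arrays(chroms, starts, ends, names)
    return IntervalSet.from_arrays(chroms, starts, ends)


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in intervals.df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            name = getattr(row, "name", None)
            if name is not None and not (isinstance(name, float) and np.isnan(name)):
                fields.append(str(name))
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: str | os.PathLike,
               lowercase_masked: bool = True) -> dict[str, GenomeSequence]:
    """Read a FASTA file into per-chromosome GenomeSequence records.

    With ``lowercase_masked`` (default) lowercase letters mark repeat-masked
    positions; the mask is dropped otherwise.
    """
    genome: dict[str, GenomeSequence] = {}
    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False) as fa:
        for name in fa.keys():
            raw = str(fa[name][:])
            mask = None
            if lowercase_masked:
                arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
                mask = (arr >= ord("a")) & (arr <= ord("z"))
            genome[name] = GenomeSequence(name, raw.upper(), mask)
    # pyfaidx leaves a .fai index next to the file; harmless, keep it.
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path: str | os.PathLike,
                width: int = 80) -> None:
    """Write FASTA; repeat-masked positions are emitted lowercase."""
    with open(path, "w") as fh:
        for chrom, rec in genome.items():
            seq = rec.seq
            if rec.mask is not None and rec.mask.any():
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                low = rec.mask & (arr >= ord("A")) & (arr <= ord("Z"))
                arr[low] += 32
                seq = arr.tobytes().decode("ascii")
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bedgraph(path: str | os.PathLike, lengths: dict[str, int],
                  dtype=np.float64) -> dict[str, np.ndarray]:
    """Expand a bedGraph file into dense per-base arrays (zeros where absent)."""
    tracks = {c: np.zeros(n, dtype=dtype) for c, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom in tracks:
                tracks[chrom][start:end] = value
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    """Run-length encode dense per-base arrays into bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom, arr in tracks.items():
            arr = np.asarray(arr)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_mappability(path: str | os.PathLike, lengths: dict[str, int]) -> MappabilityTrack:
    """Mappability from a bedGraph of 0/1 per-base scores; absent bases are
    unmappable."""
    tracks = read_bedgraph(path, lengths, dtype=np.float32)
    return MappabilityTrack({c: v >= 1.0 for c, v in tracks.items()})


def write_mappability(track: MappabilityTrack, path: str | os.PathLike) -> None:
    write_bedgraph({c: v.astype(np.int8) for c, v in track.mappable.items()}, path)


# ---------------------------------------------------------------------------
# Variants (minimal VCF)


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a minimal VCF into a biallelic-row variant table.

    Returns a DataFrame with columns chrom, pos (0-based), ref, alt, af;
    multi-allelic records become one row per ALT with its AF entry.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            afs = rec.info.get("AF")
            if afs is None:
                raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} lacks AF")
            if not isinstance(afs, tuple):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                rows.append((rec.chrom, rec.pos - 1, rec.ref, alt, float(af)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])


def write_vcf(variants: pd.DataFrame, path: str | os.PathLike,
              lengths: dict[str, int] | None = None) -> None:
    """Write a variant table (chrom, pos 0-based, ref, alt, af) as minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        if lengths:
            for chrom, n in lengths.items():
                fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        df = variants.sort_values(["chrom", "pos"], kind="mergesort")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                     f"AF={row.af:.6g}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_markers(path: str | os.PathLike) -> MarkerSet:
    """Genetic-map markers from TSV with columns chrom, pos, cm."""
    df = pd.read_csv(path, sep="\t")
    ms = MarkerSet()
    for chrom, sub in df.groupby("chrom", sort=False):
        ms.add(chrom, sub["pos"].to_numpy(), sub["cm"].to_numpy())
    return ms


def write_markers(markers: MarkerSet, path: str | os.PathLike) -> None:
    parts = []
    for chrom, df in markers.markers.items():
        part = df.copy()
        part.insert(0, "chrom", chrom)
        parts.append(part)
    pd.concat(parts).to_csv(path, sep="\t", index=False)


def read_alignment_columns(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Alignment-column TSV (chrom, pos, h, c, o, m) -> per-chromosome frames
    sorted by position. Bases may be A/C/G/T/N/-."""
    df = pd.read_csv(path, sep="\t", dtype={"h": str, "c": str, "o": str, "m": str})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = sub.sort_values("pos").reset_index(drop=True)
    return out


def write_alignment_columns(tables: dict[str, pd.DataFrame], path: str | os.PathLike) -> None:
    parts = []
    for chrom, df in tables.items():
        part = df.copy()
        if "chrom" not in part.columns:
            part.insert(0, "chrom", chrom)
        parts.append(part)
    pd.concat(parts).to_csv(path, sep="\t", index=False)
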