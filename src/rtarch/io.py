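"""Plain-text genomics formats: BED, bedGraph, FASTA, fragment-count TSV.

Coordinates are enforced 0-based half-open on read; malformed lines are
rejected with their line number.
"""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BinnedTrack, GenomicInterval, IntervalSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_fragment_counts",
    "write_fragment_counts",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    pass


def read_bed(path: PathLike) -> IntervalSet:
    """Read a 3+-column BED file into an IntervalSet."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise FormatError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            intervals.append(GenomicInterval(fields[0], start, end))
    return IntervalSet(intervals)


def write_bed(
    path: PathLike,
    intervals: Iterable[GenomicInterval],
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[int]] = None,
    strands: Optional[Sequence[str]] = None,
) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or strands is not None:
                cols.append(names[i] if names is not None else ".")
                score = scores[i] if scores is not None else 0
                cols.append(str(int(np.clip(score, 0, 1000))))
                cols.append(strands[i] if strands is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: PathLike) -> Dict[str, BinnedTrack]:
    """Read a fixed-bin bedGraph into per-chromosome tracks.

    Bins must be equal width, aligned to the bin grid and non-overlapping;
    absent bins become masked. Overlap or ragged widths are rejected.
    """
    recs: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid coordinates")
            recs.setdefault(fields[0], []).append((start, end, value))
    tracks: Dict[str, BinnedTrack] = {}
    for chrom, rows in recs.items():
        rows.sort()
        widths = {e - s for s, e, _ in rows}
        if len(widths) > 1:
            # the final bin of a chromosome may be short; tolerate one outlier
            widths = {e - s for s, e, _ in rows[:-1]} or widths
            if len(widths) > 1:
                raise FormatError(f"{path}: ragged bin widths on {chrom}")
        bin_size = max(widths)
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise FormatError(f"{path}: overlapping intervals on {chrom} at {s2}")
        for s, e, _ in rows:
            if s % bin_size != 0:
                raise FormatError(f"{path}: interval at {chrom}:{s} off the bin grid")
        n_bins = rows[-1][1] // bin_size + (1 if rows[-1][1] % bin_size else 0)
        n_bins = max(n_bins, rows[-1][0] // bin_size + 1)
        values = np.full(n_bins, np.nan)
        mask = np.ones(n_bins, dtype=bool)
        for s, e, v in rows:
            i = s // bin_size
            values[i] = v
            mask[i] = False
        tracks[chrom] = BinnedTrack(chrom, bin_size, values, mask)
    return tracks


def write_bedgraph(path: PathLike, tracks: Dict[str, BinnedTrack]) -> None:
    """Write per-chromosome tracks as bedGraph; masked bins are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            starts = t.bin_starts()
            for i in range(t.n_bins):
                if t.mask[i]:
                    continue
                fh.write(
                    f"{chrom}\t{starts[i]}\t{starts[i] + t.bin_size}\t{t.values[i]:.6g}\n"
                )


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: Dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fragment_counts(
    path: PathLike, counts: Dict[str, np.ndarray], fragments: Dict[str, np.ndarray]
) -> None:
    """TSV of per-fragment counts: chrom, start, end, count."""
    rows = []
    for chrom in sorted(counts):
        f = fragments[chrom]
        for k in range(len(f)):
            rows.append((chrom, int(f[k, 0]), int(f[k, 1]), float(counts[chrom][k])))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_fragment_counts(path: PathLike) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Read a fragment-count TSV back into (counts, fragments) dictionaries."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    counts: Dict[str, np.ndarray] = {}
    fragments: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        counts[str(chrom)] = sub["count"].to_numpy(dtype=float)
        fragments[str(chrom)] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return counts, fragments
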