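"""Sequence-derived features: GC content, CpG observed/expected ratio,
G-quadruplex and G-rich element scans, and locus stratification.

The G4 scanner is a hand-rolled backtracking matcher for the canonical
four-tract pattern G{3,}(N{1,7}G{3,}){3}; it reproduces greedy,
leftmost, non-overlapping matching on both strands (minus-strand hits are
found on the reverse complement and mapped back).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BinnedTrack, GenomicInterval, IntervalSet

__all__ = [
    "WindowFeature",
    "MotifHit",
    "gc_content",
    "cpg_ratio",
    "scan_g4",
    "scan_ogre",
    "window_features",
    "stratify_loci",
]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str  # "+" | "-"
    motif_class: str  # "G4" | "OGRE"

    @property
    def matched_length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class WindowFeature:
    interval: GenomicInterval
    gc_fraction: float
    cpg_ratio: float
    gc_defined: bool
    n_g4: int
    n_ogre: int


def gc_content(window: str) -> Tuple[float, bool]:
    """GC fraction of a window; N bases are excluded entirely.

    Returns (fraction, defined). ``defined`` is False for all-N windows.
    """
    if len(window) == 0:
        raise ValueError("empty window")
    w = window.upper()
    n_gc = w.count("G") + w.count("C")
    n_at = w.count("A") + w.count("T")
    total = n_gc + n_at
    if total == 0:
        return float("nan"), False
    return n_gc / total, True


def cpg_ratio(window: str) -> Tuple[float, bool]:
    """CpG observed/expected ratio: (CpG dinucleotide freq) / (GC/2)^2.

    Observed CpG frequency counts overlapping "CG" dinucleotides over L-1
    positions; expected is (GC/2)^2 with GC the base fraction. Undefined
    (flag False) when GC = 0.
    """
    if len(window) < 2:
        raise ValueError("window must be at least 2 bp")
    w = window.upper()
    gc, defined = gc_content(w)
    if not defined or gc == 0.0:
        return float("nan"), False
    obs = sum(1 for i in range(len(w) - 1) if w[i : i + 2] == "CG") / (len(w) - 1)
    exp = (gc / 2.0) ** 2
    return obs / exp, True


# --- G4 scanning ----------------------------------------------------------

_MIN_TRACT = 3
_MAX_LOOP = 7
_N_TRACTS = 4


def _g_run_lengths(seq: bytes) -> np.ndarray:
    """Length of the G run starting at every position (0 where not G)."""
    is_g = np.frombuffer(seq, dtype=np.uint8) == ord("G")
    run = np.zeros(len(seq), dtype=np.int32)
    acc = 0
    for i in range(len(seq) - 1, -1, -1):
        acc = acc + 1 if is_g[i] else 0
        run[i] = acc
    return run


def _match_g4_end(run: np.ndarray, i: int, n: int) -> Optional[int]:
    """End of a greedy G4 match starting exactly at position i, else None.

    Replicates backtracking of the greedy pattern G{3,}(N{1,7}G{3,}){3}:
    longest G tract first, then longest loop, varying the deepest
    quantifier fastest.
    """

    def tract(pos: int, tract_no: int) -> Optional[int]:
        g = int(run[pos]) if pos < n else 0
        if g < _MIN_TRACT:
            return None
        if tract_no == _N_TRACTS - 1:
            return pos + g  # final tract is greedy with nothing after it
        for glen in range(g, _MIN_TRACT - 1, -1):
            max_loop = min(_MAX_LOOP, n - (pos + glen))
            for llen in range(max_loop, 0, -1):
                end = tract(pos + glen + llen, tract_no + 1)
                if end is not None:
                    return end
        return None

    return tract(i, 0)


def _scan_g4_forward(seq: bytes) -> List[Tuple[int, int]]:
    """Leftmost, non-overlapping greedy G4 matches on one strand."""
    run = _g_run_lengths(seq)
    n = len(seq)
    hits: List[Tuple[int, int]] = []
    i = 0
    min_len = _N_TRACTS * _MIN_TRACT + (_N_TRACTS - 1)
    while i <= n - min_len:
        if run[i] >= _MIN_TRACT:
            end = _match_g4_end(run, i, n)
            if end is not None:
                hits.append((i, end))
                i = end
                continue
        i += 1
    return hits


def scan_g4(sequence: str, chrom: str = "seq") -> List[MotifHit]:
    """Scan both strands for canonical G4 motifs.

    Plus-strand hits are greedy leftmost matches on the given sequence;
    minus-strand hits are the same scan on the reverse complement, with
    coordinates mapped back to the forward strand.
    """
    seq = sequence.upper().encode("ascii")
    n = len(seq)
    hits = [
        MotifHit(GenomicInterval(chrom, s, e), "+", "G4")
        for s, e in _scan_g4_forward(seq)
    ]
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s, e in _scan_g4_forward(rc):
        hits.append(MotifHit(GenomicInterval(chrom, n - e, n - s), "-", "G4"))
    return sorted(hits, key=lambda h: (h.interval.start, h.strand))


# --- OGRE-style G-rich element scanning -----------------------------------


def _scan_g_dense(seq: bytes, min_len: int, min_frac: float) -> List[Tuple[int, int]]:
    """Greedy maximal G-dense windows: leftmost qualifying window of
    ``min_len``, extended right while the density stays at or above
    ``min_frac``; scanning resumes after each emitted window."""
    is_g = (np.frombuffer(seq, dtype=np.uint8) == ord("G")).astype(np.int64)
    pref = np.concatenate([[0], np.cumsum(is_g)])
    n = len(seq)
    hits: List[Tuple[int, int]] = []
    i = 0
    while i + min_len <= n:
        if (pref[i + min_len] - pref[i]) / min_len >= min_frac:
            j = i + min_len
            while j < n and (pref[j + 1] - pref[i]) / (j + 1 - i) >= min_frac:
                j += 1
            hits.append((i, j))
            i = j
        else:
            i += 1
    return hits


def scan_ogre(
    sequence: str,
    chrom: str = "seq",
    min_len: int = 30,
    min_g_frac: float = 0.67,
) -> List[MotifHit]:
    """Scan both strands for G-rich elements (>= min_g_frac G over >= min_len bp)."""
    if min_len < 1 or not (0.0 < min_g_frac <= 1.0):
        raise ValueError("invalid G-rich element parameters")
    seq = sequence.upper().encode("ascii")
    n = len(seq)
    hits = [
        MotifHit(GenomicInterval(chrom, s, e), "+", "OGRE")
        for s, e in _scan_g_dense(seq, min_len, min_g_frac)
    ]
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s, e in _scan_g_dense(rc, min_len, min_g_frac):
        hits.append(MotifHit(GenomicInterval(chrom, n - e, n - s), "-", "OGRE"))
    return sorted(hits, key=lambda h: (h.interval.start, h.strand))


def window_features(
    sequence: str, interval: GenomicInterval
) -> WindowFeature:
    """All sequence features of one window."""
    sub = sequence[interval.start : interval.end]
    gc, gc_def = gc_content(sub)
    ratio, _ = cpg_ratio(sub) if len(sub) >= 2 else (float("nan"), False)
    return WindowFeature(
        interval=interval,
        gc_fraction=gc,
        cpg_ratio=ratio,
        gc_defined=gc_def,
        n_g4=len(scan_g4(sub, interval.chrom)),
        n_ogre=len(scan_ogre(sub, interval.chrom)),
    )


# --- SNS / TSS stratification ---------------------------------------------


def stratify_loci(
    sns: Sequence[Tuple[str, int]],
    tss: Sequence[Tuple[str, int]],
    rt_tracks: Dict[str, BinnedTrack],
    overlap_bp: int = 1_000,
    rt_bin_bp: int = 200_000,
    early_thr: float = 0.5,
    late_thr: float = -0.5,
    peaks: Optional[IntervalSet] = None,
) -> Tuple[pd.DataFrame, float]:
    """Stratify origin loci by RT class and TSS association.

    Each locus is labeled by the RT class of its 200-kb bin (early, late, or
    the excluded intermediate band) and by whether any TSS lies within
    ``overlap_bp / 2`` of it. When a sharp-peak interval set is supplied the
    fraction of loci overlapped by a peak (association rate) is returned.
    """
    coarse: Dict[str, BinnedTrack] = {}
    for chrom, t in rt_tracks.items():
        coarse[chrom] = t.resample(rt_bin_bp) if t.bin_size != rt_bin_bp else t
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    rows = []
    n_assoc = 0
    for chrom, pos in sns:
        track = coarse.get(chrom)
        if track is None or pos >= track.length_bp:
            rows.append({"chrom": chrom, "pos": pos, "rt": np.nan, "rt_class": "masked",
                         "has_tss": False, "peak": False})
            continue
        rt = track.value_at(pos)
        if np.isnan(rt):
            cls = "masked"
        elif rt > early_thr:
            cls = "early"
        elif rt < late_thr:
            cls = "late"
        else:
            cls = "intermediate"
        near = tss_by_chrom.get(chrom)
        has_tss = False
        if near is not None and len(near):
            i = np.searchsorted(near, pos)
            for j in (i - 1, i):
                if 0 <= j < len(near) and abs(int(near[j]) - pos) <= overlap_bp // 2:
                    has_tss = True
        hit = bool(peaks.covers_point(chrom, pos)) if peaks is not None else False
        n_assoc += hit
        rows.append(
            {"chrom": chrom, "pos": pos, "rt": rt, "rt_class": cls,
             "has_tss": has_tss, "peak": hit}
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "rt", "rt_class", "has_tss", "peak"])
    df["stratum"] = np.where(
        df["rt_class"].isin(["early", "late"]),
        df["rt_class"] + np.where(df["has_tss"], "_TSS+", "_TSS-"),
        "excluded",
    )
    rate = n_assoc / len(sns) if len(sns) else float("nan")
    return df, rate
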