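"""Replication-timing profiles: computation, smoothing, segmentation, switches.

RT is the per-bin log2 ratio of early- over late-fraction read counts;
positive values mean early replication. Domain segmentation thresholds the
(optionally smoothed) profile; switch classification compares a knockout
profile against wild-type baseline domains.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core import BinnedTrack, GenomicInterval, IntervalSet

__all__ = [
    "RTDomain",
    "SwitchCall",
    "RTDistribution",
    "compute_rt",
    "loess_smooth",
    "rt_distribution",
    "segment_rt_domains",
    "classify_switches",
    "delta_rt",
    "boundary_concordance",
]

#: default class thresholds (late: RT < -0.5, early: RT > 0.5)
EARLY_THR = 0.5
LATE_THR = -0.5
#: |mean delta RT| beyond which a region is called switching
DELTA_THR = 1.0


@dataclass(frozen=True)
class RTDomain:
    interval: GenomicInterval
    rt_class: str  # "early" | "late" | "intermediate"
    mean_rt: float


@dataclass(frozen=True)
class SwitchCall:
    interval: GenomicInterval
    baseline_class: str
    delta_rt: float
    switch_class: str  # EtoE | EtoL | LtoE | LtoL | unclassified


@dataclass
class RTDistribution:
    counts: np.ndarray
    edges: np.ndarray
    bimodality: float
    n_tiles: int


def compute_rt(
    early: BinnedTrack, late: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Per-bin RT score log2((early + p) / (late + p)).

    With ``pseudocount == 0``, bins where either count is zero are masked.
    """
    if not early.same_grid(late):
        raise ValueError("early and late tracks are on different bin grids")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    e = early.values + pseudocount
    l = late.values + pseudocount
    mask = early.mask | late.mask
    if pseudocount == 0:
        mask = mask | (early.values <= 0) | (late.values <= 0)
    vals = np.full(early.n_bins, np.nan)
    ok = ~mask
    vals[ok] = np.log2(e[ok] / l[ok])
    return BinnedTrack(early.chrom, early.bin_size, vals, mask)


def loess_smooth(
    rt: BinnedTrack, span_bp: int = 300_000, min_informative: int = 5
) -> BinnedTrack:
    """Locally weighted linear smoothing with a window of ``span_bp``.

    Masked bins are excluded from the fits; output bins are masked where
    fewer than ``min_informative`` informative bins fall within half a span.
    """
    if span_bp < min_informative * rt.bin_size:
        raise ValueError("span must cover at least five bins")
    ok = ~rt.mask
    n_ok = int(ok.sum())
    out = np.full(rt.n_bins, np.nan)
    mask = np.ones(rt.n_bins, dtype=bool)
    if n_ok == 0:
        return BinnedTrack(rt.chrom, rt.bin_size, out, mask)
    x = rt.bin_starts().astype(float) + rt.bin_size / 2.0
    frac = min(1.0, span_bp / rt.bin_size / n_ok)
    fitted = _sm_lowess(
        rt.values[ok], x[ok], frac=frac, it=0, return_sorted=False
    )
    out[ok] = fitted
    # informative-bin count per window
    half = span_bp / 2.0
    ok_x = x[ok]
    lo = np.searchsorted(ok_x, x - half)
    hi = np.searchsorted(ok_x, x + half)
    enough = (hi - lo) >= min_informative
    mask = ~(ok & enough)
    out[mask] = np.nan
    return BinnedTrack(rt.chrom, rt.bin_size, out, mask)


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    Values above 5/9 indicate bimodality (the uniform-distribution benchmark).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 4 or np.ptp(v) == 0:
        return 0.0
    g1 = stats.skew(v, bias=False)
    g2 = stats.kurtosis(v, fisher=True, bias=False)
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1**2 + 1.0) / (g2 + corr))


def rt_distribution(
    tracks: Sequence[BinnedTrack],
    tile_bp: int = 60,
    n_hist_bins: int = 100,
    value_range: Tuple[float, float] = (-6.0, 6.0),
) -> RTDistribution:
    """Genome-wide RT value distribution on small tiles plus bimodality.

    Each bin's value is replicated onto ``tile_bp`` tiles (constant within a
    bin), mirroring a fine-tiled resampling of the binned score.
    """
    if len(tracks) == 0:
        raise ValueError("at least one track required")
    tiled: List[np.ndarray] = []
    for t in tracks:
        reps = max(1, t.bin_size // tile_bp)
        v = t.values[~t.mask]
        tiled.append(np.repeat(v, reps))
    allv = np.concatenate(tiled)
    counts, edges = np.histogram(allv, bins=n_hist_bins, range=value_range)
    return RTDistribution(
        counts=counts,
        edges=edges,
        bimodality=bimodality_coefficient(allv),
        n_tiles=len(allv),
    )


def _classify_bins(values: np.ndarray, mask: np.ndarray, early_thr: float, late_thr: float) -> np.ndarray:
    cls = np.zeros(len(values), dtype=int)  # 0 intermediate, +1 early, -1 late
    cls[(~mask) & (values > early_thr)] = 1
    cls[(~mask) & (values < late_thr)] = -1
    return cls


def segment_rt_domains(
    rt: BinnedTrack,
    early_thr: float = EARLY_THR,
    late_thr: float = LATE_THR,
    min_len_bp: int = 200_000,
) -> List[RTDomain]:
    """Segment a chromosome into early/late/intermediate RT domains.

    Bins are classified against the thresholds, maximal same-class runs are
    taken, and runs of a different class shorter than ``min_len_bp`` that sit
    between two same-class runs are absorbed (gap closing).
    """
    if early_thr <= late_thr:
        raise ValueError("early_thr must exceed late_thr")
    cls = _classify_bins(rt.values, rt.mask, early_thr, late_thr)
    runs = _runs(cls)
    runs = _close_gaps(runs, max(1, min_len_bp // rt.bin_size))
    domains: List[RTDomain] = []
    for b0, b1, c in runs:
        start = b0 * rt.bin_size
        end = min(b1 * rt.bin_size, rt.length_bp)
        name = {1: "early", -1: "late", 0: "intermediate"}[c]
        domains.append(
            RTDomain(GenomicInterval(rt.chrom, start, end), name, rt.mean_over(start, end))
        )
    return domains


def _runs(cls: np.ndarray) -> List[Tuple[int, int, int]]:
    """Maximal runs of equal labels as (start_bin, end_bin, label)."""
    runs = []
    i = 0
    n = len(cls)
    while i < n:
        j = i
        while j < n and cls[j] == cls[i]:
            j += 1
        runs.append((i, j, int(cls[i])))
        i = j
    return runs


def _close_gaps(
    runs: List[Tuple[int, int, int]], max_gap_bins: int
) -> List[Tuple[int, int, int]]:
    """Absorb short runs flanked by two runs of one identical class."""
    changed = True
    while changed:
        changed = False
        for k in range(1, len(runs) - 1):
            b0, b1, c = runs[k]
            prev_c = runs[k - 1][2]
            next_c = runs[k + 1][2]
            if (b1 - b0) < max_gap_bins and prev_c == next_c and prev_c != c:
                runs[k - 1 : k + 2] = [(runs[k - 1][0], runs[k + 1][1], prev_c)]
                changed = True
                break
    return runs


def segmentation_summary(domains: Sequence[RTDomain]) -> Dict[str, float]:
    """Fragmentation metrics: per-class domain counts and size statistics."""
    out: Dict[str, float] = {"n_domains": float(len(domains))}
    for cls in ("early", "late", "intermediate"):
        sizes = [d.interval.length for d in domains if d.rt_class == cls]
        out[f"n_{cls}"] = float(len(sizes))
        out[f"median_size_{cls}"] = float(np.median(sizes)) if sizes else float("nan")
    return out


def delta_rt(rt_wt: BinnedTrack, rt_ko: BinnedTrack) -> BinnedTrack:
    """Per-bin knockout-minus-wildtype RT track."""
    if not rt_wt.same_grid(rt_ko):
        raise ValueError("tracks are on different bin grids")
    mask = rt_wt.mask | rt_ko.mask
    return BinnedTrack(rt_wt.chrom, rt_wt.bin_size, rt_ko.values - rt_wt.values, mask)


def classify_switches(
    rt_wt: BinnedTrack,
    rt_ko: BinnedTrack,
    baseline_domains: Sequence[RTDomain],
    delta_thr: float = DELTA_THR,
) -> List[SwitchCall]:
    """Classify RT switches per baseline domain.

    Mean delta RT over each wild-type domain; late domains with
    delta > +delta_thr switch LtoE, early domains with delta < -delta_thr
    switch EtoL; everything else keeps its baseline (LtoL / EtoE).
    Intermediate baseline domains are left unclassified.
    """
    if not rt_wt.same_grid(rt_ko):
        raise ValueError("tracks are on different bin grids")
    calls: List[SwitchCall] = []
    for dom in baseline_domains:
        if dom.interval.chrom != rt_wt.chrom:
            continue
        mw = rt_wt.mean_over(dom.interval.start, dom.interval.end)
        mk = rt_ko.mean_over(dom.interval.start, dom.interval.end)
        d = mk - mw
        if dom.rt_class == "late":
            sc = "LtoE" if d > delta_thr else "LtoL"
        elif dom.rt_class == "early":
            sc = "EtoL" if d < -delta_thr else "EtoE"
        else:
            sc = "unclassified"
        calls.append(SwitchCall(dom.interval, dom.rt_class, d, sc))
    return calls


def boundary_concordance(
    calls: Sequence[SwitchCall],
    reference: IntervalSet,
    tol_bp: int,
    switching_only: bool = True,
) -> float:
    """Fraction of switch-region edges within ``tol_bp`` of a reference boundary."""
    if len(calls) == 0 or len(reference) == 0:
        raise ValueError("non-empty calls and reference required")
    bounds = reference.boundaries()
    edges: List[Tuple[str, int]] = []
    for c in calls:
        if switching_only and c.switch_class not in ("LtoE", "EtoL"):
            continue
        edges.append((c.interval.chrom, c.interval.start))
        edges.append((c.interval.chrom, c.interval.end))
    if not edges:
        return float("nan")
    hits = 0
    for chrom, pos in edges:
        b = bounds.get(chrom)
        if b is None or len(b) == 0:
            continue
        i = np.searchsorted(b, pos)
        dmin = min(
            abs(pos - b[max(0, i - 1)]),
            abs(pos - b[min(len(b) - 1, i)]),
        )
        if dmin <= tol_bp:
            hits += 1
    return hits / len(edges)
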