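"""Meta-domain and point-centered signal matrices with row clustering.

Domain bodies are rescaled to a fixed number of columns (flanks kept at
fixed bp offsets); point matrices use fixed offsets around locus centers.
Rows are clustered with k-means and relabeled deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import BinnedTrack, GenomicInterval

__all__ = [
    "MetaMatrix",
    "ClusterSolution",
    "meta_domain_matrix",
    "point_signal_matrix",
    "cluster_rows",
    "cluster_rt_summary",
]


@dataclass
class MetaMatrix:
    """Rectangular signal matrix with a missing-data mask.

    ``columns`` carries one label per column: flank columns map to fixed bp
    offsets, body columns to fractional positions within the domain.
    """

    values: np.ndarray
    mask: np.ndarray
    row_ids: List[str]
    columns: List[str]
    n_flank: int = 0  # flank columns on each side (0 for point matrices)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def body_slice(self) -> slice:
        return slice(self.n_flank, self.values.shape[1] - self.n_flank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    centers: np.ndarray  # per-cluster mean profile, ordered by label
    seed: int
    empty_clusters: List[int] = field(default_factory=list)


def _interval_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def meta_domain_matrix(
    domains: Sequence[GenomicInterval],
    tracks: Dict[str, BinnedTrack],
    n_body_bins: int = 40,
    flank_bp: int = 200_000,
    n_flank_bins: int = 20,
) -> MetaMatrix:
    """Scaled meta-domain matrix: fixed flanks around a rescaled body.

    Each domain body is rescaled to ``n_body_bins`` columns by overlap-
    weighted averaging of the source bins under each column slot; flanks of
    ``flank_bp`` on each side are resampled to ``n_flank_bins`` columns.
    Rows keep the input domain order. Domains shorter than one source bin
    produce fully masked rows.
    """
    n_cols = n_body_bins + 2 * n_flank_bins
    vals = np.full((len(domains), n_cols), np.nan)
    mask = np.ones((len(domains), n_cols), dtype=bool)
    for r, iv in enumerate(domains):
        track = tracks.get(iv.chrom)
        if track is None or iv.length < track.bin_size:
            continue
        lv, lm = track.sample_columns(iv.start - flank_bp, iv.start, n_flank_bins)
        bv, bm = track.sample_columns(iv.start, iv.end, n_body_bins)
        rv, rm = track.sample_columns(iv.end, iv.end + flank_bp, n_flank_bins)
        vals[r] = np.concatenate([lv, bv, rv])
        mask[r] = np.concatenate([lm, bm, rm])
    columns = (
        [f"flank_up:{-flank_bp + k * flank_bp // n_flank_bins}" for k in range(n_flank_bins)]
        + [f"body:{(k + 0.5) / n_body_bins:.4f}" for k in range(n_body_bins)]
        + [f"flank_down:{k * flank_bp // n_flank_bins}" for k in range(n_flank_bins)]
    )
    return MetaMatrix(vals, mask, [_interval_id(iv) for iv in domains], columns, n_flank_bins)


def point_signal_matrix(
    loci: Sequence[GenomicInterval],
    tracks: Dict[str, BinnedTrack],
    half_width_bp: int = 5_000,
    n_cols: Optional[int] = None,
) -> MetaMatrix:
    """Fixed-offset signal matrix around locus midpoints.

    Midpoints are taken for interval loci; rows preserve input order so one
    row ordering can be shared across heatmaps. Cells falling off the
    chromosome are masked. Column resolution defaults to the track bin size.
    """
    if n_cols is None:
        bin_size = min(t.bin_size for t in tracks.values())
        n_cols = max(1, (2 * half_width_bp) // bin_size)
    vals = np.full((len(loci), n_cols), np.nan)
    mask = np.ones((len(loci), n_cols), dtype=bool)
    for r, iv in enumerate(loci):
        track = tracks.get(iv.chrom)
        if track is None:
            continue
        mid = iv.mid
        v, m = track.sample_columns(mid - half_width_bp, mid + half_width_bp, n_cols)
        vals[r] = v
        mask[r] = m
    width = 2 * half_width_bp
    columns = [
        f"offset:{-half_width_bp + int((k + 0.5) * width / n_cols)}" for k in range(n_cols)
    ]
    return MetaMatrix(vals, mask, [_interval_id(iv) for iv in loci], columns, 0)


def cluster_rows(matrix: MetaMatrix, k: int = 4, seed: int = 0) -> ClusterSolution:
    """k-means clustering of matrix rows (masked cells mean-imputed).

    Cluster labels are relabeled by decreasing mean center signal, so the
    solution is reproducible under any permutation of the input rows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_rows = matrix.values.shape[0]
    if k > n_rows:
        raise ValueError(f"k={k} exceeds number of rows ({n_rows})")
    x = matrix.values.copy()
    col_means = np.nanmean(np.where(matrix.mask, np.nan, x), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    fill = np.broadcast_to(col_means, x.shape)
    x = np.where(matrix.mask | ~np.isfinite(x), fill, x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    centers = np.full((k, x.shape[1]), np.nan)
    empty = []
    for c in range(k):
        sel = labels == c
        if sel.any():
            centers[c] = x[sel].mean(axis=0)
        else:
            empty.append(c)
    return ClusterSolution(k=k, labels=labels, centers=centers, seed=seed, empty_clusters=empty)


def cluster_rt_summary(
    solution: ClusterSolution,
    rt_per_row: Sequence[float],
    rt_ko_per_row: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-cluster RT distribution summary for one or two genotypes."""
    rt = np.asarray(rt_per_row, dtype=float)
    if len(rt) != len(solution.labels):
        raise ValueError("rt_per_row length does not match cluster solution")
    data = {"cluster": solution.labels, "rt_wt": rt}
    if rt_ko_per_row is not None:
        ko = np.asarray(rt_ko_per_row, dtype=float)
        if len(ko) != len(solution.labels):
            raise ValueError("rt_ko_per_row length does not match cluster solution")
        data["rt_ko"] = ko
    df = pd.DataFrame(data)
    cols = [c for c in ("rt_wt", "rt_ko") if c in df]
    out = df.groupby("cluster")[cols].agg(["count", "mean", "median", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
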