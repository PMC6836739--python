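"""Candidate TSS-cluster calling from csRNA-seq 5'-end coverage.

A cluster is a fixed-width (default 150 bp) strand-specific window
aggregating all 5' ends it contains. Clusters are selected greedily,
deepest window first, with a minimum separation between cluster anchors
on the same strand, then filtered by (1) a depth floor of 7 reads per
10^7 aligned reads and (2) a strictly-greater-than-twofold per-bp read
density over the surrounding 10 kb of the same strand. Each emitted
cluster carries a single-bp primary TSS: the deepest position within the
window.

Window anchoring is canonical: among equal-sum windows the emitted
cluster starts at the leftmost 5' end contained in the maximal window,
so cluster starts always coincide with observed read positions and the
greedy selection is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .coverage import StrandedCoverage
from .iolib import GenomicInterval

log = logging.getLogger("cstss")


@dataclass
class CallerParams:
    """Tunable thresholds of the cluster caller.

    Defaults are the published operating point: 150-bp clusters, a depth
    floor of 7 reads per 10^7 aligned reads (inclusive), and a strictly
    greater than 2-fold per-bp density over the surrounding 10 kb.
    """

    cluster_size: int = 150
    min_depth_per1e7: float = 7.0
    local_fold: float = 2.0
    local_span: int = 10_000
    min_dist: int = 150

    def __post_init__(self) -> None:
        if self.cluster_size <= 0:
            raise ValueError("cluster_size must be > 0")
        if self.local_span <= self.cluster_size:
            raise ValueError("local_span must exceed cluster_size")
        if self.min_depth_per1e7 <= 0 or self.local_fold <= 0:
            raise ValueError("min_depth_per1e7 and local_fold must be > 0")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")


@dataclass
class TSSCluster:
    iv: GenomicInterval
    tss: int
    csrna_raw: int
    csrna_norm: float
    input_norm: Optional[float] = None
    ratio: Optional[float] = None
    local_fold: Optional[float] = None
    stable: Optional[bool] = None
    bidirectional: Optional[bool] = None
    distal: Optional[bool] = None
    feature_class: Optional[str] = None
    nearest_gene: Optional[str] = None
    tss_dist: Optional[int] = None
    sample: str = ""
    cluster_id: str = ""
    cal_class: Optional[str] = None  # TP | FP | UNLABELED (calibration)


def find_candidate_clusters(cov: StrandedCoverage,
                            params: Optional[CallerParams] = None,
                            ) -> List[TSSCluster]:
    """Greedy maximum-first selection of fixed-width candidate windows.

    Per chromosome and strand: every observed 5'-end position anchors a
    candidate ``cluster_size`` window; windows are taken deepest first
    (ties to the lower coordinate), suppressing any candidate whose
    midpoint lies within ``min_dist`` of an already-emitted cluster's
    midpoint on the same strand; a window is emitted only if its
    normalized depth meets ``min_depth_per1e7``.
    """
    params = params or CallerParams()
    w = params.cluster_size
    norm = cov.norm_factor()
    min_raw = params.min_depth_per1e7 / norm  # depth floor in raw reads
    out: List[TSSCluster] = []
    if cov.total_count() == 0:
        log.warning("find_candidate_clusters: empty coverage")
        return out
    for chrom in cov.chroms():
        chrom_len = (cov.chrom_sizes or {}).get(chrom)
        for strand in ("+", "-"):
            pos, counts = cov.arrays(chrom, strand)
            if pos.size == 0:
                continue
            anchors = pos
            if chrom_len is not None:
                anchors = np.minimum(anchors, chrom_len - w)
                anchors = np.unique(np.maximum(anchors, 0))
            cum = np.concatenate(([0], np.cumsum(counts)))
            lo = np.searchsorted(pos, anchors, side="left")
            hi = np.searchsorted(pos, anchors + w, side="left")
            sums = cum[hi] - cum[lo]
            # deepest first, lower coordinate on ties
            order = np.lexsort((anchors, -sums))
            emitted: List[int] = []
            for idx in order:
                s = int(sums[idx])
                if s < min_raw:
                    break  # sums are non-increasing from here on
                a = int(anchors[idx])
                if any(abs(a - e) < params.min_dist for e in emitted):
                    continue
                # canonical start: leftmost read within the window
                i = int(lo[idx])
                start = int(pos[i]) if pos[i] < a + w else a
                if chrom_len is not None and start + w > chrom_len:
                    start = chrom_len - w
                emitted.append(a)
                iv = GenomicInterval(chrom, start, start + w, strand)
                raw = cov.range_count(chrom, strand, start, start + w)
                out.append(TSSCluster(iv=iv, tss=-1, csrna_raw=raw,
                                      csrna_norm=raw * norm,
                                      sample=cov.label))
    return out


def local_background_filter(clusters: List[TSSCluster],
                            cov: StrandedCoverage,
                            params: Optional[CallerParams] = None,
                            ) -> List[TSSCluster]:
    """Keep clusters whose per-bp density strictly exceeds ``local_fold``
    times the same-strand density of the surrounding ``local_span``.

    The background window is centered on the cluster and excludes the
    cluster's own span; an empty background receives a pseudocount of
    0.5 reads. The achieved fold is stored on each kept cluster.
    """
    params = params or CallerParams()
    kept: List[TSSCluster] = []
    for c in clusters:
        chrom = c.iv.chrom
        chrom_len = (cov.chrom_sizes or {}).get(chrom)
        mid = c.iv.midpoint
        bg_start = mid - params.local_span // 2
        bg_end = mid + params.local_span // 2
        if chrom_len is not None:
            bg_start, bg_end = max(bg_start, 0), min(bg_end, chrom_len)
        else:
            bg_start = max(bg_start, 0)
        bg_total = cov.range_count(chrom, c.iv.strand, bg_start, bg_end)
        inner = cov.range_count(chrom, c.iv.strand,
                                max(c.iv.start, bg_start),
                                min(c.iv.end, bg_end))
        bg_reads = bg_total - inner
        overlap = max(0, min(c.iv.end, bg_end) - max(c.iv.start, bg_start))
        bg_width = (bg_end - bg_start) - overlap
        if bg_width <= 0:
            bg_width = params.local_span - params.cluster_size
        density_bg = (bg_reads if bg_reads > 0 else 0.5) / bg_width
        density_in = c.csrna_raw / len(c.iv)
        fold = density_in / density_bg
        if density_in > params.local_fold * density_bg:
            c.local_fold = fold
            kept.append(c)
    return kept


def primary_tss(cluster: TSSCluster, cov: StrandedCoverage) -> int:
    """Deepest single-bp position within the cluster on its strand.

    Ties break toward the 5'-most position in the direction of
    transcription (lowest coordinate on +, highest on -).
    """
    pos, counts = cov.arrays(cluster.iv.chrom, cluster.iv.strand)
    i = np.searchsorted(pos, cluster.iv.start, side="left")
    j = np.searchsorted(pos, cluster.iv.end, side="left")
    if i == j:
        raise ValueError(f"cluster {cluster.iv} contains no reads")
    seg_pos, seg_counts = pos[i:j], counts[i:j]
    best = seg_counts.max()
    candidates = seg_pos[seg_counts == best]
    return int(candidates.min() if cluster.iv.strand == "+"
               else candidates.max())


def call_tss(csrna: StrandedCoverage,
             params: Optional[CallerParams] = None) -> List[TSSCluster]:
    """Candidate windows -> local-background filter -> primary TSS.

    Returns clusters sorted by (chrom, start, strand) with stable ids.
    """
    params = params or CallerParams()
    clusters = find_candidate_clusters(csrna, params)
    clusters = local_background_filter(clusters, csrna, params)
    for c in clusters:
        c.tss = primary_tss(c, csrna)
    clusters.sort(key=lambda c: (c.iv.chrom, c.iv.start, c.iv.strand))
    for i, c in enumerate(clusters, 1):
        c.cluster_id = f"TSS{i:06d}"
    return clusters
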