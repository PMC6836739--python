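"""Rule-based annotation of called TSS clusters.

Three orthogonal calls per cluster, all anchored at the single-bp
primary TSS:

* stability — sense-strand total-RNA-seq signal in [-100, +500]
  (transcription-direction, endpoint-inclusive) at >= 2 reads per 10^7
  marks a stable transcript; the vast majority of enhancer RNAs and
  PROMPTs fail this and are classed unstable.
* bidirectionality — csRNA-seq signal on the opposite strand in
  [-500, +100] at >= 2 reads per 10^7 marks divergent initiation.
* genomic feature — promoter (within 500 bp of an annotated gene TSS,
  any strand), else exon, else intron, else intergenic, with the
  promoter-distal flag strictly > 500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .caller import TSSCluster
from .coverage import StrandedCoverage, tss_relative_window
from .iolib import GeneModel

OPPOSITE = {"+": "-", "-": "+"}


@dataclass
class AnnotationParams:
    stability_window: Tuple[int, int] = (-100, 500)
    stability_min: float = 2.0  # reads per 10^7, inclusive
    bidir_window: Tuple[int, int] = (-500, 100)
    bidir_min: float = 2.0      # reads per 10^7, inclusive
    distal_dist: int = 500      # strictly greater-than => distal

    def __post_init__(self) -> None:
        for a, b in (self.stability_window, self.bidir_window):
            if a >= b:
                raise ValueError("annotation windows need a < b")
        if self.stability_min <= 0 or self.bidir_min <= 0:
            raise ValueError("signal minima must be > 0")


def classify_stability(cluster: TSSCluster,
                       rnaseq: Optional[StrandedCoverage],
                       params: Optional[AnnotationParams] = None,
                       ) -> Optional[bool]:
    """Stable iff sense RNA-seq in [-100,+500] >= 2 per 10^7 (inclusive).

    With no RNA-seq library the flag is None (NA in output tables).
    """
    params = params or AnnotationParams()
    if rnaseq is None:
        cluster.stable = None
        return None
    a, b = params.stability_window
    iv = tss_relative_window(cluster.tss, cluster.iv.strand, a, b,
                             cluster.iv.chrom)
    norm = rnaseq.window_count(iv, normalized=True)
    cluster.stable = bool(norm >= params.stability_min)
    return cluster.stable


def classify_bidirectional(cluster: TSSCluster, csrna: StrandedCoverage,
                           params: Optional[AnnotationParams] = None,
                           ) -> bool:
    """Bidirectional iff opposite-strand csRNA in [-500,+100] >= 2 per
    10^7 (inclusive); the window is oriented by the cluster's own strand.
    """
    params = params or AnnotationParams()
    a, b = params.bidir_window
    iv = tss_relative_window(cluster.tss, cluster.iv.strand, a, b,
                             cluster.iv.chrom)
    anti = replace(iv, strand=OPPOSITE[cluster.iv.strand])
    norm = csrna.window_count(anti, normalized=True)
    cluster.bidirectional = bool(norm >= params.bidir_min)
    return cluster.bidirectional


def assign_feature(cluster: TSSCluster, genes: Sequence[GeneModel],
                   params: Optional[AnnotationParams] = None,
                   *, _index: Optional[dict] = None) -> str:
    """Feature class with precedence promoter > exon > intron > intergenic.

    The signed distance runs from the nearest gene TSS (any strand) to
    the cluster's primary TSS, positive downstream of that gene.
    Promoter means |distance| <= distal_dist; the distal flag is the
    strict complement (> distal_dist). An empty gene set yields
    intergenic with distance and distal flag NA.
    """
    params = params or AnnotationParams()
    if not genes:
        cluster.feature_class = "intergenic"
        cluster.nearest_gene = None
        cluster.tss_dist = None
        cluster.distal = None
        return "intergenic"
    idx = _index if _index is not None else build_gene_index(genes)
    chrom = cluster.iv.chrom
    x = cluster.tss
    nearest_gene, nearest_d = None, None
    arr = idx["tss"].get(chrom)
    if arr is not None:
        positions, order = arr
        i = int(np.searchsorted(positions, x))
        for j in (i - 1, i):
            if 0 <= j < positions.size:
                g = genes[order[j]]
                d = abs(int(positions[j]) - x)
                if nearest_d is None or d < nearest_d:
                    nearest_d, nearest_gene = d, g
    if nearest_gene is None:
        cluster.feature_class = "intergenic"
        cluster.nearest_gene = None
        cluster.tss_dist = None
        cluster.distal = None
        return "intergenic"
    signed = x - nearest_gene.tss
    if nearest_gene.strand == "-":
        signed = -signed
    cluster.nearest_gene = nearest_gene.gene_id
    cluster.tss_dist = int(signed)
    cluster.distal = nearest_d > params.distal_dist
    if nearest_d <= params.distal_dist:
        cluster.feature_class = "promoter"
    elif _in_intervals(idx["exon_ivs"].get(chrom), x):
        cluster.feature_class = "exon"
    elif _in_intervals(idx["span_ivs"].get(chrom), x):
        cluster.feature_class = "intron"
    else:
        cluster.feature_class = "intergenic"
    return cluster.feature_class


def _in_intervals(ivs: Optional[Tuple[np.ndarray, np.ndarray]],
                  x: int) -> bool:
    if ivs is None:
        return False
    starts, ends = ivs
    return bool(np.any((starts <= x) & (x < ends)))


def build_gene_index(genes: Sequence[GeneModel]) -> dict:
    """Precomputed lookup structures for annotation over many clusters."""
    tss: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    exon_raw: Dict[str, List[Tuple[int, int]]] = {}
    span_raw: Dict[str, List[Tuple[int, int]]] = {}
    tmp: Dict[str, List[Tuple[int, int]]] = {}
    for gi, g in enumerate(genes):
        tmp.setdefault(g.chrom, []).append((g.tss, gi))
        exon_raw.setdefault(g.chrom, []).extend(
            (e.start, e.end) for e in g.exons)
        span_raw.setdefault(g.chrom, []).append((g.start, g.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        tss[chrom] = (np.asarray([p for p, _ in pairs]),
                      np.asarray([i for _, i in pairs]))

    def _pack(raw: Dict[str, List[Tuple[int, int]]]) -> Dict[str, Tuple]:
        return {chrom: (np.asarray([s for s, _ in ivs]),
                        np.asarray([e for _, e in ivs]))
                for chrom, ivs in raw.items()}

    return {"tss": tss, "exon_ivs": _pack(exon_raw),
            "span_ivs": _pack(span_raw)}


def annotate_clusters(clusters: Sequence[TSSCluster],
                      genes: Optional[Sequence[GeneModel]],
                      csrna: StrandedCoverage,
                      rnaseq: Optional[StrandedCoverage] = None,
                      params: Optional[AnnotationParams] = None,
                      ) -> List[TSSCluster]:
    """Apply all three annotation rules to every cluster in place."""
    params = params or AnnotationParams()
    idx = build_gene_index(genes) if genes else None
    for c in clusters:
        classify_stability(c, rnaseq, params)
        classify_bidirectional(c, csrna, params)
        assign_feature(c, genes or [], params, _index=idx)
    return list(clusters)
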