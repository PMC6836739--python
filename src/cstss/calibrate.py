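"""Input-library integration and semi-supervised enrichment thresholding.

Small-RNA input libraries (or total RNA-seq) contain the degradation
products that produce false-positive TSS calls in degraded samples. Each
candidate cluster gets a pseudocounted csRNA/input enrichment ratio over
its own window; clusters near annotated gene TSSs serve as presumptive
true positives and clusters inside downstream (non-first) exons as
likely false positives. The optimal ratio threshold maximizes the
difference of the two classes' empirical cumulative distributions
(the signed Kolmogorov-Smirnov location), and clusters with ratio
strictly above it are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .caller import TSSCluster
from .coverage import StrandedCoverage
from .iolib import GeneModel

log = logging.getLogger("cstss")

#: Ratio threshold applied when calibration is impossible (no annotation
#: or an empty TP/FP class); mirrors the pervasive twofold convention.
FALLBACK_THRESHOLD = 2.0


class CalibrationError(RuntimeError):
    """Raised when no TP or no FP clusters are available."""


@dataclass
class CalibrationResult:
    threshold: float
    curve: List[Tuple[float, float]]
    n_tp: int
    n_fp: int
    separation: float
    fallback: bool = False


def enrichment_ratio(cluster: TSSCluster,
                     input_cov: StrandedCoverage) -> float:
    """Pseudocounted csRNA/input ratio over the cluster's own window.

    ratio = (csrna_norm + 1) / (input_norm + 1), both per 10^7; stores
    ``input_norm`` and ``ratio`` on the cluster.
    """
    input_norm = float(input_cov.window_count(cluster.iv, normalized=True))
    cluster.input_norm = input_norm
    cluster.ratio = (cluster.csrna_norm + 1.0) / (input_norm + 1.0)
    return cluster.ratio


def partition_tp_fp(clusters: Sequence[TSSCluster],
                    genes: Sequence[GeneModel],
                    promoter_window: int = 500) -> Dict[str, int]:
    """Label clusters TP / FP / UNLABELED for threshold calibration.

    TP: primary TSS within +/- ``promoter_window`` of an annotated gene
    TSS on the same strand. FP: primary TSS inside a non-first exon of a
    same-strand gene and farther than ``promoter_window`` from every
    annotated gene TSS. Everything else is UNLABELED. Labels are stored
    on ``cluster.cal_class``; returns class counts.
    """
    per_cs: Dict[Tuple[str, str], List[int]] = {}
    per_c: Dict[str, List[int]] = {}
    downstream_exons: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for g in genes:
        per_cs.setdefault((g.chrom, g.strand), []).append(g.tss)
        per_c.setdefault(g.chrom, []).append(g.tss)
        for i, e in enumerate(g.exons):
            if i == g.first_exon_index:
                continue
            downstream_exons.setdefault((g.chrom, g.strand), []).append(
                (e.start, e.end))
    per_cs_arr = {k: np.sort(np.asarray(v)) for k, v in per_cs.items()}
    per_c_arr = {k: np.sort(np.asarray(v)) for k, v in per_c.items()}
    exon_arr = {k: sorted(v) for k, v in downstream_exons.items()}

    def _mindist(arr: Optional[np.ndarray], x: int) -> float:
        if arr is None or arr.size == 0:
            return float("inf")
        i = int(np.searchsorted(arr, x))
        best = float("inf")
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                best = min(best, abs(int(arr[j]) - x))
        return best

    counts = {"TP": 0, "FP": 0, "UNLABELED": 0}
    for c in clusters:
        key = (c.iv.chrom, c.iv.strand)
        d_same = _mindist(per_cs_arr.get(key), c.tss)
        if d_same <= promoter_window:
            c.cal_class = "TP"
        else:
            d_any = _mindist(per_c_arr.get(c.iv.chrom), c.tss)
            in_exon = any(s <= c.tss < e for s, e in exon_arr.get(key, []))
            if in_exon and d_any > promoter_window:
                c.cal_class = "FP"
            else:
                c.cal_class = "UNLABELED"
        counts[c.cal_class] += 1
    return counts


def optimal_threshold(tp_ratios: Sequence[float],
                      fp_ratios: Sequence[float],
                      grid: Optional[Sequence[float]] = None,
                      ) -> CalibrationResult:
    """Threshold maximizing F_FP(t) - F_TP(t) over a candidate grid.

    F is the <=-type empirical CDF; the grid defaults to the sorted
    union of all observed ratios; ties resolve to the smallest
    maximizer. The maximum difference is the separation (the signed
    Kolmogorov-Smirnov statistic between the two ratio distributions).
    """
    tp = np.sort(np.asarray(tp_ratios, dtype=float))
    fp = np.sort(np.asarray(fp_ratios, dtype=float))
    if tp.size == 0 or fp.size == 0:
        raise CalibrationError(
            "calibration requires non-empty TP and FP classes "
            f"(got n_tp={tp.size}, n_fp={fp.size})")
    if grid is None:
        grid_arr = np.unique(np.concatenate([tp, fp]))
    else:
        grid_arr = np.asarray(sorted(grid), dtype=float)
    f_fp = np.searchsorted(fp, grid_arr, side="right") / fp.size
    f_tp = np.searchsorted(tp, grid_arr, side="right") / tp.size
    diff = f_fp - f_tp
    best = int(np.argmax(diff))  # argmax returns the first (smallest) max
    sep = float(diff[best])
    if sep <= 0:
        log.warning("optimal_threshold: no separation between TP and FP "
                    "ratio distributions (max D = %.3f)", sep)
    return CalibrationResult(
        threshold=float(grid_arr[best]),
        curve=list(zip(grid_arr.tolist(), diff.tolist())),
        n_tp=int(tp.size), n_fp=int(fp.size),
        separation=sep,
    )


def apply_threshold(clusters: Sequence[TSSCluster],
                    result: CalibrationResult) -> List[TSSCluster]:
    """Keep clusters whose enrichment ratio is strictly above threshold.

    Logs kept/removed counts per calibration class (TP retention and FP
    removal) as machine-parsable lines.
    """
    kept: List[TSSCluster] = []
    tally: Dict[Tuple[str, bool], int] = {}
    for c in clusters:
        if c.ratio is None:
            raise ValueError(f"cluster {c.cluster_id} has no ratio; run "
                             "enrichment_ratio first")
        keep = c.ratio > result.threshold
        tally[(c.cal_class or "UNLABELED", keep)] = \
            tally.get((c.cal_class or "UNLABELED", keep), 0) + 1
        if keep:
            kept.append(c)
    for cls in ("TP", "FP", "UNLABELED"):
        k, r = tally.get((cls, True), 0), tally.get((cls, False), 0)
        if k + r:
            log.info("apply_threshold class=%s kept=%d removed=%d", cls, k, r)
    return kept


def calibrate_threshold(clusters: Sequence[TSSCluster],
                        genes: Optional[Sequence[GeneModel]],
                        promoter_window: int = 500,
                        fallback_threshold: Optional[float] =
                        FALLBACK_THRESHOLD) -> CalibrationResult:
    """Partition clusters and compute the optimal threshold, falling back
    to ``fallback_threshold`` when calibration is impossible.

    Pass ``fallback_threshold=None`` to make an impossible calibration a
    hard :class:`CalibrationError` instead.
    """
    try:
        if genes is None:
            raise CalibrationError("no gene annotation supplied")
        partition_tp_fp(clusters, genes, promoter_window)
        tp = [c.ratio for c in clusters if c.cal_class == "TP"]
        fp = [c.ratio for c in clusters if c.cal_class == "FP"]
        if any(r is None for r in tp + fp):
            raise ValueError("ratios missing; run enrichment_ratio first")
        return optimal_threshold(tp, fp)
    except CalibrationError as exc:
        if fallback_threshold is None:
            raise
        log.warning("calibration impossible (%s); falling back to "
                    "threshold %.3g", exc, fallback_threshold)
        return CalibrationResult(threshold=fallback_threshold, curve=[],
                                 n_tp=0, n_fp=0, separation=float("nan"),
                                 fallback=True)
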