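"""Cross-sample merging, raw count matrices and metaprofiles.

Clusters from several samples are merged into a union of nonredundant
features by single-linkage on primary-TSS distance (same strand, within
150 bp), then quantified as raw same-strand 5'-end counts per sample —
the matrix handed to external differential tools (e.g. DESeq2), together
with a library-size sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import TSSCluster
from .coverage import StrandedCoverage
from .iolib import GenomicInterval


@dataclass
class MergedFeature:
    iv: GenomicInterval
    tss: int                       # primary TSS of the deepest member
    members: Dict[str, List[str]]  # sample label -> member cluster ids
    feature_id: str = ""


def merge_clusters(cluster_sets: Sequence[Sequence[TSSCluster]],
                   max_dist: int = 150) -> List[MergedFeature]:
    """Single-linkage merge of same-strand clusters within ``max_dist``.

    Distance is between primary TSSs (the single-bp anchors); the
    feature span is the union of member spans and the representative TSS
    comes from the deepest member. Deterministic ordering by
    (chrom, start, strand).
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, TSSCluster, int]]] = {}
    for si, cset in enumerate(cluster_sets):
        for c in cset:
            by_key.setdefault((c.iv.chrom, c.iv.strand), []).append(
                (c.tss, c, si))
    features: List[MergedFeature] = []
    for (chrom, strand), rows in by_key.items():
        rows.sort(key=lambda r: (r[0], r[2]))
        chain: List[Tuple[int, TSSCluster, int]] = []
        for row in rows:
            if chain and row[0] - chain[-1][0] > max_dist:
                features.append(_make_feature(chrom, strand, chain))
                chain = []
            chain.append(row)
        if chain:
            features.append(_make_feature(chrom, strand, chain))
    features.sort(key=lambda f: (f.iv.chrom, f.iv.start, f.iv.strand))
    for i, f in enumerate(features, 1):
        f.feature_id = f"MF{i:06d}"
    return features


def _make_feature(chrom: str, strand: str,
                  chain: List[Tuple[int, TSSCluster, int]]) -> MergedFeature:
    start = min(c.iv.start for _, c, _ in chain)
    end = max(c.iv.end for _, c, _ in chain)
    deepest = max(chain, key=lambda r: (r[1].csrna_raw, -r[0]))[1]
    members: Dict[str, List[str]] = {}
    for _, c, si in chain:
        label = c.sample or f"sample{si}"
        members.setdefault(label, []).append(c.cluster_id)
    return MergedFeature(GenomicInterval(chrom, start, end, strand),
                         deepest.tss, members)


def count_features(features: Sequence[MergedFeature],
                   covs: Sequence[StrandedCoverage],
                   ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Raw same-strand 5'-end counts per feature and sample.

    Returns (matrix, library_sizes); rows are feature ids, columns are
    sample labels. Duplicate sample labels are an error.
    """
    labels = [cov.label or f"sample{i}" for i, cov in enumerate(covs)]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    mat = np.zeros((len(features), len(covs)), dtype=np.int64)
    for fi, f in enumerate(features):
        for ci, cov in enumerate(covs):
            mat[fi, ci] = cov.window_count(f.iv, normalized=False)
    df = pd.DataFrame(mat, index=[f.feature_id for f in features],
                      columns=labels)
    df.index.name = "feature_id"
    sizes = {label: cov.library_size for label, cov in zip(labels, covs)}
    return df, sizes


def write_count_matrix(df: pd.DataFrame, sizes: Dict[str, int],
                       matrix_path: str, sizes_path: str) -> None:
    df.to_csv(matrix_path, sep="\t")
    with open(sizes_path, "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for label, n in sizes.items():
            fh.write(f"{label}\t{n}\n")


def metaprofile(anchors: Sequence[Tuple[str, int, str]],
                cov: StrandedCoverage, flank: int, bin_size: int = 1,
                normalized: bool = True,
                per_anchor: bool = False):
    """Average signal around oriented anchors in transcription-direction
    coordinates.

    Parameters
    ----------
    anchors : (chrom, position, strand) triples; minus-strand anchors
        are mirrored so +x is always downstream.
    flank : half-width in bp; must be a multiple of ``bin_size``.
    per_anchor : also return the full anchors x bins matrix (heatmap).

    Returns (bin_start_positions, mean_profile[, matrix]); values are
    per-10^7 normalized when ``normalized``.
    """
    if not anchors:
        raise ValueError("metaprofile requires at least one anchor")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    nbins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    mat = np.zeros((len(anchors), nbins), dtype=float)
    scale = cov.norm_factor() if normalized else 1.0
    for ai, (chrom, pos, strand) in enumerate(anchors):
        for bi, off in enumerate(offsets):
            if strand == "+":
                s, e = pos + off, pos + off + bin_size
            elif strand == "-":
                # bin covering [off, off+bin) downstream on the - strand
                s, e = pos - off - bin_size + 1, pos - off + 1
            else:
                raise ValueError("anchors must be stranded")
            raw = cov.range_count(chrom, strand, max(s, 0), max(e, 0))
            mat[ai, bi] = raw * scale
    profile = mat.mean(axis=0)
    if per_anchor:
        return offsets, profile, mat
    return offsets, profile
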