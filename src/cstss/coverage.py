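"""Strand-specific 5'-end coverage and normalized window quantification.

Counts are stored sparsely as sorted position/count arrays per
(chromosome, strand); behaviour is identical to a dense per-base vector
but scales to large genomes. Normalization is "per 10^7 uniquely aligned
reads": ``norm = raw * 1e7 / library_size``.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .iolib import ChromSizes, DataError, FivePrimeRead, GenomicInterval

NORM_SCALE = 1e7  # reads-per-10^7 reference library size


class StrandedCoverage:
    """Per-chromosome, per-strand counts of read 5' ends.

    Attributes
    ----------
    library_size : number of uniquely aligned reads contributing (the
        per-10^7 normalization denominator).
    label : sample name used in count matrices and logs.
    """

    def __init__(self, data: Dict[Tuple[str, str], Tuple[np.ndarray,
                                                         np.ndarray]],
                 library_size: int, label: str = "",
                 chrom_sizes: Optional[ChromSizes] = None):
        if library_size <= 0:
            raise DataError("empty library: library_size must be > 0")
        self._data = data
        self._cumsums = {key: np.concatenate(([0], np.cumsum(counts)))
                         for key, (pos, counts) in data.items()}
        self.library_size = int(library_size)
        self.label = label
        self.chrom_sizes = chrom_sizes

    # -- construction -----------------------------------------------------

    @classmethod
    def from_reads(cls, reads: Iterable[FivePrimeRead],
                   sizes: Optional[ChromSizes] = None,
                   label: str = "") -> "StrandedCoverage":
        """Accumulate a stream of 5'-end reads into counts."""
        buckets: Dict[Tuple[str, str], List[int]] = {}
        n = 0
        for r in reads:
            if sizes is not None:
                length = sizes.get(r.chrom)
                if length is None:
                    raise DataError(f"unknown chromosome {r.chrom!r}")
                if not (0 <= r.pos5 < length):
                    raise DataError(
                        f"read 5' end {r.chrom}:{r.pos5} outside chromosome "
                        f"(length {length}); clamp upstream")
            buckets.setdefault((r.chrom, r.strand), []).append(r.pos5)
            n += 1
        if n == 0:
            raise DataError("empty library: no reads in input stream")
        return cls.from_position_lists(buckets, n, sizes=sizes, label=label)

    @classmethod
    def from_position_lists(cls, positions: Dict[Tuple[str, str], object],
                            library_size: Optional[int] = None,
                            sizes: Optional[ChromSizes] = None,
                            label: str = "") -> "StrandedCoverage":
        """Build from {(chrom, strand): array-like of 5' positions}."""
        data = {}
        total = 0
        for key, plist in positions.items():
            arr = np.asarray(plist, dtype=np.int64)
            if arr.size == 0:
                continue
            pos, counts = np.unique(arr, return_counts=True)
            data[key] = (pos, counts)
            total += int(arr.size)
        if library_size is None:
            library_size = total
        return cls(data, library_size, label=label, chrom_sizes=sizes)

    # -- accessors --------------------------------------------------------

    def chroms(self) -> List[str]:
        return sorted({chrom for chrom, _ in self._data})

    def arrays(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted distinct 5' positions and their counts."""
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return self._data.get((chrom, strand), empty)

    def total_count(self) -> int:
        return int(sum(int(c.sum()) for _, c in self._data.values()))

    def norm_factor(self) -> float:
        return NORM_SCALE / self.library_size

    # -- quantification ---------------------------------------------------

    def range_count(self, chrom: str, strand: str, start: int,
                    end: int) -> int:
        """Raw 5'-end count on one strand over [start, end)."""
        pos, _counts = self._data.get((chrom, strand), (None, None))
        if pos is None:
            return 0
        cum = self._cumsums[(chrom, strand)]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return int(cum[j] - cum[i])

    def window_count(self, iv: GenomicInterval, normalized: bool = False):
        """Stranded count over an interval, optionally per-10^7.

        The window is clipped to chromosome bounds when sizes are known;
        the out-of-bounds part contributes nothing.
        """
        if iv.strand not in ("+", "-"):
            raise DataError("stranded quantification requires a strand "
                            "('+' or '-'), got '.'")
        start, end = iv.start, iv.end
        if self.chrom_sizes is not None and iv.chrom in self.chrom_sizes:
            end = min(end, self.chrom_sizes[iv.chrom])
        start = max(start, 0)
        if start >= end:
            return 0.0 if normalized else 0
        raw = self.range_count(iv.chrom, iv.strand, start, end)
        return raw * self.norm_factor() if normalized else raw


# ---------------------------------------------------------------------------
# Window arithmetic
# ---------------------------------------------------------------------------

def tss_relative_window(tss_pos: int, strand: str, a: int, b: int,
                        chrom: str = "") -> GenomicInterval:
    """Interval [a, b] around a TSS in transcription-direction coordinates.

    Endpoints are inclusive on both sides (so [-100, +500] spans 601 bp);
    downstream (+b) always points in the direction of transcription of
    ``strand``. The returned interval is unclipped; clipping happens at
    quantification time.
    """
    if a > b:
        raise ValueError(f"need a <= b, got a={a}, b={b}")
    if strand == "+":
        start, end = tss_pos + a, tss_pos + b + 1
    elif strand == "-":
        start, end = tss_pos - b, tss_pos - a + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    # windows reaching past the chromosome start are clipped at zero;
    # the missing part contributes no reads either way
    start = max(start, 0)
    return GenomicInterval(chrom, start, max(end, start + 1), strand)


def log2_ratio(num: float, den: float) -> float:
    """log2 ratio of two per-10^7 counts with a pseudocount of one read
    per 10^7 in numerator and denominator."""
    return math.log2((num + 1.0) / (den + 1.0))
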