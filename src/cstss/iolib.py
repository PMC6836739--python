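"""Genomic file I/O with fixed coordinate conventions.

All internal coordinates are 0-based half-open intervals. GTF input
(1-based inclusive) is converted on read; BED/bedGraph output is written
0-based half-open. Strand-specific data are anchored to the 5' end of
each read: the leftmost aligned base on the + strand, the rightmost on
the - strand.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

log = logging.getLogger("cstss")

#: 3' adapter ligated in capped-small-RNA library construction.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

STRANDS = ("+", "-")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded ('.' = unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def clipped(self, chrom_len: int) -> "GenomicInterval":
        """Clip to [0, chrom_len); raises if nothing remains."""
        s, e = max(self.start, 0), min(self.end, chrom_len)
        if (s, e) == (self.start, self.end):
            return self
        return replace(self, start=s, end=e)


@dataclass(frozen=True)
class FivePrimeRead:
    """An aligned read reduced to its 5'-end position."""

    chrom: str
    strand: str
    pos5: int
    unique: bool = True

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError("FivePrimeRead strand must be '+' or '-'")


@dataclass
class GeneModel:
    """A gene with its 5'-most TSS and merged exon set."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: List[GenomicInterval]
    first_exon_index: int = 0

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class ChromSizes(dict):
    """Mapping chromosome name -> length (bp)."""

    def __setitem__(self, name: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length")
        super().__setitem__(name, int(length))


def read_chrom_sizes(path: str) -> ChromSizes:
    sizes = ChromSizes()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise DataError(f"{path}:{ln}: expected 'name<TAB>length'")
            name, length = fields[0], int(fields[1])
            if name in sizes:
                raise DataError(f"{path}:{ln}: duplicate chromosome {name}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

def _shift_and_clamp(pos5: int, strand: str, offset: int,
                     chrom: str, sizes: Optional[ChromSizes]) -> int:
    # offset is applied along the direction of transcription
    pos5 = pos5 + offset if strand == "+" else pos5 - offset
    if sizes is not None:
        length = sizes.get(chrom)
        if length is None:
            raise DataError(f"unknown chromosome {chrom!r} in alignments")
        pos5 = min(max(pos5, 0), length - 1)
    else:
        pos5 = max(pos5, 0)
    return pos5


def _iter_bed6(path: str, offset: int,
               sizes: Optional[ChromSizes]) -> Iterator[FivePrimeRead]:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{ln}: BED6 needs 6 columns, "
                                f"got {len(fields)}")
            chrom, start, end, _name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: non-integer coordinate") from exc
            if strand not in STRANDS:
                raise DataError(f"{path}:{ln}: strand must be + or -")
            if end_i <= start_i:
                raise DataError(f"{path}:{ln}: end <= start")
            pos5 = start_i if strand == "+" else end_i - 1
            pos5 = _shift_and_clamp(pos5, strand, offset, chrom, sizes)
            yield FivePrimeRead(chrom, strand, pos5)


def _iter_sam(path: str, offset: int, unique_only: bool,
              sizes: Optional[ChromSizes]) -> Iterator[FivePrimeRead]:
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        if sizes is None and af.references:
            sizes = ChromSizes()
            for name, length in zip(af.references, af.lengths):
                sizes[name] = length
        for i, aln in enumerate(af.fetch(until_eof=True), 1):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            unique = (not aln.is_secondary) and aln.mapping_quality > 0
            if unique_only and not unique:
                continue
            strand = "-" if aln.is_reverse else "+"
            pos5 = (aln.reference_end - 1) if aln.is_reverse \
                else aln.reference_start
            if pos5 is None or aln.reference_name is None:
                raise DataError(f"{path}: record {i}: incomplete alignment")
            pos5 = _shift_and_clamp(pos5, strand, offset,
                                    aln.reference_name, sizes)
            yield FivePrimeRead(aln.reference_name, strand, pos5, unique)


def read_alignments(path: str, offset: int = 0, unique_only: bool = True,
                    chrom_sizes: Optional[ChromSizes] = None,
                    ) -> Iterator[FivePrimeRead]:
    """Stream aligned reads as 5'-end positions.

    Parameters
    ----------
    path : SAM/BAM or BED6 file (by extension).
    offset : signed shift in the read's transcription direction, e.g. +75
        for ChIP-seq (nucleosome dyad) or +35 for DNase fragments; 0 for
        csRNA-seq, small-RNA input and RNA-seq.
    unique_only : for SAM/BAM, keep only primary alignments with MAPQ > 0.
        BED input is trusted as already filtered.
    chrom_sizes : optional bounds; shifted positions are clamped into the
        chromosome and unknown chromosomes are an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".bed", ".bed6")):
        yield from _iter_bed6(path, offset, chrom_sizes)
    elif path.endswith((".sam", ".bam")):
        yield from _iter_sam(path, offset, unique_only, chrom_sizes)
    else:
        raise DataError(f"cannot infer alignment format of {path} "
                        "(expected .bed/.bed6/.sam/.bam)")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def merge_intervals(ivs: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of possibly overlapping intervals on one chrom/strand."""
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def read_gtf(path: str) -> List[GeneModel]:
    """Parse gene models from GTF/GFF exon features.

    The gene TSS is the 5'-most position over all transcripts of the
    gene; exons are merged per gene. Genes whose exons span multiple
    chromosomes or strands are skipped (a warning reports the count).
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True,
                            merge_strategy="create_unique")
    by_gene: Dict[str, List[Tuple[str, str, int, int]]] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        # GTF is 1-based inclusive -> 0-based half-open
        by_gene.setdefault(gid, []).append(
            (feat.seqid, feat.strand, feat.start - 1, feat.end))
    genes: List[GeneModel] = []
    skipped = 0
    for gid, rows in by_gene.items():
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) > 1 or len(strands) > 1 or strands & {".", "?"}:
            skipped += 1
            continue
        chrom, strand = rows[0][0], rows[0][1]
        exons = merge_intervals(
            [GenomicInterval(chrom, s, e, strand) for _, _, s, e in rows])
        if strand == "+":
            tss = exons[0].start
            first = 0
        else:
            tss = exons[-1].end - 1
            first = len(exons) - 1
        genes.append(GeneModel(gid, chrom, strand, tss, exons, first))
    if skipped:
        log.warning("read_gtf: skipped %d genes with exons on multiple "
                    "chromosomes/strands", skipped)
    genes.sort(key=lambda g: (g.chrom, g.start, g.strand))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str,
              source: str = "cstss") -> None:
    """Write gene models as GTF (gene/transcript/exon rows, 1-based)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([g.chrom, source, "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".",
                                f'gene_id "{g.gene_id}";']) + "\n")
            fh.write("\t".join([g.chrom, source, "transcript",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                ".", attrs]) + "\n")
            for e in g.exons:
                fh.write("\t".join([g.chrom, source, "exon", str(e.start + 1),
                                    str(e.end), ".", g.strand, ".", attrs])
                         + "\n")


# ---------------------------------------------------------------------------
# Cluster tables
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = [
    "cluster_id", "chrom", "start", "end", "strand", "tss",
    "csrna_raw", "csrna_norm", "input_norm", "ratio", "local_fold",
    "stable", "bidirectional", "distal", "feature_class",
    "nearest_gene", "tss_dist", "sample",
]


def write_clusters(clusters: Sequence, tsv_path: str,
                   bed_path: Optional[str] = None) -> None:
    """Write TSS clusters as a documented TSV plus a BED6 companion.

    Rows are ordered by (chrom, start, strand); missing annotations are
    written as NA. The BED score is the normalized csRNA depth rounded
    to an integer, capped at 1000 per BED convention.
    """
    import pandas as pd

    rows = []
    for c in sorted(clusters, key=lambda c: (c.iv.chrom, c.iv.start,
                                             c.iv.strand)):
        rows.append({
            "cluster_id": c.cluster_id,
            "chrom": c.iv.chrom, "start": c.iv.start, "end": c.iv.end,
            "strand": c.iv.strand, "tss": c.tss,
            "csrna_raw": c.csrna_raw, "csrna_norm": c.csrna_norm,
            "input_norm": c.input_norm, "ratio": c.ratio,
            "local_fold": c.local_fold, "stable": c.stable,
            "bidirectional": c.bidirectional, "distal": c.distal,
            "feature_class": c.feature_class, "nearest_gene": c.nearest_gene,
            "tss_dist": c.tss_dist, "sample": c.sample,
        })
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in rows:
                score = min(1000, int(round(r["csrna_norm"])))
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                         f"{r['cluster_id']}\t{score}\t{r['strand']}\n")


def read_clusters(tsv_path: str) -> List:
    """Re-read a cluster TSV written by :func:`write_clusters`."""
    import pandas as pd

    from .caller import TSSCluster

    df = pd.read_csv(tsv_path, sep="\t", na_values=["NA"],
                     keep_default_na=True, float_precision="round_trip")
    out: List[TSSCluster] = []

    def _opt(v, cast=float):
        if pd.isna(v):
            return None
        if cast is bool and isinstance(v, str):
            return v == "True"
        return cast(v)

    for _, r in df.iterrows():
        out.append(TSSCluster(
            iv=GenomicInterval(str(r.chrom), int(r.start), int(r.end),
                               str(r.strand)),
            tss=int(r.tss),
            csrna_raw=int(r.csrna_raw),
            csrna_norm=float(r.csrna_norm),
            input_norm=_opt(r.input_norm),
            ratio=_opt(r.ratio),
            local_fold=_opt(r.local_fold),
            stable=_opt(r.stable, bool),
            bidirectional=_opt(r.bidirectional, bool),
            distal=_opt(r.distal, bool),
            feature_class=_opt(r.feature_class, str),
            nearest_gene=_opt(r.nearest_gene, str),
            tss_dist=_opt(r.tss_dist, int),
            sample="" if pd.isna(r["sample"]) else str(r["sample"]),
            cluster_id=str(r.cluster_id),
        ))
    return out


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(cov, path_plus: str, path_minus: str,
                   normalized: bool = False) -> None:
    """Write per-strand run-length-encoded bedGraph tracks.

    Zero positions emit no lines; adjacent equal values are merged.
    Normalized values are per 10^7 uniquely aligned reads.
    """
    scale = 1e7 / cov.library_size if normalized else 1.0
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for chrom in cov.chroms():
                positions, counts = cov.arrays(chrom, strand)
                run_start = None
                run_end = None
                run_val = None
                for pos, cnt in zip(positions.tolist(), counts.tolist()):
                    val = cnt * scale
                    if run_val is not None and pos == run_end and \
                            val == run_val:
                        run_end += 1
                        continue
                    if run_val is not None:
                        fh.write(_bg_line(chrom, run_start, run_end, run_val,
                                          normalized))
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_val is not None:
                    fh.write(_bg_line(chrom, run_start, run_end, run_val,
                                      normalized))


def _bg_line(chrom: str, start: int, end: int, val: float,
             normalized: bool) -> str:
    txt = f"{val:g}" if normalized else f"{int(val)}"
    return f"{chrom}\t{start}\t{end}\t{txt}\n"


# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------

def trim_adapter(read_sequence: str, adapter: str = DEFAULT_ADAPTER,
                 min_overlap: int = 4) -> str:
    """Trim the 3' sequencing adapter from a read.

    Removes the read suffix that exactly matches a prefix of the adapter
    with at least ``min_overlap`` bases (a full internal adapter match
    trims from the match start), repeating until no match remains so the
    operation is idempotent. No match leaves the read unchanged.
    """
    seq = read_sequence
    while True:
        n = len(seq)
        cut = None
        for i in range(n):
            k = min(n - i, len(adapter))
            if k < min_overlap:
                break
            if seq[i:i + k] == adapter[:k]:
                cut = i
                break
        if cut is None:
            return seq
        seq = seq[:cut]
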