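"""Format round-trips, coordinate conventions and adapter trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cstss import (DEFAULT_ADAPTER, ChromSizes, DataError, GenomicInterval,
                   TSSCluster, read_alignments, read_chrom_sizes,
                   read_clusters, read_gtf, trim_adapter, write_bedgraph,
                   write_clusters)
from cstss.iolib import merge_intervals, write_chrom_sizes
from conftest import make_cov


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _bed(tmp_path, lines):
    path = tmp_path / "reads.bed"
    path.write_text("".join(line + "\n" for line in lines))
    return str(path)


@pytest.mark.parametrize("line,offset,expected", [
    ("chr1\t100\t125\tr1\t0\t+", 0, ("chr1", "+", 100)),
    ("chr1\t100\t125\tr2\t0\t-", 0, ("chr1", "-", 124)),
    ("chr1\t100\t125\tr3\t0\t-", 35, ("chr1", "-", 89)),
    ("chr1\t100\t125\tr4\t0\t+", 75, ("chr1", "+", 175)),
])
def test_bed_five_prime_end(tmp_path, line, offset, expected):
    """The 5' end is the leftmost base on +, rightmost on -, and the
    offset is applied along the direction of transcription."""
    reads = list(read_alignments(_bed(tmp_path, [line]), offset=offset))
    assert len(reads) == 1
    r = reads[0]
    assert (r.chrom, r.strand, r.pos5) == expected


def test_bed_offset_clamped_to_chromosome(tmp_path):
    sizes = ChromSizes()
    sizes["chr1"] = 200
    path = _bed(tmp_path, ["chr1\t150\t180\tr\t0\t+"])
    (r,) = read_alignments(path, offset=75, chrom_sizes=sizes)
    assert r.pos5 == 199  # 150+75=225 clamped to len-1


def test_bed_unknown_chromosome_fails(tmp_path):
    sizes = ChromSizes()
    sizes["chr1"] = 200
    path = _bed(tmp_path, ["chrX\t10\t40\tr\t0\t+"])
    with pytest.raises(DataError, match="chrX"):
        list(read_alignments(path, chrom_sizes=sizes))


def test_bed_malformed_record_names_line(tmp_path):
    path = _bed(tmp_path, ["chr1\t10\t40\tr\t0\t+", "chr1\t10\t40"])
    with pytest.raises(DataError, match=":2"):
        list(read_alignments(path))


def test_sam_parsing_skips_secondary_and_unmapped(tmp_path):
    sam = "\n".join([
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chr1\tLN:1000",
        # primary + strand, pos 1-based 101 -> 5' end 100
        "r1\t0\tchr1\t101\t60\t25M\t*\t0\t0\t*\t*",
        # reverse strand: reference_end-1 = 101-1+25-1 = 124
        "r2\t16\tchr1\t101\t60\t25M\t*\t0\t0\t*\t*",
        # secondary: skipped
        "r3\t256\tchr1\t201\t60\t25M\t*\t0\t0\t*\t*",
        # unmapped: skipped
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*",
        # MAPQ 0: not unique, dropped under unique_only
        "r5\t0\tchr1\t301\t0\t25M\t*\t0\t0\t*\t*",
    ]) + "\n"
    path = tmp_path / "reads.sam"
    path.write_text(sam)
    reads = list(read_alignments(str(path)))
    assert [(r.strand, r.pos5) for r in reads] == [("+", 100), ("-", 124)]
    all_reads = list(read_alignments(str(path), unique_only=False))
    assert len(all_reads) == 3


def test_strand_symmetry_under_mirroring(tmp_path):
    """Reversing strands and mirroring coordinates around the chromosome
    midpoint mirrors the 5'-end output."""
    L = 1000
    fwd = ["chr1\t100\t125\ta\t0\t+", "chr1\t300\t350\tb\t0\t-"]
    # mirror of interval [s,e) on length L is [L-e, L-s), strand flipped
    mir = ["chr1\t875\t900\ta\t0\t-", "chr1\t650\t700\tb\t0\t+"]
    r_fwd = list(read_alignments(_bed(tmp_path, fwd)))
    (tmp_path / "reads.bed").unlink()
    r_mir = list(read_alignments(_bed(tmp_path, mir)))
    for a, b in zip(r_fwd, r_mir):
        assert b.pos5 == L - 1 - a.pos5
        assert b.strand != a.strand


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf(tmp_path, rows):
    path = tmp_path / "genes.gtf"
    lines = []
    for chrom, start1, end1, strand, gid in rows:
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t";'
        lines.append("\t".join([chrom, "src", "exon", str(start1),
                                str(end1), ".", strand, ".", attrs]))
    path.write_text("".join(l + "\n" for l in lines))
    return str(path)


def test_gtf_plus_strand_tss_and_coordinates(tmp_path):
    (g,) = read_gtf(_gtf(tmp_path, [("chr1", 1001, 2000, "+", "g1")]))
    assert g.tss == 1000  # GTF 1-based -> 0-based
    assert g.exons[0].start == 1000 and g.exons[0].end == 2000


def test_gtf_minus_strand_tss_is_five_prime_most(tmp_path):
    g, = read_gtf(_gtf(tmp_path, [
        ("chr1", 3000, 5000, "-", "g1"),
        ("chr1", 3000, 5200, "-", "g1"),
    ]))
    assert g.tss == 5199
    assert g.first_exon_index == len(g.exons) - 1


def test_gtf_overlapping_exons_merged(tmp_path):
    (g,) = read_gtf(_gtf(tmp_path, [
        ("chr1", 101, 200, "+", "g1"),
        ("chr1", 151, 300, "+", "g1"),
    ]))
    assert len(g.exons) == 1
    assert (g.exons[0].start, g.exons[0].end) == (100, 300)


def test_gtf_multichrom_gene_skipped(tmp_path):
    genes = read_gtf(_gtf(tmp_path, [
        ("chr1", 101, 200, "+", "bad"),
        ("chr2", 101, 200, "+", "bad"),
        ("chr1", 501, 900, "+", "ok"),
    ]))
    assert [g.gene_id for g in genes] == ["ok"]


def test_merge_intervals_union():
    ivs = [GenomicInterval("c", 100, 200), GenomicInterval("c", 150, 300),
           GenomicInterval("c", 400, 500)]
    merged = merge_intervals(ivs)
    assert [(m.start, m.end) for m in merged] == [(100, 300), (400, 500)]


# ---------------------------------------------------------------------------
# cluster tables
# ---------------------------------------------------------------------------

def _cluster(chrom="chr1", start=500, end=650, strand="+", tss=540,
             **kw):
    defaults = dict(csrna_raw=50, csrna_norm=50.0, cluster_id="TSS000001")
    defaults.update(kw)
    return TSSCluster(iv=GenomicInterval(chrom, start, end, strand),
                      tss=tss, **defaults)


def test_write_clusters_empty(tmp_path):
    tsv, bed = str(tmp_path / "c.tsv"), str(tmp_path / "c.bed")
    write_clusters([], tsv, bed)
    assert len(open(tsv).readlines()) == 1  # header only
    assert open(bed).read() == ""


def test_write_clusters_bed_line(tmp_path):
    tsv, bed = str(tmp_path / "c.tsv"), str(tmp_path / "c.bed")
    write_clusters([_cluster()], tsv, bed)
    assert open(bed).read() == "chr1\t500\t650\tTSS000001\t50\t+\n"
    assert "\t540\t" in open(tsv).readlines()[1]


def test_cluster_round_trip(tmp_path):
    clusters = [
        _cluster(),
        _cluster(chrom="chr2", start=10, end=160, strand="-", tss=100,
                 cluster_id="TSS000002", input_norm=3.5, ratio=2.25,
                 local_fold=8.0, stable=False, bidirectional=True,
                 distal=True, feature_class="intergenic",
                 nearest_gene="g1", tss_dist=-1200, sample="s1"),
    ]
    tsv = str(tmp_path / "c.tsv")
    write_clusters(clusters, tsv)
    back = read_clusters(tsv)
    assert len(back) == 2
    for orig in clusters:
        match = [b for b in back if b.cluster_id == orig.cluster_id][0]
        assert match == orig


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def test_bedgraph_raw_and_rle(tmp_path):
    cov = make_cov({("chr1", "+"): [1000, 1000, 1000, 1001, 1001, 1001,
                                    2000]})
    p, m = str(tmp_path / "p.bg"), str(tmp_path / "m.bg")
    write_bedgraph(cov, p, m)
    assert open(p).read() == "chr1\t1000\t1002\t3\nchr1\t2000\t2001\t1\n"
    assert open(m).read() == ""  # zero positions emit no lines


def test_bedgraph_normalized_per_1e7(tmp_path):
    cov = make_cov({("chr1", "+"): [1000, 1000, 1000]},
                   library_size=20_000_000)
    p, m = str(tmp_path / "p.bg"), str(tmp_path / "m.bg")
    write_bedgraph(cov, p, m, normalized=True)
    assert open(p).read() == "chr1\t1000\t1001\t1.5\n"


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------

def test_chrom_sizes_round_trip(tmp_path):
    sizes = ChromSizes()
    sizes["chr1"] = 1000
    sizes["chr2"] = 500
    path = str(tmp_path / "genome.chrom.sizes")
    write_chrom_sizes(sizes, path)
    assert read_chrom_sizes(path) == sizes


def test_chrom_sizes_rejects_nonpositive():
    sizes = ChromSizes()
    with pytest.raises(ValueError):
        sizes["chr1"] = 0


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,kwargs,expected", [
    ("ACGT" + DEFAULT_ADAPTER, {}, "ACGT"),
    ("ACGTACGT", {}, "ACGTACGT"),
    ("ACGTAGATC", {"min_overlap": 5}, "ACGT"),
    ("ACGT" + DEFAULT_ADAPTER + "TTTT", {}, "ACGT"),  # internal match
    ("AGA", {}, "AGA"),  # below min_overlap
])
def test_trim_adapter(seq, kwargs, expected):
    assert trim_adapter(seq, **kwargs) == expected


def test_trim_adapter_matches_exhaustive_scan():
    """Against a brute-force suffix/prefix scan on short random reads."""
    rng = np.random.default_rng(0)
    alphabet = "ACGT"
    adapter = DEFAULT_ADAPTER

    def scan_once(seq, min_overlap):
        for i in range(len(seq)):
            k = min(len(seq) - i, len(adapter))
            if k >= min_overlap and seq[i:i + k] == adapter[:k]:
                return seq[:i]
        return seq

    def oracle(seq, min_overlap):
        # trimming can expose a shorter terminal adapter prefix; repeat
        # the scan to the fixpoint
        while True:
            out = scan_once(seq, min_overlap)
            if out == seq:
                return out
            seq = out

    for _ in range(300):
        n = int(rng.integers(0, 30))
        seq = "".join(alphabet[i] for i in rng.integers(0, 4, n))
        if rng.random() < 0.5:
            cut = int(rng.integers(1, len(adapter) + 1))
            seq += adapter[:cut]
        assert trim_adapter(seq, min_overlap=4) == oracle(seq, 4)


@given(st.text(alphabet="ACGTN", max_size=80),
       st.integers(min_value=1, max_value=10))
@settings(max_examples=200, deadline=None)
def test_trim_adapter_idempotent(seq, min_overlap):
    once = trim_adapter(seq, min_overlap=min_overlap)
    assert trim_adapter(once, min_overlap=min_overlap) == once
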