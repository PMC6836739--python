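"""Synthetic genome, annotation and read sets with planted ground truth.

The generator emulates the signal structure a capped-small-RNA
experiment sees:

* csRNA-seq — read 5' ends concentrated at planted TSSs (discretized
  Gaussian scatter), a 1% uniform genomic noise floor, and a small
  cap-selection leakage of exon-body degradation fragments that grows
  with the RNA-degradation knob (the mechanism that makes the input
  library informative).
* small-RNA input — the same TSS signal mixed with exon-body
  degradation reads from stable, expressed genes; the degradation
  fraction is the RNA-quality knob (RIN analogue).
* total RNA-seq — gene-body coverage for stable transcripts only, so
  enhancer RNAs, PROMPTs and unstable promoters are RNA-seq dark.

Planted loci are stable/unstable promoters (with optional divergent
PROMPTs), and intergenic enhancers (optionally bidirectional). Every
locus is recorded in a truth table carrying its expected stability and
bidirectionality flags. All randomness flows from ``SimConfig.seed``;
outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coverage import StrandedCoverage
from .iolib import ChromSizes, GeneModel, GenomicInterval

_SLOT = 50_000          # placement grid keeping loci >= ~20 kb apart
_PROMPT_DIST = (150, 400)   # PROMPT upstream-antisense offset range (bp)
_ENH_PAIR_DIST = (110, 250)  # divergent enhancer pair separation (bp)


@dataclass
class SimConfig:
    """Study conditions for the planted-truth simulation.

    Depths and genome size are scaled so that the published per-10^7
    thresholds translate into meaningful raw-read requirements (the
    7-per-10^7 depth floor is ~4 raw reads, the 2-per-10^7 stability /
    bidirectionality minima are 2 raw reads) while a 1% uniform noise
    floor stays below them, mirroring the read-depth-to-genome-size
    ratio of a real experiment.
    """

    seed: int = 42
    n_chroms: int = 4
    chrom_len: int = 30_000_000
    n_genes: int = 40
    n_enhancers: int = 15
    frac_stable_promoters: float = 0.6
    tss_spread_sd: float = 2.0
    depth_csrna: int = 6_000_000
    depth_input: int = 6_000_000
    depth_rnaseq: int = 6_000_000
    degradation_level: float = 0.5
    prompt_rate: float = 0.3
    enhancer_bidir_rate: float = 0.8
    noise_frac: float = 0.01
    capture_leak: float = 0.005  # csRNA degradation carryover per unit knob

    def __post_init__(self) -> None:
        for name in ("frac_stable_promoters", "degradation_level",
                     "prompt_rate", "enhancer_bidir_rate", "noise_frac",
                     "capture_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.depth_csrna, self.depth_input, self.depth_rnaseq) <= 0:
            raise ValueError("depths must be > 0")
        if self.tss_spread_sd < 0:
            raise ValueError("tss_spread_sd must be >= 0")

    def chrom_sizes(self) -> ChromSizes:
        sizes = ChromSizes()
        for i in range(self.n_chroms):
            sizes[f"chr{i + 1}"] = self.chrom_len
        return sizes

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TruthRecord:
    locus_id: str
    kind: str        # stable_promoter | unstable_promoter | enhancer | prompt
    chrom: str
    tss: int
    strand: str
    rate: float
    expected_stable: bool
    expected_bidirectional: bool

    def __post_init__(self) -> None:
        if self.kind in ("enhancer", "prompt") and self.expected_stable:
            raise ValueError(f"{self.kind} loci cannot be stable")


class SimReads:
    """Positional reads of one simulated library."""

    def __init__(self, positions: Dict[Tuple[str, str], np.ndarray],
                 label: str):
        self.positions = positions
        self.label = label
        self.n = int(sum(int(a.size) for a in positions.values()))

    def to_coverage(self, sizes: ChromSizes) -> StrandedCoverage:
        return StrandedCoverage.from_position_lists(
            self.positions, self.n, sizes=sizes, label=self.label)

    def to_bed(self, path: str, seed: int = 0,
               length_range: Tuple[int, int] = (20, 60)) -> None:
        """Write reads as BED6; lengths drawn uniformly per read."""
        rng = np.random.default_rng([seed, 97])
        with open(path, "w") as fh:
            for (chrom, strand) in sorted(self.positions):
                pos = self.positions[(chrom, strand)]
                lens = rng.integers(length_range[0], length_range[1] + 1,
                                    size=pos.size)
                for i, (p, ln) in enumerate(zip(pos.tolist(),
                                                lens.tolist())):
                    if strand == "+":
                        s, e = p, p + ln
                    else:
                        s, e = max(0, p - ln + 1), p + 1
                    fh.write(f"{chrom}\t{s}\t{e}\t{self.label}_{i}\t0\t"
                             f"{strand}\n")


# ---------------------------------------------------------------------------
# Annotation / truth
# ---------------------------------------------------------------------------

def make_annotation(cfg: SimConfig,
                    ) -> Tuple[List[GeneModel], List[TruthRecord],
                               ChromSizes]:
    """Place genes, enhancers and PROMPTs on a fresh genome.

    Loci occupy distinct 50-kb slots, which keeps every pair of planted
    loci far beyond all quantification windows; divergent partners
    (PROMPTs, enhancer pairs) share a slot by construction.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    sizes = cfg.chrom_sizes()
    slots = [(chrom, s) for chrom in sizes
             for s in range(0, sizes[chrom] - _SLOT + 1, _SLOT)]
    n_loci = cfg.n_genes + cfg.n_enhancers
    if n_loci > len(slots):
        raise ValueError(
            f"cannot place {n_loci} loci in {len(slots)} slots; increase "
            "chrom_len or n_chroms")
    order = rng.permutation(len(slots))[:n_loci]
    genes: List[GeneModel] = []
    truth: List[TruthRecord] = []

    n_stable = int(round(cfg.frac_stable_promoters * cfg.n_genes))
    stable_mask = np.zeros(cfg.n_genes, dtype=bool)
    stable_mask[rng.permutation(cfg.n_genes)[:n_stable]] = True

    for gi in range(cfg.n_genes):
        chrom, slot_start = slots[order[gi]]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(slot_start + rng.integers(22_000, 28_000))
        exons = _make_exons(rng, chrom, strand, tss)
        gene_id = f"gene{gi + 1:03d}"
        first = 0 if strand == "+" else len(exons) - 1
        genes.append(GeneModel(gene_id, chrom, strand, tss, exons, first))
        rate = float(rng.lognormal(0.0, 1.0))
        stable = bool(stable_mask[gi])
        has_prompt = rng.random() < cfg.prompt_rate
        truth.append(TruthRecord(
            gene_id, "stable_promoter" if stable else "unstable_promoter",
            chrom, tss, strand, rate, stable, has_prompt))
        if has_prompt:
            d = int(rng.integers(*_PROMPT_DIST))
            p_tss = tss - d if strand == "+" else tss + d
            truth.append(TruthRecord(
                f"{gene_id}_prompt", "prompt", chrom, p_tss,
                "-" if strand == "+" else "+",
                rate * 0.2, False, True))

    for ei in range(cfg.n_enhancers):
        chrom, slot_start = slots[order[cfg.n_genes + ei]]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(slot_start + rng.integers(22_000, 28_000))
        rate = float(rng.lognormal(0.0, 1.0)) * 0.3
        bidir = rng.random() < cfg.enhancer_bidir_rate
        eid = f"enh{ei + 1:03d}"
        truth.append(TruthRecord(eid, "enhancer", chrom, tss, strand,
                                 rate, False, bidir))
        if bidir:
            d = int(rng.integers(*_ENH_PAIR_DIST))
            p_tss = tss - d if strand == "+" else tss + d
            truth.append(TruthRecord(
                f"{eid}_b", "enhancer", chrom, p_tss,
                "-" if strand == "+" else "+",
                rate * float(rng.uniform(0.5, 1.0)), False, True))
    return genes, truth, sizes


def _make_exons(rng: np.random.Generator, chrom: str, strand: str,
                tss: int) -> List[GenomicInterval]:
    n_ex = int(rng.integers(2, 6))
    ex_lens = rng.integers(300, 1501, size=n_ex)
    in_lens = rng.integers(800, 3001, size=n_ex - 1)
    exons = []
    cursor = tss
    for i in range(n_ex):
        if strand == "+":
            exons.append(GenomicInterval(chrom, cursor,
                                         cursor + int(ex_lens[i]), strand))
            cursor += int(ex_lens[i])
            if i < n_ex - 1:
                cursor += int(in_lens[i])
        else:
            exons.append(GenomicInterval(chrom, cursor - int(ex_lens[i]) + 1,
                                         cursor + 1, strand))
            cursor -= int(ex_lens[i])
            if i < n_ex - 1:
                cursor -= int(in_lens[i])
    exons.sort(key=lambda e: e.start)
    return exons


def write_truth(truth: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tkind\tchrom\ttss\tstrand\trate\t"
                 "expected_stable\texpected_bidirectional\n")
        for t in truth:
            fh.write(f"{t.locus_id}\t{t.kind}\t{t.chrom}\t{t.tss}\t"
                     f"{t.strand}\t{t.rate!r}\t{t.expected_stable}\t"
                     f"{t.expected_bidirectional}\n")


def read_truth(path: str) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            (lid, kind, chrom, tss, strand, rate, stable,
             bidir) = line.rstrip("\n").split("\t")
            out.append(TruthRecord(lid, kind, chrom, int(tss), strand,
                                   float(rate), stable == "True",
                                   bidir == "True"))
    return out


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _collect(buckets: Dict[Tuple[str, str], List[np.ndarray]],
             key: Tuple[str, str], arr: np.ndarray) -> None:
    if arr.size:
        buckets.setdefault(key, []).append(arr)


def _finish(buckets: Dict[Tuple[str, str], List[np.ndarray]],
            label: str) -> SimReads:
    return SimReads({k: np.concatenate(v) for k, v in buckets.items()},
                    label)


def _tss_signal(rng: np.random.Generator, cfg: SimConfig,
                truth: Sequence[TruthRecord], n: int,
                buckets: Dict) -> None:
    rates = np.asarray([t.rate for t in truth], dtype=float)
    counts = rng.multinomial(n, rates / rates.sum())
    for t, k in zip(truth, counts):
        if k == 0:
            continue
        scatter = np.rint(rng.normal(0.0, cfg.tss_spread_sd, size=int(k)))
        pos = np.clip(t.tss + scatter.astype(np.int64), 0,
                      cfg.chrom_len - 1)
        _collect(buckets, (t.chrom, t.strand), pos)


def _uniform_noise(rng: np.random.Generator, cfg: SimConfig, n: int,
                   buckets: Dict) -> None:
    chrom_idx = rng.integers(0, cfg.n_chroms, size=n)
    pos = rng.integers(0, cfg.chrom_len, size=n)
    strands = rng.integers(0, 2, size=n)
    for ci in range(cfg.n_chroms):
        for si, strand in enumerate(("+", "-")):
            sel = (chrom_idx == ci) & (strands == si)
            _collect(buckets, (f"chr{ci + 1}", strand), pos[sel])


class _ExonSampler:
    """Rate-weighted uniform sampling over stable genes' exon bodies."""

    def __init__(self, truth: Sequence[TruthRecord],
                 genes: Sequence[GeneModel]):
        by_id = {g.gene_id: g for g in genes}
        self.genes: List[GeneModel] = []
        rates = []
        for t in truth:
            if t.kind == "stable_promoter":
                self.genes.append(by_id[t.locus_id])
                rates.append(t.rate)
        self.rates = np.asarray(rates, dtype=float)

    @property
    def empty(self) -> bool:
        return not self.genes

    def sample(self, rng: np.random.Generator, n: int,
               buckets: Dict) -> None:
        counts = rng.multinomial(n, self.rates / self.rates.sum())
        for g, k in zip(self.genes, counts):
            if k == 0:
                continue
            seg_lens = np.asarray([len(e) for e in g.exons])
            offs = rng.integers(0, int(seg_lens.sum()), size=int(k))
            seg = np.searchsorted(np.cumsum(seg_lens), offs, side="right")
            starts = np.asarray([e.start for e in g.exons])
            seg_off = offs - np.concatenate(([0],
                                             np.cumsum(seg_lens)))[seg]
            _collect(buckets, (g.chrom, g.strand), starts[seg] + seg_off)


def simulate_csrna(cfg: SimConfig, truth: Sequence[TruthRecord],
                   genes: Optional[Sequence[GeneModel]] = None) -> SimReads:
    """csRNA-seq: TSS signal + 1% uniform noise + degradation carryover.

    The carryover fraction is ``capture_leak * degradation_level`` of
    reads, drawn from the same exon-body distribution as the input
    library's degradation component (cap selection is not perfect, and
    the worse the RNA the more degradation fragments slip through).
    Omit ``genes`` to disable the carryover term.
    """
    rng = np.random.default_rng([cfg.seed, 23])
    n = cfg.depth_csrna
    n_noise = int(round(cfg.noise_frac * n))
    sampler = None
    if genes is not None:
        sampler = _ExonSampler(truth, genes)
        if sampler.empty:
            sampler = None
    n_leak = int(round(cfg.capture_leak * cfg.degradation_level * n)) \
        if sampler is not None else 0
    buckets: Dict[Tuple[str, str], List[np.ndarray]] = {}
    _tss_signal(rng, cfg, truth, n - n_noise - n_leak, buckets)
    _uniform_noise(rng, cfg, n_noise, buckets)
    if n_leak:
        sampler.sample(rng, n_leak, buckets)
    return _finish(buckets, "csrna")


def simulate_input(cfg: SimConfig, truth: Sequence[TruthRecord],
                   genes: Sequence[GeneModel]) -> SimReads:
    """Small-RNA input: (1 - degradation_level) TSS-like reads plus
    degradation_level exon-body reads from stable, expressed genes."""
    rng = np.random.default_rng([cfg.seed, 37])
    n = cfg.depth_input
    sampler = _ExonSampler(truth, genes)
    n_deg = int(round(cfg.degradation_level * n)) if not sampler.empty else 0
    n_rest = n - n_deg
    n_noise = int(round(cfg.noise_frac * n_rest))
    buckets: Dict[Tuple[str, str], List[np.ndarray]] = {}
    _tss_signal(rng, cfg, truth, n_rest - n_noise, buckets)
    _uniform_noise(rng, cfg, n_noise, buckets)
    if n_deg:
        sampler.sample(rng, n_deg, buckets)
    return _finish(buckets, "input")


def simulate_rnaseq(cfg: SimConfig, truth: Sequence[TruthRecord],
                    genes: Sequence[GeneModel]) -> SimReads:
    """Total RNA-seq: 5' ends uniform over stable gene bodies
    (rate-weighted) plus the 1% noise floor; unstable loci are dark."""
    rng = np.random.default_rng([cfg.seed, 53])
    n = cfg.depth_rnaseq
    n_noise = int(round(cfg.noise_frac * n))
    buckets: Dict[Tuple[str, str], List[np.ndarray]] = {}
    by_id = {g.gene_id: g for g in genes}
    stable = [(by_id[t.locus_id], t.rate) for t in truth
              if t.kind == "stable_promoter"]
    n_sig = n - n_noise if stable else 0
    if stable:
        rates = np.asarray([r for _, r in stable])
        counts = rng.multinomial(n_sig, rates / rates.sum())
        for (g, _), k in zip(stable, counts):
            if k == 0:
                continue
            pos = rng.integers(g.start, g.end, size=int(k))
            _collect(buckets, (g.chrom, g.strand), pos)
    _uniform_noise(rng, cfg, n - n_sig, buckets)
    return _finish(buckets, "rnaseq")


# ---------------------------------------------------------------------------
# Expectations used by recovery scoring
# ---------------------------------------------------------------------------

def expected_norm_depth(t: TruthRecord, truth: Sequence[TruthRecord],
                        cfg: SimConfig) -> float:
    """Expected csRNA cluster depth of a planted locus, per 10^7 reads."""
    total = sum(x.rate for x in truth)
    signal_frac = (1.0 - cfg.noise_frac
                   - cfg.capture_leak * cfg.degradation_level)
    return t.rate / total * signal_frac * 1e7
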