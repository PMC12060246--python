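"""Per-contig and per-assembly statistics.

The quantities here are the axes of a standard post-assembly triage plot:
GC content, read depth at two mapping-quality strata, the fraction of
distinct 21-mers occurring exactly once (low values flag collapsed
repeats), telomere-motif enrichment, masked fraction, and the usual
contiguity metrics (N50 / NG50 / L50).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from .annotation import AnnotationIndex

TELOMERE_MOTIF = "TTAGGG"


@dataclass
class ContigStats:
    contig_id: str
    length: int
    gc: float
    depth_all: float
    depth_hq: float
    unique_kmer_fraction: float
    telomere_count: int
    telomere_enrichment: float
    masked_fraction: float


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_length: int
    min_len: int
    max_len: int
    n50: int
    ng50: int | None
    l50: int
    genome_size_assumed: int | None


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases; NaN if no ACGT base present.

    N and other ambiguity codes are excluded from both numerator and
    denominator; case-insensitive.
    """
    if not sequence:
        raise ValueError("empty sequence")
    up = sequence.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def unique_kmer_fraction(sequence: str, k: int = 21, canonical: bool = True) -> float:
    """Fraction of distinct (canonical) k-mers present exactly once.

    A pure tandem repeat with period < k tends to 0 with length; a sequence
    with all-distinct k-mers gives 1.0. k-mers containing non-ACGT bases
    are skipped; NaN if no valid k-mer exists.
    """
    codes = _kmers.kmer_codes(sequence, k, canonical=canonical)
    if len(codes) == 0:
        return math.nan
    _, counts = np.unique(codes, return_counts=True)
    return float(np.count_nonzero(counts == 1) / len(counts))


def telomere_stats(
    sequence: str, motif: str = TELOMERE_MOTIF, assembly_baseline: float | None = None
) -> tuple[int, float]:
    """Motif occurrences (both strands, non-overlapping) and fold enrichment.

    Enrichment is the per-bp motif density over ``assembly_baseline``
    (motifs/bp). 0 when both are 0; inf when the baseline is 0 but the
    motif occurs.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not motif:
        raise ValueError("empty motif")
    up = sequence.upper()
    count = up.count(motif.upper()) + up.count(_kmers.revcomp(motif).upper())
    if assembly_baseline is None:
        return count, math.nan
    if assembly_baseline < 0:
        raise ValueError("baseline must be >= 0")
    density = count / len(sequence)
    if assembly_baseline == 0:
        return count, (0.0 if count == 0 else math.inf)
    return count, density / assembly_baseline


def masked_fraction(sequence: str) -> float:
    """Fraction of bases that are N/n or soft-masked (lowercase acgt)."""
    if not sequence:
        raise ValueError("empty sequence")
    masked = sum(sequence.count(c) for c in "Nnacgt")
    return masked / len(sequence)


def depth_from_intervals(
    starts: np.ndarray, ends: np.ndarray, contig_length: int
) -> tuple[float, float]:
    """Median and mean per-base depth from 0-based half-open read intervals.

    Uncovered bases count as 0; the median of an even count is the mean of
    the central pair.
    """
    cov = np.zeros(contig_length + 1, dtype=np.int64)
    starts = np.clip(np.asarray(starts, dtype=np.int64), 0, contig_length)
    ends = np.clip(np.asarray(ends, dtype=np.int64), 0, contig_length)
    np.add.at(cov, starts, 1)
    np.add.at(cov, ends, -1)
    depth = np.cumsum(cov[:-1])
    return float(np.median(depth)), float(depth.mean())


def _read_filter(aln) -> bool:
    return not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)


def depth_profile(alignments, contig: str, mapq_min: int = 20,
                  contig_length: int | None = None) -> tuple[float, float]:
    """Median and mean depth on *contig* from alignments with MAPQ > mapq_min.

    ``alignments`` is a SAM path, a ``pysam.AlignmentFile`` or an object
    with ``read_intervals(contig, mapq_min)`` (e.g. the synthetic
    ``AlignmentSet``). Only primary, non-supplementary alignments count;
    the MAPQ inequality is strict.
    """
    if hasattr(alignments, "read_intervals"):
        length = contig_length or alignments.contig_lengths[contig]
        starts, ends = alignments.read_intervals(contig, mapq_min)
        return depth_from_intervals(starts, ends, length)

    import pysam

    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if contig not in af.references:
            raise ValueError(f"contig {contig!r} absent from SAM header")
        length = contig_length or af.get_reference_length(contig)
        starts, ends = [], []
        for aln in af.fetch(contig) if af.has_index() else af:
            if af.has_index() or aln.reference_name == contig:
                if _read_filter(aln) and aln.mapping_quality > mapq_min:
                    starts.append(aln.reference_start)
                    ends.append(aln.reference_end)
        return depth_from_intervals(np.asarray(starts), np.asarray(ends), length)
    finally:
        if own:
            af.close()


def assembly_metrics(lengths: Sequence[int], genome_size_assumed: int | None = None) -> AssemblyMetrics:
    """Contiguity metrics. NG50 is None when the assembly is shorter than
    half the assumed genome size."""
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("empty length list")
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be > 0")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    cum = np.cumsum(desc)
    i50 = int(np.searchsorted(cum, total / 2))
    n50 = desc[i50]
    ng50 = None
    if genome_size_assumed is not None:
        half_g = genome_size_assumed / 2
        if total >= half_g:
            ng50 = desc[int(np.searchsorted(cum, half_g))]
    return AssemblyMetrics(
        n_contigs=len(desc), total_length=total, min_len=desc[-1], max_len=desc[0],
        n50=n50, ng50=ng50, l50=i50 + 1, genome_size_assumed=genome_size_assumed,
    )


@dataclass
class AnnotationSummary:
    genome_length: int
    n_genes: int
    n_exons: int
    n_introns: int
    exonic_bp: int
    intronic_bp: int
    intergenic_bp: int
    exonic_fraction: float
    intronic_fraction: float
    genic_fraction: float
    intergenic_fraction: float
    mean_gene_length: float
    mean_exon_length: float
    mean_intron_length: float


def annotation_summary(index: AnnotationIndex, genome_length: int | None = None) -> AnnotationSummary:
    """Genome-fraction accounting over an annotation index.

    Exonic bp is the union of exon intervals; intronic bp is the gene-span
    union minus the exon union; the three fractions sum to 1.
    """
    genome_length = genome_length or index.genome_length
    exonic = index.exonic_bp()
    intronic = index.intronic_bp()
    genic = index.genic_bp()
    exon_lens = [e - s + 1 for g in index.genes for s, e in g.exons]
    intron_lens = []
    for g in index.genes:
        exons = sorted(g.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                intron_lens.append(s2 - e1 - 1)
    return AnnotationSummary(
        genome_length=genome_length,
        n_genes=len(index.genes),
        n_exons=len(exon_lens),
        n_introns=len(intron_lens),
        exonic_bp=exonic,
        intronic_bp=intronic,
        intergenic_bp=genome_length - genic,
        exonic_fraction=exonic / genome_length,
        intronic_fraction=intronic / genome_length,
        genic_fraction=genic / genome_length,
        intergenic_fraction=(genome_length - genic) / genome_length,
        mean_gene_length=float(np.mean([g.length for g in index.genes])) if index.genes else 0.0,
        mean_exon_length=float(np.mean(exon_lens)) if exon_lens else 0.0,
        mean_intron_length=float(np.mean(intron_lens)) if intron_lens else 0.0,
    )


def compute_contig_stats(
    sequences: Mapping[str, str],
    alignments=None,
    k: int = 21,
    mapq_min: int = 20,
    motif: str = TELOMERE_MOTIF,
) -> pd.DataFrame:
    """One ContigStats row per contig, as a DataFrame.

    The telomere baseline is the motif density over the whole assembly
    (both strands), computed first so per-contig enrichments are relative
    to it.
    """
    total_bp = sum(len(s) for s in sequences.values())
    total_motifs = 0
    counts = {}
    for name, seq in sequences.items():
        c, _ = telomere_stats(seq, motif, assembly_baseline=None)
        counts[name] = c
        total_motifs += c
    baseline = total_motifs / total_bp if total_bp else 0.0

    rows = []
    for name, seq in sequences.items():
        if alignments is not None:
            d_all = depth_profile(alignments, name, mapq_min=-1, contig_length=len(seq))[0]
            d_hq = depth_profile(alignments, name, mapq_min=mapq_min, contig_length=len(seq))[0]
        else:
            d_all = d_hq = math.nan
        _, enrich = telomere_stats(seq, motif, assembly_baseline=baseline)
        rows.append(ContigStats(
            contig_id=name,
            length=len(seq),
            gc=gc_content(seq),
            depth_all=d_all,
            depth_hq=d_hq,
            unique_kmer_fraction=unique_kmer_fraction(seq, k) if len(seq) >= k else math.nan,
            telomere_count=counts[name],
            telomere_enrichment=enrich,
            masked_fraction=masked_fraction(seq),
        ))
    return pd.DataFrame([asdict(r) for r in rows])


def write_metrics_json(metrics: AssemblyMetrics, path: str) -> None:
    Path(path).write_text(json.dumps(asdict(metrics), indent=2) + "\n")
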