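"""Dual-caller variant consensus and distributional analyses.

Re-implements the consensus workflow used on long-read diploid call sets:
normalize both call sets (split multiallelics, trim, left-align indels),
find each caller's quality dip (callers emit a bimodal quality mixture of
error-mode and true-mode calls), filter above it, intersect on
(contig, pos, ref, alt), then partition the retained calls by annotation
(exon / intron / intergenic), analyse indel reading-frame effects, and
summarise SNP density by contig class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotationIndex, REGIONS
from .contig_stats import AnnotationSummary

logger = logging.getLogger(__name__)

VTYPES = ("snv", "ins", "del")


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotype: str = "0/1"
    phase_set: int | None = None

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        return "ins" if len(self.alt) > len(self.ref) else "del"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_het(self) -> bool:
        g = self.genotype.replace("|", "/")
        alleles = g.split("/")
        return len(set(alleles)) > 1

    @property
    def anchor_pos(self) -> int:
        """Position of the first altered base (after normalization an indel
        keeps a shared anchor base at ``pos``)."""
        if self.vtype == "snv":
            return self.pos
        return self.pos + 1

    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> list[VariantRecord]:
    """Read a (plain-text) VCF; multiallelic sites are split per ALT."""
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[0] if rec.samples else None
            ps = None
            gt_str = "0/1"
            if sample is not None:
                gt = sample.get("GT")
                sep = "|" if sample.phased else "/"
                if gt is not None:
                    gt_str = sep.join("." if a is None else str(a) for a in gt)
                ps = sample.get("PS")
            for alt in rec.alts or ():
                records.append(VariantRecord(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else math.nan,
                    genotype=gt_str, phase_set=int(ps) if ps is not None else None,
                ))
    return records


def write_vcf(records: Sequence[VariantRecord], contig_lengths: Mapping[str, int],
              path: str, sample: str = "sample1") -> None:
    """Write records to a VCF v4.2 text file with GT and PS FORMAT fields."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    order = {c: i for i, c in enumerate(contig_lengths)}
    for r in sorted(records, key=lambda r: (order.get(r.contig, 1 << 30), r.pos, r.ref, r.alt)):
        if r.phase_set is not None:
            fmt, val = "GT:PS", f"{r.genotype}:{r.phase_set}"
        else:
            fmt, val = "GT", r.genotype
        qual = f"{r.qual:g}" if not math.isnan(r.qual) else "."
        lines.append(f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t.\t{fmt}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _seq(reference, contig: str) -> str:
    seq = reference[contig]
    return str(seq if isinstance(seq, str) else seq[:])


def normalize_variants(records: Iterable[VariantRecord], reference: Mapping[str, str]) -> list[VariantRecord]:
    """Trim shared prefix/suffix and left-align indels against the reference.

    The standard parsimony/left-alignment loop: repeatedly drop a shared
    terminal base (extending left with the reference base when an allele
    would empty), then drop shared leading bases. Output is sorted by
    (contig, pos, ref, alt). Raises when a REF allele disagrees with the
    reference sequence.
    """
    out = []
    for rec in records:
        seq = _seq(reference, rec.contig).upper()
        ref, alt, pos = rec.ref.upper(), rec.alt.upper(), rec.pos
        if seq[pos - 1: pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"REF mismatch at {rec.contig}:{pos}: VCF says {ref!r}, "
                f"assembly has {seq[pos - 1: pos - 1 + len(ref)]!r}"
            )
        while True:
            if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    if pos == 1:
                        # cannot extend left of the contig; restore the base
                        base = seq[pos - 1]
                        ref, alt = base + ref, base + alt
                        break
                    pos -= 1
                    base = seq[pos - 1]
                    ref, alt = base + ref, base + alt
            else:
                break
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        out.append(replace(rec, pos=pos, ref=ref, alt=alt))
    out.sort(key=VariantRecord.key)
    return out


# ---------------------------------------------------------------------------
# Quality dip and filtering
# ---------------------------------------------------------------------------

def detect_quality_dip(
    qualities: Sequence[float],
    fallback: int | None = None,
    smooth_window: int = 3,
    min_separation: int = 5,
    valley_prominence: float = 0.5,
) -> int | None:
    """Valley between the two modes of a bimodal quality histogram.

    Integer-bin histogram, centred moving-average smoothing, then the two
    largest local maxima at least ``min_separation`` bins apart; the
    threshold is the leftmost minimum-count bin strictly between them.
    The valley must dip below ``valley_prominence`` times the smaller peak
    (otherwise the "second mode" is just a shoulder of a unimodal
    histogram); an effectively unimodal histogram returns ``fallback``.
    """
    q = np.asarray(qualities, dtype=float)
    if len(q) == 0:
        raise ValueError("no quality values supplied")
    binned = np.round(q).astype(int)
    lo = int(binned.min())
    hist = np.bincount(binned - lo)
    sm = np.convolve(hist, np.ones(smooth_window) / smooth_window, mode="same")
    peaks = [i for i in range(len(sm))
             if sm[i] > 0
             and (i == 0 or sm[i] >= sm[i - 1])
             and (i == len(sm) - 1 or sm[i] > sm[i + 1])]
    peaks.sort(key=lambda i: (-sm[i], i))
    if not peaks:
        return fallback
    first = peaks[0]
    for p in peaks[1:]:
        if abs(p - first) < min_separation:
            continue
        a, b = sorted((first, p))
        between = sm[a + 1: b]
        if len(between) == 0:
            continue
        if between.min() > valley_prominence * min(sm[first], sm[p]):
            continue  # shoulder, not a genuine second mode
        return int(lo + a + 1 + int(np.argmin(between)))
    return fallback


def filter_by_quality(records: Iterable[VariantRecord], threshold: float) -> list[VariantRecord]:
    """Keep records with quality strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [r for r in records if r.qual > threshold]


# ---------------------------------------------------------------------------
# Intersection
# ---------------------------------------------------------------------------

def _check_sorted(records: Sequence[VariantRecord], name: str) -> None:
    keys = [r.key() for r in records]
    if keys != sorted(keys):
        raise ValueError(f"call set {name!r} is not sorted; normalize it first")


def intersect_callsets(
    a: Sequence[VariantRecord], b: Sequence[VariantRecord]
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Exact intersection on (contig, pos, ref, alt).

    Returns (shared, a_only, b_only, per-vtype count table). Shared records
    keep caller A's genotype/quality. Insertion/deletion designation is
    relative to the (haploid) assembly reference.
    """
    _check_sorted(a, "a")
    _check_sorted(b, "b")
    bkeys = {r.key() for r in b}
    akeys = {r.key() for r in a}
    shared = [r for r in a if r.key() in bkeys]
    a_only = [r for r in a if r.key() not in bkeys]
    b_only = [r for r in b if r.key() not in akeys]
    counts = pd.DataFrame(
        {
            "shared": _vtype_counts(shared),
            "a_only": _vtype_counts(a_only),
            "b_only": _vtype_counts(b_only),
        }
    )
    return shared, a_only, b_only, counts


def _vtype_counts(records: Sequence[VariantRecord]) -> pd.Series:
    s = pd.Series(0, index=list(VTYPES), dtype=int)
    for r in records:
        s[r.vtype] += 1
    return s


# ---------------------------------------------------------------------------
# Annotation partition
# ---------------------------------------------------------------------------

@dataclass
class PartitionSummary:
    counts: pd.DataFrame           # index vtype, columns exon/intron/intergenic
    fractions: pd.DataFrame        # same shape, rows sum to 1
    genome_exonic_fraction: float
    genome_intronic_fraction: float
    depletion_fold: dict[str, float]

    def depletion_fold_rounded(self, vtype: str) -> float:
        return round(self.depletion_fold[vtype], 1)


def depletion_fold(genome_fraction: float, variant_fraction: float) -> float:
    """Fold depletion of variants in a region: genome share / variant share."""
    if variant_fraction == 0:
        return math.inf if genome_fraction > 0 else math.nan
    return genome_fraction / variant_fraction


def partition_by_annotation(
    records: Sequence[VariantRecord],
    index: AnnotationIndex,
    summary: AnnotationSummary,
) -> PartitionSummary:
    """Partition variants by region of their anchor position.

    The anchor is the first altered base (the base after the shared anchor
    base, for normalized indels); exon takes precedence over intron.
    Variants on contigs absent from the annotation genome are counted
    intergenic with a warning.
    """
    counts = pd.DataFrame(0, index=list(VTYPES), columns=list(REGIONS), dtype=int)
    by_contig: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r)
    for contig, recs in by_contig.items():
        if contig not in index.contig_lengths:
            logger.warning("contig %r absent from annotation genome; counted intergenic", contig)
        regions = index.classify_positions(contig, np.asarray([r.anchor_pos for r in recs]))
        for r, reg in zip(recs, regions):
            counts.loc[r.vtype, reg] += 1
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    dep = {}
    for vt in VTYPES:
        dep[vt] = depletion_fold(summary.exonic_fraction, float(fractions.loc[vt, "exon"]))
    # indel depletion pooled over ins+del, as conventionally reported
    n_indel = counts.loc[["ins", "del"]].sum()
    tot_indel = int(n_indel.sum())
    dep["indel"] = depletion_fold(
        summary.exonic_fraction, (n_indel["exon"] / tot_indel) if tot_indel else 0.0
    )
    return PartitionSummary(
        counts=counts,
        fractions=fractions,
        genome_exonic_fraction=summary.exonic_fraction,
        genome_intronic_fraction=summary.intronic_fraction,
        depletion_fold=dep,
    )


def indel_frame_spectrum(records: Sequence[VariantRecord], index: AnnotationIndex) -> pd.DataFrame:
    """Frame-preserving (length % 3 == 0) vs frame-disrupting indel counts
    per region, with their ratio."""
    rows = {reg: {"frame_preserving": 0, "frame_disrupting": 0} for reg in REGIONS}
    for r in records:
        if r.vtype == "snv":
            continue
        reg = index.classify_position(r.contig, r.anchor_pos)
        key = "frame_preserving" if r.indel_length % 3 == 0 else "frame_disrupting"
        rows[reg][key] += 1
    df = pd.DataFrame(rows).T
    df["preserving_ratio"] = df["frame_preserving"] / (
        df["frame_preserving"] + df["frame_disrupting"]
    ).replace(0, np.nan)
    return df


def per_gene_indel_stats(
    records: Sequence[VariantRecord],
    index: AnnotationIndex,
    indel_length: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene exonic indel counts and per-exonic-kbp rates.

    Counts indels of exactly ``indel_length`` bp whose anchor falls in a
    gene's exons; the binned table groups genes by log2 gene length.
    """
    indels = [r for r in records if r.vtype != "snv" and r.indel_length == indel_length]
    per_gene = []
    for g in index.genes:
        if g.length <= 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        exonic_bp = g.exonic_bp
        n = 0
        for r in indels:
            if r.contig == g.contig and any(s <= r.anchor_pos <= e for s, e in g.exons):
                n += 1
        per_gene.append({
            "gene_id": g.gene_id, "contig": g.contig, "gene_length": g.length,
            "exonic_bp": exonic_bp, "n_indels": n,
            "rate_per_kbp": (n / exonic_bp * 1000) if exonic_bp else 0.0,
        })
    df = pd.DataFrame(per_gene)
    if df.empty:
        return df, pd.DataFrame()
    df["log2_length_bin"] = np.floor(np.log2(df["gene_length"])).astype(int)
    binned = df.groupby("log2_length_bin").agg(
        n_genes=("gene_id", "count"),
        total_indels=("n_indels", "sum"),
        total_exonic_kbp=("exonic_bp", lambda x: x.sum() / 1000),
    ).reset_index()
    binned["rate_per_kbp"] = binned["total_indels"] / binned["total_exonic_kbp"].replace(0, np.nan)
    return df, binned


def rate_length_trend(per_gene: pd.DataFrame) -> tuple[float, float, float]:
    """Least-squares slope of per-kbp indel rate vs log2 gene length,
    with a 95% CI (slope, lo, hi)."""
    x = np.log2(per_gene["gene_length"].to_numpy(dtype=float))
    y = per_gene["rate_per_kbp"].to_numpy(dtype=float)
    res = sps.linregress(x, y)
    half = 1.96 * res.stderr
    return res.slope, res.slope - half, res.slope + half


# ---------------------------------------------------------------------------
# Density by contig class
# ---------------------------------------------------------------------------

def density_by_contig_class(
    records: Sequence[VariantRecord],
    labels: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    het_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNVs per kbp aggregated by contig class, plus per-contig densities.

    Per class: total SNVs / total class bp x 1000. With ``het_only`` only
    heterozygous genotypes count (the default, matching a diploid
    heterozygosity readout).
    """
    label_of = dict(zip(labels["contig_id"], labels["label"]))
    snvs = [r for r in records if r.vtype == "snv" and (r.is_het or not het_only)]
    per_contig_n: dict[str, int] = {c: 0 for c in contig_lengths}
    for r in snvs:
        if r.contig in per_contig_n:
            per_contig_n[r.contig] += 1
    rows = [{
        "contig_id": c, "label": label_of.get(c, "unresolved"),
        "length": contig_lengths[c], "n_snvs": per_contig_n[c],
        "snv_per_kbp": per_contig_n[c] / contig_lengths[c] * 1000,
    } for c in contig_lengths]
    per_contig = pd.DataFrame(rows)
    by_class = per_contig.groupby("label").agg(
        n_contigs=("contig_id", "count"),
        total_bp=("length", "sum"),
        total_snvs=("n_snvs", "sum"),
    ).reset_index()
    by_class["snv_per_kbp"] = by_class["total_snvs"] / by_class["total_bp"] * 1000
    return by_class, per_contig
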