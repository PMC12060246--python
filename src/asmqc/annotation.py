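"""Gene-annotation interval index.

Holds, per contig, the merged exon union and gene-span union, and answers
point queries (exon / intron / intergenic) plus base-pair accounting.
Coordinates are 1-based inclusive throughout, as in GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np

REGIONS = ("exon", "intron", "intergenic")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def exonic_bp(self) -> int:
        return int(_interval_bp(_merge(self.exons)))


def _merge(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge 1-based inclusive intervals into disjoint sorted arrays."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end {e} precedes start {s}")
        if starts and s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _interval_bp(merged: tuple[np.ndarray, np.ndarray]) -> int:
    starts, ends = merged
    return int(np.sum(ends - starts + 1)) if len(starts) else 0


def _subtract(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]) -> int:
    """Base pairs in merged set *a* not covered by merged set *b*."""
    return _interval_bp(a) - _overlap_bp(a, b)


def _overlap_bp(a, b) -> int:
    sa, ea = a
    sb, eb = b
    total = 0
    j = 0
    for s, e in zip(sa, ea):
        while j < len(sb) and eb[j] < s:
            j += 1
        k = j
        while k < len(sb) and sb[k] <= e:
            total += min(e, eb[k]) - max(s, sb[k]) + 1
            k += 1
    return int(total)


def _in_union(merged: tuple[np.ndarray, np.ndarray], pos: np.ndarray) -> np.ndarray:
    starts, ends = merged
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[ok] = pos[ok] <= ends[idx[ok]]
    return inside


class AnnotationIndex:
    """Per-contig exon/gene interval unions with region classification."""

    def __init__(self, genes: Sequence[GeneModel], contig_lengths: Mapping[str, int]):
        self.genes = list(genes)
        self.contig_lengths = dict(contig_lengths)
        self._exon_union: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._gene_union: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_contig_exons: dict[str, list[tuple[int, int]]] = {}
        by_contig_genes: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            for s, e in g.exons:
                if s < g.start or e > g.end:
                    raise ValueError(
                        f"exon {s}-{e} outside gene {g.gene_id} span {g.start}-{g.end}"
                    )
            by_contig_exons.setdefault(g.contig, []).extend(g.exons)
            by_contig_genes.setdefault(g.contig, []).append((g.start, g.end))
        for contig in self.contig_lengths:
            self._exon_union[contig] = _merge(by_contig_exons.get(contig, []))
            self._gene_union[contig] = _merge(by_contig_genes.get(contig, []))
        # contigs annotated but absent from the length table are an error
        for contig in by_contig_genes:
            if contig not in self.contig_lengths:
                raise ValueError(f"annotated contig {contig!r} missing from contig lengths")

    @classmethod
    def from_gff3(cls, path: str, contig_lengths: Mapping[str, int]) -> "AnnotationIndex":
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for g in db.features_of_type("gene"):
            exons = []
            for ex in db.children(g, featuretype="exon"):
                exons.append((ex.start, ex.end))
            genes.append(GeneModel(g.id, g.seqid, g.start, g.end, sorted(set(exons))))
        return cls(genes, contig_lengths)

    # ---- bp accounting -------------------------------------------------
    def exonic_bp(self, contig: str | None = None) -> int:
        if contig is not None:
            return _interval_bp(self._exon_union[contig])
        return sum(_interval_bp(u) for u in self._exon_union.values())

    def intronic_bp(self, contig: str | None = None) -> int:
        if contig is not None:
            return _subtract(self._gene_union[contig], self._exon_union[contig])
        return sum(self.intronic_bp(c) for c in self.contig_lengths)

    def genic_bp(self, contig: str | None = None) -> int:
        if contig is not None:
            return _interval_bp(self._gene_union[contig])
        return sum(_interval_bp(u) for u in self._gene_union.values())

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())

    def intergenic_bp(self) -> int:
        return self.genome_length - self.genic_bp()

    # ---- classification ------------------------------------------------
    def classify_positions(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Region per position: array of 'exon' / 'intron' / 'intergenic'.

        Exon takes precedence over intron. Positions on contigs absent from
        the index are intergenic.
        """
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), "intergenic", dtype=object)
        if contig not in self.contig_lengths:
            return out
        in_exon = _in_union(self._exon_union[contig], positions)
        in_gene = _in_union(self._gene_union[contig], positions)
        out[in_gene & ~in_exon] = "intron"
        out[in_exon] = "exon"
        return out

    def classify_position(self, contig: str, pos: int) -> str:
        return str(self.classify_positions(contig, np.asarray([pos]))[0])
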