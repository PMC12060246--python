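"""Phase-block summaries from a phased VCF.

A phase block is the set of heterozygous variants sharing a PS FORMAT tag.
The summary reports blocks per contig, the fraction of contigs phased into
a single block and into three or fewer, and a joint table of contig
length, heterozygous-site count and block count for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .variant_landscape import VariantRecord, read_vcf


@dataclass
class PhaseSummary:
    per_contig: pd.DataFrame  # contig, n_het, n_phased, n_blocks, largest_block_span
    fraction_single_block: float
    fraction_le3_blocks: float
    denominator_policy: str
    n_denominator: int


def phase_block_summary(
    variants: Sequence[VariantRecord] | str,
    contig_lengths: Mapping[str, int] | None = None,
    denominator: str = "phased_contigs",
) -> PhaseSummary:
    """Blocks per contig and global phasing fractions.

    ``denominator`` controls what the single-block and <=3-block fractions
    are over: ``"phased_contigs"`` (default) counts only contigs with at
    least one phased heterozygous record — contigs whose heterozygous
    records are all unphased are reported with 0 blocks but excluded;
    ``"all_contigs"`` uses every contig in ``contig_lengths``.
    Raises when no record anywhere carries a PS tag.
    """
    if isinstance(variants, (str, bytes)) or hasattr(variants, "__fspath__"):
        variants = read_vcf(variants)
    het = [r for r in variants if r.is_het]
    if het and all(r.phase_set is None for r in het):
        raise ValueError("no PS tags found on any heterozygous record; input looks unphased")
    per: dict[str, dict] = {}
    for r in het:
        d = per.setdefault(r.contig, {"n_het": 0, "n_phased": 0, "blocks": {}})
        d["n_het"] += 1
        if r.phase_set is not None:
            d["n_phased"] += 1
            d["blocks"].setdefault(r.phase_set, []).append(r.pos)
    rows = []
    for contig, d in sorted(per.items()):
        spans = [max(p) - min(p) + 1 for p in d["blocks"].values()]
        rows.append({
            "contig": contig,
            "length": (contig_lengths or {}).get(contig),
            "n_het": d["n_het"],
            "n_phased": d["n_phased"],
            "n_blocks": len(d["blocks"]),
            "largest_block_span": max(spans) if spans else 0,
        })
    per_contig = pd.DataFrame(
        rows, columns=["contig", "length", "n_het", "n_phased", "n_blocks", "largest_block_span"]
    )
    phased = per_contig[per_contig["n_blocks"] >= 1]
    if denominator == "phased_contigs":
        denom = len(phased)
    elif denominator == "all_contigs":
        if contig_lengths is None:
            raise ValueError("all_contigs denominator needs contig_lengths")
        denom = len(contig_lengths)
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    single = int((phased["n_blocks"] == 1).sum())
    le3 = int((phased["n_blocks"] <= 3).sum())
    return PhaseSummary(
        per_contig=per_contig,
        fraction_single_block=single / denom if denom else 0.0,
        fraction_le3_blocks=le3 / denom if denom else 0.0,
        denominator_policy=denominator,
        n_denominator=denom,
    )


def blocks_vs_heterozygosity(
    summary: PhaseSummary, labels: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Joint (contig length, het sites, block count) table for plotting.

    Contigs without heterozygous records never appear; rows with zero
    phased blocks are dropped. Class labels are merged in when provided.
    """
    df = summary.per_contig.copy()
    df = df[df["n_het"] > 0].reset_index(drop=True)
    if labels is not None:
        df = df.merge(
            labels[["contig_id", "label"]], left_on="contig", right_on="contig_id", how="left"
        ).drop(columns=["contig_id"])
    return df
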