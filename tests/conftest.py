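"""Shared fixtures: a small genome for cheap unit tests and one
default-scale synthetic run (contigs at depth modes 52/26, ~5 Mbp) shared
by the parameter-recovery and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from asmqc import contig_classify as cc
from asmqc import contig_stats as cs
from asmqc import synthetic_data as sd
from asmqc.annotation import AnnotationIndex


SMALL_LENGTHS = {
    "autosomal": (40_000, 60_000),
    "sex": (30_000, 50_000),
    "collapsed": (12_000, 20_000),
    "contaminant": (12_000, 16_000),
}


def make_small_spec(seed: int = 11, **overrides) -> sd.SyntheticGenomeSpec:
    kwargs = dict(
        n_autosomal=3, n_sex=2, n_collapsed=2, n_contaminant=1,
        length_range=dict(SMALL_LENGTHS), seed=seed,
    )
    kwargs.update(overrides)
    return sd.SyntheticGenomeSpec(**kwargs)


@pytest.fixture(scope="session")
def small_genome():
    spec = make_small_spec()
    sequences, truth = sd.generate_assembly(spec)
    return spec, sequences, truth


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale synthetic analysis with known truth."""
    spec = sd.SyntheticGenomeSpec(seed=42)
    sequences, truth = sd.generate_assembly(spec)
    lengths = {c: len(s) for c, s in sequences.items()}
    aln = sd.simulate_alignments(sequences, truth, seed=spec.seed + 1)
    stats = cs.compute_contig_stats(sequences, aln)
    genes = sd.generate_annotation(sequences, seed=spec.seed + 2)
    index = AnnotationIndex(genes, lengths)
    set_a, set_b, truth = sd.simulate_callsets(sequences, index, truth, seed=spec.seed + 3)
    config = cc.ThresholdConfig(sketch_size=5_000)
    ref_e, ref_c = sd.simulate_references(sequences, truth, seed=spec.seed + 5)
    screen = cc.contaminant_screen(
        sequences,
        cc.minhash_sketch(ref_e, config.minhash_k, config.sketch_size),
        cc.minhash_sketch(ref_c, config.minhash_k, config.sketch_size),
        config=config,
    )
    labels = cc.classify_contigs(
        stats, config, contaminants=dict(zip(screen["contig_id"], screen["assignment"]))
    )
    return {
        "spec": spec,
        "sequences": sequences,
        "lengths": lengths,
        "truth": truth,
        "alignments": aln,
        "stats": stats,
        "genes": genes,
        "index": index,
        "set_a": set_a,
        "set_b": set_b,
        "screen": screen,
        "labels": labels,
        "config": config,
    }


# ---------------------------------------------------------------------------
# Independent oracles (brute force, kept deliberately naive)
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_unique_kmer_fraction(seq: str, k: int) -> float:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k].upper()
        if any(b not in "ACGT" for b in kmer):
            continue
        rc = kmer.translate(_COMP)[::-1]
        canon = min(kmer, rc)
        counts[canon] = counts.get(canon, 0) + 1
    if not counts:
        return float("nan")
    return sum(1 for v in counts.values() if v == 1) / len(counts)


def oracle_n50(lengths, genome_size=None):
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    half = (genome_size if genome_size is not None else total) / 2
    acc = 0
    for rank, length in enumerate(desc, start=1):
        acc += length
        if acc >= half:
            return length, rank
    return None, None


def oracle_pileup(reads, contig_length):
    """Per-base depth from (start0, end0) half-open read intervals."""
    depth = np.zeros(contig_length, dtype=int)
    for s, e in reads:
        depth[max(s, 0): min(e, contig_length)] += 1
    return depth


def oracle_interval_union_bp(intervals) -> int:
    """1-based inclusive intervals -> covered base count, via a position set."""
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e + 1))
    return len(covered)
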