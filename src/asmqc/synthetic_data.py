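"""Synthetic genomes, alignments, annotations, call sets and BUSCO tables
with known ground truth.

The generator emulates the structure a post-assembly triage pipeline sees
on a diploid mammalian assembly from a male individual:

* autosomal contigs at a primary depth mode (~52x) and sex-linked contigs
  at half that (~26x);
* "collapsed" contigs built from a short tandem repeat plus a telomere
  array, giving a unique-21-mer fraction far below 0.5, mostly-ambiguous
  read placement (MAPQ 0) and inflated all-read depth;
* contaminant contigs drawn from a distinct composition model (different
  GC, independent k-mer source);
* heterozygous SNVs/indels at class-specific rates (~2.4 SNVs/kbp on
  autosomes, ~0.11/kbp on sex contigs), called by two simulated callers
  whose quality scores form a bimodal error/true mixture, one call set
  phased into a planted number of blocks per contig;
* multi-species BUSCO status tables with planted nested sharing.

Reads are error-free and ungapped: the diagnostics under test consume
depth and MAPQ, not base errors, and exact reads keep the pileup oracle
exact. All randomness flows through one seeded generator per invocation;
identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import AnnotationIndex, GeneModel
from .busco_compare import BuscoTable, CATEGORIES
from .variant_landscape import VariantRecord

logger = logging.getLogger(__name__)

CLASSES = ("autosomal", "sex", "collapsed", "contaminant")
TELOMERE_MOTIF = "TTAGGG"

#: truth label -> classifier label vocabulary
TRUTH_TO_LABEL = {
    "autosomal": "autosomal",
    "sex": "sex_candidate",
    "collapsed": "collapsed_repeat",
    "contaminant": "contaminant_candidate",
}


def _default_length_range():
    return {
        "autosomal": (250_000, 450_000),
        "sex": (150_000, 350_000),
        "collapsed": (30_000, 80_000),
        "contaminant": (30_000, 60_000),
    }


def _default_gc():
    return {"autosomal": 0.41, "sex": 0.41, "collapsed": 0.48, "contaminant": 0.58}


def _default_snv_rate():
    # ~2.4 het SNVs/kbp on autosomes, ~0.11/kbp on sex-linked contigs
    return {"autosomal": 2.4e-3, "sex": 1.1e-4, "collapsed": 0.0, "contaminant": 0.0}


def _default_indel_rate():
    return {"autosomal": 2.0e-4, "sex": 1.0e-5, "collapsed": 0.0, "contaminant": 0.0}


@dataclass
class SyntheticGenomeSpec:
    n_autosomal: int = 10
    n_sex: int = 4
    n_collapsed: int = 4
    n_contaminant: int = 2
    length_range: dict = field(default_factory=_default_length_range)
    gc_target: dict = field(default_factory=_default_gc)
    het_snv_rate: dict = field(default_factory=_default_snv_rate)
    het_indel_rate: dict = field(default_factory=_default_indel_rate)
    telomere_array_len: int = 3_000
    repeat_unit_len: int = 50
    # collapsed contigs are built as pure tandem arrays: even a light point-
    # mutation load would add ~2k unique k-mers against a ~60 k-mer
    # denominator and swamp the low-uniqueness signal they must carry
    collapsed_mutation_rate: float = 0.0
    autosomal_depth: float = 52.0
    sex_depth: float = 26.0
    collapsed_depth: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_autosomal", "n_sex", "n_collapsed", "n_contaminant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cls in CLASSES:
            gc = self.gc_target[cls]
            if not (0 < gc < 1):
                raise ValueError(f"gc_target[{cls!r}] must be in (0, 1), got {gc}")
            lo, hi = self.length_range[cls]
            if not (0 < lo <= hi):
                raise ValueError(f"length_range[{cls!r}] invalid: {(lo, hi)}")
            for rates in ("het_snv_rate", "het_indel_rate"):
                if getattr(self, rates)[cls] < 0:
                    raise ValueError(f"{rates}[{cls!r}] must be >= 0")
        if not self.sex_depth < self.autosomal_depth:
            raise ValueError("sex_depth must be < autosomal_depth")

    def class_depth(self, cls: str) -> float:
        return {
            "autosomal": self.autosomal_depth,
            "sex": self.sex_depth,
            "collapsed": self.collapsed_depth,
            "contaminant": self.autosomal_depth,
        }[cls]


@dataclass
class SyntheticTruth:
    contigs: pd.DataFrame                       # contig_id,label,length,target_depth,rates
    variants: pd.DataFrame | None = None        # filled by simulate_callsets
    phase_blocks: dict = field(default_factory=dict)    # contig -> planted block count
    quality_valleys: dict = field(default_factory=dict)  # caller -> planted valley
    busco: dict = field(default_factory=dict)   # planted set cardinalities

    def label_of(self, contig_id: str) -> str:
        row = self.contigs.loc[self.contigs["contig_id"] == contig_id]
        return str(row["label"].iloc[0])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_assembly(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate one contig per planned record plus a truth table.

    Collapsed-class contigs are a short seed repeat tiled to length with a
    light mutation load, plus a telomere-motif array — guaranteeing a
    unique-21-mer fraction well below 0.5. Contaminant contigs come from
    an independent composition model.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    rows = []
    plan = [("autosomal", spec.n_autosomal), ("sex", spec.n_sex),
            ("collapsed", spec.n_collapsed), ("contaminant", spec.n_contaminant)]
    for cls, n in plan:
        lo, hi = spec.length_range[cls]
        for i in range(n):
            cid = f"{cls}_{i + 1:02d}"
            length = int(rng.integers(lo, hi + 1))
            if cls == "collapsed":
                unit = _random_seq(rng, spec.repeat_unit_len, spec.gc_target[cls])
                body_len = max(length - spec.telomere_array_len, spec.repeat_unit_len)
                body = (unit * (body_len // len(unit) + 1))[:body_len]
                body = _mutate(rng, body, spec.collapsed_mutation_rate)
                telo = (TELOMERE_MOTIF * (spec.telomere_array_len // 6 + 1))[: spec.telomere_array_len]
                seq = body + telo
                length = len(seq)
            else:
                seq = _random_seq(rng, length, spec.gc_target[cls])
            sequences[cid] = seq
            rows.append({
                "contig_id": cid, "label": cls, "length": length,
                "target_depth": spec.class_depth(cls),
                "het_snv_rate": spec.het_snv_rate[cls],
                "het_indel_rate": spec.het_indel_rate[cls],
            })
    truth = SyntheticTruth(contigs=pd.DataFrame(
        rows, columns=["contig_id", "label", "length", "target_depth",
                       "het_snv_rate", "het_indel_rate"]))
    return sequences, truth


def simulate_references(
    sequences: Mapping[str, str], truth: SyntheticTruth,
    divergence: float = 0.01, seed: int = 0,
) -> tuple[str, str]:
    """Diverged reference genomes for the two-reference contaminant screen.

    The "expected" reference is a mutated copy of the autosomal and
    sex-class contigs (a conspecific-like genome); the "contaminant"
    reference is a mutated copy of the contaminant-class contigs.
    """
    rng = np.random.default_rng(seed)
    expected, contaminant = [], []
    for row in truth.contigs.itertuples():
        seq = sequences[row.contig_id]
        if row.label in ("autosomal", "sex"):
            expected.append(_mutate(rng, seq, divergence))
        elif row.label == "contaminant":
            contaminant.append(_mutate(rng, seq, divergence))
    return "".join(expected), "".join(contaminant)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSet:
    """Simulated error-free ungapped alignments, kept as per-contig arrays."""

    contig_lengths: dict[str, int]
    starts: dict[str, np.ndarray]    # 0-based
    lengths: dict[str, np.ndarray]
    mapqs: dict[str, np.ndarray]

    @property
    def n_reads(self) -> int:
        return sum(len(s) for s in self.starts.values())

    def read_intervals(self, contig: str, mapq_min: int) -> tuple[np.ndarray, np.ndarray]:
        keep = self.mapqs[contig] > mapq_min
        s = self.starts[contig][keep]
        return s, s + self.lengths[contig][keep]

    def write_sam(self, path: str, sequences: Mapping[str, str] | None = None) -> None:
        """SAM v1.6 with @SQ headers; SEQ is emitted when sequences are
        given, '*' otherwise (reads are error-free copies of the
        reference, so SEQ carries no extra information)."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for name, length in self.contig_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
            for name in self.contig_lengths:
                order = np.argsort(self.starts[name], kind="stable")
                for i in order:
                    start = int(self.starts[name][i])
                    rlen = int(self.lengths[name][i])
                    mq = int(self.mapqs[name][i])
                    seq = sequences[name][start: start + rlen] if sequences else "*"
                    fh.write(
                        f"read_{name}_{i}\t0\t{name}\t{start + 1}\t{mq}\t{rlen}M\t*\t0\t0\t{seq}\t*\n"
                    )


def simulate_alignments(
    sequences: Mapping[str, str],
    truth: SyntheticTruth,
    read_len: int = 1_000,
    seed: int = 0,
    collapsed_mapq0_prob: float = 0.95,
) -> AlignmentSet:
    """Tile error-free reads uniformly to hit each contig's target depth.

    Reads from collapsed-class contigs get MAPQ 0 with probability
    ``collapsed_mapq0_prob`` (ambiguous placement proxy), all others
    MAPQ 60.
    """
    if read_len < 50:
        raise ValueError("read_len must be >= 50")
    rng = np.random.default_rng(seed)
    starts, lengths, mapqs = {}, {}, {}
    contig_lengths = {}
    for row in truth.contigs.itertuples():
        cid = row.contig_id
        if cid not in sequences:
            raise ValueError(f"contig {cid!r} in truth but missing from genome")
        L = len(sequences[cid])
        contig_lengths[cid] = L
        rl = min(read_len, L)
        n = int(round(row.target_depth * L / rl))
        s = rng.integers(0, L - rl + 1, size=n) if n else np.empty(0, dtype=np.int64)
        starts[cid] = np.asarray(s, dtype=np.int64)
        lengths[cid] = np.full(n, rl, dtype=np.int64)
        if row.label == "collapsed":
            mapqs[cid] = np.where(rng.random(n) < collapsed_mapq0_prob, 0, 60).astype(np.int64)
        else:
            mapqs[cid] = np.full(n, 60, dtype=np.int64)
    return AlignmentSet(contig_lengths, starts, lengths, mapqs)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    sequences: Mapping[str, str],
    gene_density: float = 9.0,
    exon_count_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    exon_len_mean: float = 156.0,
    intron_len_mean: float = 1_605.0,
    max_placement_tries: int = 10,
) -> list[GeneModel]:
    """Non-overlapping gene models at ``gene_density`` genes/Mbp.

    Exon/intron lengths are exponential around mammalian-like means. A
    gene that cannot be placed without overlap (or is longer than its
    contig) is retried and then skipped.
    """
    if gene_density <= 0:
        raise ValueError("gene_density must be > 0")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    gi = 0
    for cid, seq in sequences.items():
        L = len(seq)
        n = rng.poisson(gene_density * L / 1e6)
        occupied: list[tuple[int, int]] = []
        for _ in range(n):
            n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
            ex_lens = np.maximum(30, rng.exponential(exon_len_mean, n_ex).astype(int))
            in_lens = np.maximum(60, rng.exponential(intron_len_mean, n_ex - 1).astype(int))
            glen = int(ex_lens.sum() + in_lens.sum())
            if glen >= L:
                logger.debug("gene longer than contig %s; skipped", cid)
                continue
            placed = False
            for _try in range(max_placement_tries):
                s = int(rng.integers(1, L - glen + 1))
                e = s + glen - 1
                if all(e < os or s > oe for os, oe in occupied):
                    placed = True
                    break
            if not placed:
                continue
            occupied.append((s, e))
            gi += 1
            exons = []
            cur = s
            for j in range(n_ex):
                exons.append((cur, cur + int(ex_lens[j]) - 1))
                cur += int(ex_lens[j])
                if j < n_ex - 1:
                    cur += int(in_lens[j])
            genes.append(GeneModel(f"gene{gi:05d}", cid, s, e, exons))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(f"{g.contig}\tasmqc\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}")
        mrna = f"{g.gene_id}.t1"
        lines.append(f"{g.contig}\tasmqc\tmRNA\t{g.start}\t{g.end}\t.\t+\t.\tID={mrna};Parent={g.gene_id}")
        for k, (s, e) in enumerate(sorted(g.exons), 1):
            lines.append(
                f"{g.contig}\tasmqc\texon\t{s}\t{e}\t.\t+\t.\tID={mrna}.exon{k};Parent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

@dataclass
class CallerModel:
    name: str
    error_mean: float
    error_sd: float
    true_mean: float
    true_sd: float

    def validate(self) -> None:
        if self.true_mean - self.error_mean < 10:
            raise ValueError(
                f"caller {self.name}: true and error quality modes must be >= 10 apart"
            )


#: defaults calibrated so the expected-histogram valley sits at 14 (A) and 20 (B)
DEFAULT_CALLER_A = CallerModel("caller_a", 8.0, 2.0, 30.0, 6.0)
DEFAULT_CALLER_B = CallerModel("caller_b", 13.0, 3.0, 34.0, 6.0)

QUAL_MIN, QUAL_MAX = 1, 60
PHASE_BLOCK_PROBS = (0.55, 0.15, 0.10, 0.10, 0.10)  # planted counts 1..5


def _draw_qual(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    q = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.clip(q, QUAL_MIN, QUAL_MAX)


def planted_valley(model: CallerModel, error_weight: float) -> int:
    """Analytic valley of the expected (smoothed) quality histogram: the
    between-modes argmin of the error/true normal mixture discretised to
    integer bins — the value the dip detector should recover."""
    q = np.arange(QUAL_MIN, QUAL_MAX + 1)
    h = error_weight * norm.pdf(q, model.error_mean, model.error_sd) + norm.pdf(
        q, model.true_mean, model.true_sd
    )
    sm = np.convolve(h, np.ones(3) / 3, mode="same")
    lo, hi = int(round(model.error_mean)), int(round(model.true_mean))
    seg = sm[lo - QUAL_MIN: hi - QUAL_MIN + 1]
    return int(lo + np.argmin(seg))


def simulate_callsets(
    sequences: Mapping[str, str],
    annotation: AnnotationIndex | Sequence[GeneModel] | None,
    truth: SyntheticTruth,
    caller_a: CallerModel = DEFAULT_CALLER_A,
    caller_b: CallerModel = DEFAULT_CALLER_B,
    seed: int = 0,
    error_snv_per_kbp: float = 0.5,
    exon_indel_suppression: float = 3.5,
    exon_frameshift_suppression: float = 5.0,
    phase_block_probs: Sequence[float] = PHASE_BLOCK_PROBS,
) -> tuple[list[VariantRecord], list[VariantRecord], SyntheticTruth]:
    """Two overlapping call sets (A phased) over planted true variants.

    True heterozygous variants appear in both call sets with qualities from
    each caller's true mode; caller-specific false SNV calls (at
    ``error_snv_per_kbp`` per kbp of assembly, on positions disjoint from
    the truth and from each other) carry error-mode qualities, so each
    call set's quality histogram is bimodal with a known valley. Exonic indels are thinned by
    ``exon_indel_suppression`` and frame-disrupting exonic indels further
    by ``exon_frameshift_suppression``. Caller A's true heterozygous calls
    are phased into a planted number of PS blocks per contig.
    """
    caller_a.validate()
    caller_b.validate()
    rng = np.random.default_rng(seed)
    if annotation is not None and not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(
            annotation, {c: len(s) for c, s in sequences.items()}
        )

    truth_rows: list[dict] = []
    taken: dict[str, set[int]] = {c: set() for c in sequences}
    dropped = 0

    for row in truth.contigs.itertuples():
        cid = row.contig_id
        seq = sequences[cid].upper()
        L = len(seq)
        # --- true SNVs ---
        n_snv = rng.binomial(L, row.het_snv_rate) if row.het_snv_rate > 0 else 0
        snv_pos = rng.choice(L, size=n_snv, replace=False) + 1 if n_snv else []
        for pos in sorted(int(p) for p in snv_pos):
            ref = seq[pos - 1]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            taken[cid].add(pos)
            truth_rows.append({"contig": cid, "pos": pos, "ref": ref, "alt": alt,
                               "vtype": "snv", "membership": "both", "is_error": False})
        # --- true indels ---
        n_ind = rng.binomial(L, row.het_indel_rate) if row.het_indel_rate > 0 else 0
        ind_pos = rng.choice(L - 10, size=n_ind, replace=False) + 1 if n_ind else []
        for pos in sorted(int(p) for p in ind_pos):
            if pos in taken[cid]:
                dropped += 1
                continue
            length = int(rng.geometric(0.5))
            if annotation is not None:
                region = annotation.classify_position(cid, pos + 1)
                if region == "exon":
                    if rng.random() >= 1.0 / exon_indel_suppression:
                        continue
                    if length % 3 != 0 and rng.random() >= 1.0 / exon_frameshift_suppression:
                        continue
            if rng.random() < 0.5 and pos + length <= L:  # deletion
                ref = seq[pos - 1: pos + length]
                alt = ref[0]
                vtype = "del"
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + _random_seq(rng, length, 0.5)
                vtype = "ins"
            taken[cid].add(pos)
            truth_rows.append({"contig": cid, "pos": pos, "ref": ref, "alt": alt,
                               "vtype": vtype, "membership": "both", "is_error": False})

    n_true = len(truth_rows)
    # --- caller-specific false SNV calls at disjoint positions ---
    contigs = list(sequences)
    total_bp = sum(len(s) for s in sequences.values())
    weights = np.array([len(sequences[c]) for c in contigs], dtype=float)
    weights /= weights.sum()
    n_err = int(round(error_snv_per_kbp / 1000 * total_bp))
    for membership in ("a_only", "b_only"):
        made = 0
        while made < n_err:
            cid = contigs[int(rng.choice(len(contigs), p=weights))]
            pos = int(rng.integers(1, len(sequences[cid]) + 1))
            if pos in taken[cid]:
                dropped += 1
                continue
            ref = sequences[cid][pos - 1].upper()
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            taken[cid].add(pos)
            truth_rows.append({"contig": cid, "pos": pos, "ref": ref, "alt": alt,
                               "vtype": "snv", "membership": membership, "is_error": True})
            made += 1
    if dropped:
        logger.info("dropped %d colliding variant draws", dropped)

    variants = pd.DataFrame(
        truth_rows, columns=["contig", "pos", "ref", "alt", "vtype", "membership", "is_error"]
    )
    if len(variants):
        variants = variants.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
        variants["qual_a"] = np.where(
            variants["is_error"] & (variants["membership"] == "a_only"),
            _draw_qual(rng, caller_a.error_mean, caller_a.error_sd, len(variants)),
            _draw_qual(rng, caller_a.true_mean, caller_a.true_sd, len(variants)),
        )
        variants["qual_b"] = np.where(
            variants["is_error"] & (variants["membership"] == "b_only"),
            _draw_qual(rng, caller_b.error_mean, caller_b.error_sd, len(variants)),
            _draw_qual(rng, caller_b.true_mean, caller_b.true_sd, len(variants)),
        )
    else:
        variants["qual_a"] = pd.Series(dtype=int)
        variants["qual_b"] = pd.Series(dtype=int)

    # --- phase blocks on caller A's true calls ---
    phase_blocks: dict[str, int] = {}
    ps_of: dict[tuple[str, int], int] = {}
    probs = np.asarray(phase_block_probs, dtype=float)
    probs = probs / probs.sum()
    for cid in contigs:
        sub = variants[(variants["contig"] == cid) & (~variants["is_error"])]
        n_sites = len(sub)
        if n_sites == 0:
            continue
        planted = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
        planted = min(planted, n_sites)
        phase_blocks[cid] = planted
        positions = sub["pos"].to_numpy()
        if planted > 1:
            cuts = np.sort(rng.choice(np.arange(1, n_sites), size=planted - 1, replace=False))
        else:
            cuts = np.empty(0, dtype=int)
        bounds = np.concatenate(([0], cuts, [n_sites]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            ps = int(positions[b0])
            for p in positions[b0:b1]:
                ps_of[(cid, int(p))] = ps

    # --- materialise records ---
    set_a: list[VariantRecord] = []
    set_b: list[VariantRecord] = []
    for v in variants.itertuples():
        if v.membership in ("both", "a_only"):
            if not v.is_error and (v.contig, v.pos) in ps_of:
                gt = "0|1" if rng.random() < 0.5 else "1|0"
                ps = ps_of[(v.contig, v.pos)]
            else:
                gt, ps = "0/1", None
            set_a.append(VariantRecord(v.contig, int(v.pos), v.ref, v.alt,
                                       float(v.qual_a), gt, ps))
        if v.membership in ("both", "b_only"):
            set_b.append(VariantRecord(v.contig, int(v.pos), v.ref, v.alt,
                                       float(v.qual_b), "0/1", None))

    truth.variants = variants
    truth.phase_blocks = phase_blocks
    if n_true and n_err:
        weight = n_err / n_true
        truth.quality_valleys = {
            caller_a.name: planted_valley(caller_a, weight),
            caller_b.name: planted_valley(caller_b, weight),
        }
    else:
        truth.quality_valleys = {}
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# BUSCO fixture
# ---------------------------------------------------------------------------

def generate_busco_fixture(
    n_species: int = 10,
    n_busco: int = 12_234,
    ancestral_missing: int = 33,
    lineage_specific: Mapping[tuple, int] | None = None,
    seed: int = 0,
    off_status: str = "missing",
) -> tuple[BuscoTable, dict]:
    """Species x BUSCO status matrix with planted sharing structure.

    ``lineage_specific`` maps a tuple of species names (the set in which a
    block of BUSCOs is single-copy) to the block size; those BUSCOs carry
    ``off_status`` in the remaining species. Exactly ``ancestral_missing``
    ids are missing in every species; everything else is single-copy
    everywhere.
    """
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    lineage_specific = dict(lineage_specific or {})
    planted_total = ancestral_missing + sum(lineage_specific.values())
    if planted_total > n_busco:
        raise ValueError(
            f"infeasible fixture: {planted_total} planted ids exceed n_busco={n_busco}"
        )
    for subset in lineage_specific:
        unknown = set(subset) - set(species)
        if unknown:
            raise ValueError(f"lineage_specific names unknown species: {sorted(unknown)}")
    ids = [f"busco{i + 1:05d}" for i in range(n_busco)]
    status = pd.DataFrame("single", index=pd.Index(ids, name="busco_id"), columns=species)
    cursor = 0
    status.iloc[cursor: cursor + ancestral_missing, :] = "missing"
    cursor += ancestral_missing
    for subset, count in lineage_specific.items():
        block = status.index[cursor: cursor + count]
        absent = [sp for sp in species if sp not in subset]
        status.loc[block, absent] = off_status
        cursor += count
    table = BuscoTable.from_status(status, lineage="synthetic")
    truth = {
        "ancestral_missing": ancestral_missing,
        "lineage_specific": {tuple(k): v for k, v in lineage_specific.items()},
        "single_in_all": n_busco - cursor,
        "species": species,
    }
    return table, truth


def default_busco_lineage_specific(species: Sequence[str]) -> dict[tuple, int]:
    """Nested sharing structure shaped like a real clade comparison:
    a large all-but-one block, a block excluding the most diverged
    species, that species' private block, and a small two-species loss."""
    sp = list(species)
    return {
        tuple(sp[:-1]): 122,            # single everywhere except the last species
        tuple(sp[1:]): 50,              # single everywhere except the first
        (sp[0],): 13,                   # private to the first
        tuple(s for s in sp if s not in (sp[1], sp[5])): 9,
    }


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.contigs.to_csv(out / "truth_contigs.tsv", sep="\t", index=False)
    if truth.variants is not None:
        truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    if truth.phase_blocks:
        pd.DataFrame(
            sorted(truth.phase_blocks.items()), columns=["contig_id", "n_blocks"]
        ).to_csv(out / "truth_phase_blocks.tsv", sep="\t", index=False)
    if truth.quality_valleys:
        pd.DataFrame(
            sorted(truth.quality_valleys.items()), columns=["caller", "valley"]
        ).to_csv(out / "truth_quality_valleys.tsv", sep="\t", index=False)


def write_busco_status_tsv(table: BuscoTable, path: str) -> None:
    long = table.status.stack().rename("status").reset_index()
    long.columns = ["busco_id", "species", "status"]
    long[["species", "busco_id", "status"]].to_csv(path, sep="\t", index=False)
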