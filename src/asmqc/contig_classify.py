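"""Contig triage: depth-mode estimation, rule-based classification,
MinHash sketches and the two-reference contaminant screen.

The classification mirrors a common post-assembly workflow on a diploid
genome sequenced from a male individual: high-quality-mapper depth is
bimodal (autosomes at the primary mode, X/Y at half), contigs with a low
fraction of unique 21-mers are collapsed repeats, and contigs closer (by
Mash distance) to a contaminant reference than to a conspecific reference
are contamination candidates. Depth cutoffs are expressed relative to the
estimated primary mode so the same rules apply at any coverage; the
defaults reproduce absolute cutoffs of 30 and 45 when the primary mode
is 52.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kmers

LABELS = ("autosomal", "sex_candidate", "collapsed_repeat", "contaminant_candidate", "unresolved")


@dataclass
class ThresholdConfig:
    k: int = 21
    mapq_min: int = 20
    unique_kmer_min: float = 0.90
    telomere_fold_min: float = 4.0
    sex_depth_max_rel: float = 30 / 52
    autosome_depth_min_rel: float = 45 / 52
    sketch_size: int = 500_000
    minhash_k: int = 21
    small_contig_bp: int = 10_000
    collapsed_mapq0_prob: float = 0.95  # used by the synthetic read model

    def __post_init__(self):
        if not (0 < self.sex_depth_max_rel < self.autosome_depth_min_rel <= 1):
            raise ValueError("require 0 < sex_depth_max_rel < autosome_depth_min_rel <= 1")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")


@dataclass
class ContigLabel:
    contig_id: str
    label: str
    evidence: dict = field(default_factory=dict)
    telomere_flag: bool = False


def _plateau_peaks(sm: np.ndarray) -> list[int]:
    """Indices of local maxima of a smoothed histogram; a flat plateau
    (produced by smoothing a single spike) counts once, at its centre."""
    peaks = []
    i = 0
    n = len(sm)
    while i < n:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        left_ok = i == 0 or sm[i - 1] < sm[i]
        right_ok = j == n - 1 or sm[j + 1] < sm[i]
        if sm[i] > 0 and left_ok and right_ok:
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def estimate_depth_modes(
    hq_depths: Sequence[float],
    weights: Sequence[float] | None = None,
    min_separation: int = 10,
    smooth_window: int = 5,
) -> tuple[float, float | None]:
    """Primary and secondary depth modes of a length-weighted histogram.

    Bin width 1, centred moving-average smoothing; modes are the two
    highest local maxima separated by at least ``min_separation`` bins.
    The primary mode is the higher-depth peak of the top pair by height;
    secondary is None when the histogram is effectively unimodal.
    """
    depths = np.asarray(hq_depths, dtype=float)
    if len(depths) == 0:
        raise ValueError("no depths supplied")
    if np.all(depths == 0):
        raise ValueError("all depths are zero")
    w = np.ones(len(depths)) if weights is None else np.asarray(weights, dtype=float)
    # pad past the maximum so smoothing a spike at the top edge still
    # yields a symmetric plateau
    edges = np.arange(0, int(np.max(depths)) + 2 + smooth_window)
    hist, _ = np.histogram(depths, bins=edges, weights=w)
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(hist, kernel, mode="same")
    peaks = _plateau_peaks(sm)
    if not peaks:
        peaks = [int(np.argmax(sm))]
    peaks.sort(key=lambda i: (-sm[i], i))
    best = peaks[0]
    second = None
    for p in peaks[1:]:
        if abs(p - best) < min_separation:
            continue
        a, b = sorted((best, p))
        between = sm[a + 1: b]
        # a genuine second mode is separated from the primary by a valley,
        # not a shoulder of the same peak
        if len(between) and between.min() <= 0.5 * sm[p]:
            second = p
            break
    if second is None:
        return float(best), None
    primary, secondary = (best, second) if best >= second else (second, best)
    # primary = higher-depth peak of the top pair
    return float(primary), float(secondary)


def classify_contigs(
    stats: pd.DataFrame,
    config: ThresholdConfig | None = None,
    primary_mode: float | None = None,
    contaminants: Mapping[str, str] | None = None,
) -> list[ContigLabel]:
    """Rule-based labels from a per-contig stats table.

    Rule order: contaminant screen result (if supplied) overrides all;
    then (1) collapsed_repeat when unique-k-mer fraction is below the
    cutoff, (2) sex_candidate when nonrepetitive with HQ depth below
    ``sex_depth_max_rel`` x primary mode, (3) autosomal when nonrepetitive
    with HQ depth above ``autosome_depth_min_rel`` x primary mode,
    (4) unresolved. The telomere flag is set independently of the label.
    """
    config = config or ThresholdConfig()
    if primary_mode is None:
        primary_mode, _ = estimate_depth_modes(
            stats["depth_hq"].to_numpy(), stats["length"].to_numpy()
        )
    sex_max = config.sex_depth_max_rel * primary_mode
    auto_min = config.autosome_depth_min_rel * primary_mode
    contaminants = contaminants or {}
    labels = []
    for row in stats.itertuples():
        cid = row.contig_id
        tel = bool(
            not math.isnan(row.telomere_enrichment)
            and row.telomere_enrichment >= config.telomere_fold_min
        )
        if contaminants.get(cid) == "contaminant_candidate":
            lab = ContigLabel(cid, "contaminant_candidate",
                              {"screen": "closer_to_contaminant_reference"}, tel)
        elif not math.isnan(row.unique_kmer_fraction) and row.unique_kmer_fraction < config.unique_kmer_min:
            lab = ContigLabel(cid, "collapsed_repeat",
                              {"unique_kmer_fraction": row.unique_kmer_fraction}, tel)
        elif row.depth_hq < sex_max:
            lab = ContigLabel(cid, "sex_candidate",
                              {"depth_hq": row.depth_hq, "cutoff": sex_max}, tel)
        elif row.depth_hq > auto_min:
            lab = ContigLabel(cid, "autosomal",
                              {"depth_hq": row.depth_hq, "cutoff": auto_min}, tel)
        else:
            lab = ContigLabel(cid, "unresolved", {}, tel)
        labels.append(lab)
    return labels


def labels_to_frame(labels: Iterable[ContigLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig_id": l.contig_id, "label": l.label, "telomere_flag": l.telomere_flag,
          "evidence": ";".join(f"{k}={v}" for k, v in l.evidence.items())}
         for l in labels]
    )


# ---------------------------------------------------------------------------
# MinHash sketches and Mash distance
# ---------------------------------------------------------------------------

@dataclass
class MinHashSketch:
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, distinct uint64

    def __len__(self) -> int:
        return len(self.hashes)


def minhash_sketch(sequence: str, k: int = 21, sketch_size: int = 500_000) -> MinHashSketch:
    """Bottom-s sketch: the ``sketch_size`` smallest distinct SplitMix64
    hashes of the canonical k-mers."""
    codes = _kmers.kmer_codes(sequence, k, canonical=True)
    hashes = np.unique(_kmers.mix64(codes))
    return MinHashSketch(k, sketch_size, hashes[:sketch_size])


def sketch_jaccard(a: MinHashSketch, b: MinHashSketch) -> float:
    """Bottom-sketch Jaccard estimate from two sketches of equal k."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    s = min(a.sketch_size, b.sketch_size)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if len(union) == 0:
        return 0.0
    both = np.intersect1d(union, np.intersect1d(a.hashes, b.hashes, assume_unique=True))
    return len(both) / len(union)


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance d = -ln(2j/(1+j))/k from the bottom-sketch Jaccard.

    0 when j = 1, capped at 1.0 when j = 0.
    """
    j = sketch_jaccard(a, b)
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    return min(1.0, -math.log(2 * j / (1 + j)) / a.k)


# ---------------------------------------------------------------------------
# Contaminant screen
# ---------------------------------------------------------------------------

def parse_paf(lines: Iterable[str]) -> pd.DataFrame:
    """Minimal PAF reader: query, target and alignment-block length."""
    rows = []
    for ln, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(f"malformed PAF line {ln}: expected >= 12 fields, got {len(parts)}")
        try:
            rows.append({
                "query": parts[0], "query_len": int(parts[1]),
                "target": parts[5], "block_len": int(parts[10]),
            })
        except ValueError as exc:
            raise ValueError(f"malformed PAF line {ln}: {exc}") from exc
    return pd.DataFrame(rows, columns=["query", "query_len", "target", "block_len"])


def contaminant_screen(
    sequences: Mapping[str, str],
    ref_expected: MinHashSketch,
    ref_contaminant: MinHashSketch,
    alignments=None,
    ref_names: Mapping[str, str] | None = None,
    config: ThresholdConfig | None = None,
    sum_blocks: bool = False,
) -> pd.DataFrame:
    """Two-reference screen: Mash distance first, alignment fallback second.

    A contig is a contaminant candidate when its Mash distance to the
    contaminant reference is smaller than to the expected (conspecific)
    reference. Contigs below ``small_contig_bp``, or whose sketch shares
    nothing with either reference, fall back to comparing the longest
    single aligned block per reference in the PAF (``sum_blocks`` switches
    to summed block lengths); ties or no alignment leave the contig
    unresolved.

    ``ref_names`` maps PAF target names to ``"expected"`` /
    ``"contaminant"``; unlisted targets are ignored.
    """
    if ref_expected.k != ref_contaminant.k:
        raise ValueError("reference sketches must share k")
    config = config or ThresholdConfig()
    paf = None
    if alignments is not None:
        if isinstance(alignments, pd.DataFrame):
            paf = alignments
        else:
            if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
                with open(alignments) as fh:
                    paf = parse_paf(fh)
            else:
                paf = parse_paf(alignments)
    rows = []
    for cid, seq in sequences.items():
        row = {"contig_id": cid, "length": len(seq), "method": "", "assignment": "unresolved",
               "dist_expected": math.nan, "dist_contaminant": math.nan,
               "block_expected": 0, "block_contaminant": 0}
        use_mash = len(seq) >= max(config.small_contig_bp, ref_expected.k)
        if use_mash:
            sk = minhash_sketch(seq, ref_expected.k, config.sketch_size)
            de = mash_distance(sk, ref_expected)
            dc = mash_distance(sk, ref_contaminant)
            row["dist_expected"], row["dist_contaminant"] = de, dc
            if de >= 1.0 and dc >= 1.0:
                use_mash = False  # no shared hashes with either reference
            else:
                row["method"] = "mash"
                if dc < de:
                    row["assignment"] = "contaminant_candidate"
                elif de < dc:
                    row["assignment"] = "expected"
                # equidistant -> unresolved
        if not use_mash:
            row["method"] = "alignment"
            if paf is not None and ref_names:
                sub = paf[paf["query"] == cid]
                be = bc = 0
                for r in sub.itertuples():
                    side = ref_names.get(r.target)
                    if side == "expected":
                        be = be + r.block_len if sum_blocks else max(be, r.block_len)
                    elif side == "contaminant":
                        bc = bc + r.block_len if sum_blocks else max(bc, r.block_len)
                row["block_expected"], row["block_contaminant"] = be, bc
                if bc > be:
                    row["assignment"] = "contaminant_candidate"
                elif be > bc and be > 0:
                    row["assignment"] = "expected"
        rows.append(row)
    return pd.DataFrame(rows)
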