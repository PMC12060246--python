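"""Comparative BUSCO completeness across assemblies.

Works from either per-species category counts (single-copy complete,
duplicated, missing, fragmented) or a full species x BUSCO-id status
matrix. Provides category percentages, cross-species means, upset-style
intersection cardinalities, and the ancestral-loss adjustment: BUSCOs
missing from every species in a clade were plausibly lost in the common
ancestor, so per-species missing counts can be restated net of them.

A counts table for ten Delphinoidea reference assemblies (compleasm,
Laurasiatheria odb10) ships with the package as example data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Mapping

import pandas as pd

CATEGORIES = ("single", "duplicated", "missing", "fragmented")
STATUSES = frozenset(CATEGORIES)


@dataclass
class BuscoTable:
    counts: pd.DataFrame                 # index species, columns CATEGORIES
    status: pd.DataFrame | None = None   # index busco_id, columns species
    lineage: str = ""

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lineage_total(self) -> int:
        totals = self.counts[list(CATEGORIES)].sum(axis=1)
        if totals.nunique() != 1:
            raise ValueError("category counts do not sum to a common lineage total")
        return int(totals.iloc[0])

    @classmethod
    def from_status(cls, status: pd.DataFrame, lineage: str = "") -> "BuscoTable":
        bad = set(status.values.ravel()) - STATUSES
        if bad:
            raise ValueError(f"unknown BUSCO statuses: {sorted(bad)}")
        counts = pd.DataFrame(
            {cat: (status == cat).sum(axis=0) for cat in CATEGORIES}
        )
        counts.index.name = "species"
        return cls(counts=counts, status=status, lineage=lineage)


def load_counts_tsv(path) -> BuscoTable:
    df = pd.read_csv(path, sep="\t").set_index("species")
    return BuscoTable(counts=df[list(CATEGORIES)])


def load_status_tsv(path) -> BuscoTable:
    """Long-format TSV with columns species, busco_id, status."""
    long = pd.read_csv(path, sep="\t")
    status = long.pivot(index="busco_id", columns="species", values="status")
    if status.isna().any().any():
        raise ValueError("inconsistent BUSCO id universes across species")
    return BuscoTable.from_status(status)


def load_reference_counts() -> BuscoTable:
    """The packaged Delphinoidea comparison counts."""
    with resources.files("asmqc.data").joinpath("delphinoidea_busco_counts.tsv").open() as fh:
        return load_counts_tsv(fh)


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def completeness_percentages(counts: pd.DataFrame | Mapping[str, int]) -> pd.DataFrame:
    """Per-category percentages of the four-category total, to 2 decimals
    (half away from zero)."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame([counts])
    counts = counts[list(CATEGORIES)]
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero category total")
    pct = counts.div(totals, axis=0) * 100
    return pct.map(lambda v: _round_half_up(v, 2))


def category_means(
    table: BuscoTable, category: str, include_focal: bool = True, focal: str | None = None
) -> tuple[float, int]:
    """Mean of a category count across species: (raw, rounded-to-integer).

    By default the focal species is part of the average; pass
    ``include_focal=False`` with ``focal`` to leave it out.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    col = table.counts[category]
    if not include_focal:
        if focal is None:
            raise ValueError("focal species required when include_focal=False")
        col = col.drop(index=focal)
    raw = float(col.mean())
    return raw, int(_round_half_up(raw))


def upset_intersections(
    status: pd.DataFrame, status_value: str = "single", top_n: int | None = None
) -> pd.DataFrame:
    """Exact set-partition of BUSCO ids by their per-species status pattern.

    Every BUSCO id lands in exactly one pattern (the tuple of species for
    which its status equals ``status_value``), so cardinalities over all
    patterns sum to the universe size. Returns the ``top_n`` patterns by
    cardinality, ties broken by pattern bit-order (species order).
    """
    if status.isna().any().any():
        raise ValueError("inconsistent BUSCO id universes across species")
    species = list(status.columns)
    mask = status == status_value
    patterns: dict[tuple[bool, ...], int] = {}
    for bits, sub in mask.groupby(list(species)):
        key = bits if isinstance(bits, tuple) else (bits,)
        patterns[tuple(bool(b) for b in key)] = len(sub)
    rows = [
        {
            "pattern": tuple(sp for sp, b in zip(species, bits) if b),
            "bits": bits,
            "n_species": sum(bits),
            "count": n,
        }
        for bits, n in patterns.items()
    ]
    rows.sort(key=lambda r: (-r["count"], tuple(not b for b in r["bits"])))
    df = pd.DataFrame(rows, columns=["pattern", "bits", "n_species", "count"])
    return df.head(top_n) if top_n else df


def ancestral_missing_adjustment(
    table: BuscoTable, missing_in_all: int
) -> tuple[pd.DataFrame, int, tuple[float, int]]:
    """Restate missing counts net of BUSCOs missing in every species.

    Returns (adjusted per-species table, adjusted lineage total,
    (raw mean adjusted missing, rounded)).
    """
    if missing_in_all > int(table.counts["missing"].min()):
        raise ValueError(
            f"missing_in_all={missing_in_all} exceeds some species' missing count"
        )
    adj = table.counts.copy()
    adj["missing_adjusted"] = adj["missing"] - missing_in_all
    total_adj = table.lineage_total - missing_in_all
    raw = float(adj["missing_adjusted"].mean())
    return adj, total_adj, (raw, int(_round_half_up(raw)))
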