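"""Summary tables: clade composition, subspecies cross-tab, polymorphisms.

Percent formatting reproduces the conventions of published organelle
population tables: half-up rounding at the displayed precision, one decimal
at >= 10 % and two decimals below for the composition table, and one
decimal throughout for the subspecies cross-tab (whose denominator is the
number of domesticated accessions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alignment import SUBSPECIES_LABELS
from .scan import PolymorphismRecord

#: display order for the composition table
GROUP_ORDER = (
    ("australian", "Australian"),
    ("wild_asian", "Wild Asian"),
    ("clade_A", "Clade A"),
    ("clade_B", "Clade B"),
    ("african", "African"),
    ("south_american", "South American"),
    ("outgroup", "Out group"),
)

#: display order for the cross-tab
SUBSPECIES_ORDER = (
    ("intermediate", "Intermediate type"),
    ("japonica", "Japonica"),
    ("indica", "Indica"),
    ("tropical_japonica", "Tropical japonica"),
    ("temperate_japonica", "Temperate japonica"),
    ("basmati", "Basmati"),
    ("aus", "Aus"),
    ("none", "Unassigned"),
)


def round_half_up(value: float, ndigits: int = 0) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def composition_percent(count: int, total: int) -> float:
    """Percent of total, 1 decimal at >= 10 %, 2 decimals below."""
    pct = 100.0 * count / total
    return round_half_up(pct, 1 if pct >= 10 else 2)


def clade_share_percent(count: int, clade_size: int) -> int:
    """Whole-percent share of a clade (e.g. the indica share of clade A)."""
    return int(round_half_up(100.0 * count / clade_size, 0))


@dataclass(frozen=True)
class CladeSummaryRow:
    group_label: str
    count: int
    percent: float


@dataclass(frozen=True)
class CrossTabRow:
    subspecies: str
    total: int
    percent_of_domesticated: float
    n_clade_A: int
    n_clade_B: int


def clade_summary(
    metadata: pd.DataFrame, clade_assignment: Mapping[str, str]
) -> list[CladeSummaryRow]:
    """Composition table: one row per wild group plus the two clades.

    Percents are computed over all accessions; the domesticated group is
    reported as its two clades rather than as a single row.
    """
    labels = dict(getattr(clade_assignment, "labels", clade_assignment))
    total = len(metadata)
    group_counts = metadata["group"].value_counts().to_dict()
    counts = {
        "australian": group_counts.get("australian", 0),
        "wild_asian": group_counts.get("wild_asian", 0),
        "clade_A": sum(
            1 for a, g in zip(metadata["accession_id"], metadata["group"])
            if g == "domesticated" and labels.get(a) == "A"
        ),
        "clade_B": sum(
            1 for a, g in zip(metadata["accession_id"], metadata["group"])
            if g == "domesticated" and labels.get(a) == "B"
        ),
        "african": group_counts.get("african", 0),
        "south_american": group_counts.get("south_american", 0),
        "outgroup": group_counts.get("outgroup", 0),
    }
    rows = [
        CladeSummaryRow(key, counts[key], composition_percent(counts[key], total))
        for key, _ in GROUP_ORDER
    ]
    rows.append(CladeSummaryRow("total", total, 100.0))
    return rows


def cross_tabulate(
    metadata: pd.DataFrame,
    clade_assignment: Mapping[str, str],
    domesticated_total: Optional[int] = None,
) -> list[CrossTabRow]:
    """Subspecies cross-tab over the two domesticated clades.

    The percent column uses ``domesticated_total`` (default: the number of
    domesticated accessions in the metadata) as denominator.
    """
    labels = dict(getattr(clade_assignment, "labels", clade_assignment))
    dom = metadata[metadata["group"] == "domesticated"]
    if domesticated_total is None:
        domesticated_total = len(dom)
    rows = []
    for key, _ in SUBSPECIES_ORDER:
        members = dom[dom["subspecies"] == key]
        n_a = sum(1 for a in members["accession_id"] if labels.get(a) == "A")
        n_b = sum(1 for a in members["accession_id"] if labels.get(a) == "B")
        rows.append(
            CrossTabRow(
                subspecies=key,
                total=len(members),
                percent_of_domesticated=round_half_up(
                    100.0 * len(members) / domesticated_total, 1
                ),
                n_clade_A=n_a,
                n_clade_B=n_b,
            )
        )
    return rows


def write_clade_summary(rows: Sequence[CladeSummaryRow], path: str | Path) -> None:
    names = dict(GROUP_ORDER) | {"total": "Total"}
    frame = pd.DataFrame(
        {
            "group": [names.get(r.group_label, r.group_label) for r in rows],
            "n_accessions": [r.count for r in rows],
            "percent": [r.percent for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_cross_tab(rows: Sequence[CrossTabRow], path: str | Path) -> None:
    names = dict(SUBSPECIES_ORDER)
    frame = pd.DataFrame(
        {
            "subspecies": [names.get(r.subspecies, r.subspecies) for r in rows],
            "n_accessions": [r.total for r in rows],
            "percent_of_domesticated": [r.percent_of_domesticated for r in rows],
            "n_clade_A": [r.n_clade_A for r in rows],
            "n_clade_B": [r.n_clade_B for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_polymorphism_table(
    records: Sequence[PolymorphismRecord], path: str | Path
) -> None:
    """Polymorphism table: position, alleles B/A, category, gene, effect.

    The effect cell follows the published vocabulary: full amino-acid names
    for nonsynonymous changes, ``no`` for synonymous, ``RNA`` for tRNA/rRNA
    changes, ``-`` otherwise.
    """
    positions = [r.reference_position or 0 for r in records]
    if positions != sorted(positions):
        warnings.warn("polymorphism records were unsorted; sorting by position")
        records = sorted(records, key=lambda r: r.reference_position or 0)
    rows = []
    for r in records:
        effect = r.effect
        rows.append(
            {
                "position": r.reference_position,
                "alleles_B_A": f"{r.majority_allele('B')}/{r.majority_allele('A')}",
                "category": r.category,
                "gene": (effect.gene_name if effect and effect.gene_name else "-"),
                "effect": effect.describe() if effect else "-",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["position", "alleles_B_A", "category", "gene", "effect"]
    )
    frame.to_csv(path, sep="\t", index=False)
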