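"""Clade-diagnostic scanning of alignment columns.

Every alignment column is tallied separately for the two designated
domesticated clades and classified:

``invariant``
    both clades monomorphic for the same allele;
``fixed_difference``
    both clades monomorphic, for different alleles — a strict diagnostic
    site ("all members of one clade differ from all members of the other");
``mixed``
    exactly one clade polymorphic at the column;
``very_mixed``
    both clades polymorphic;
``uninformative``
    fewer than two usable (non-N) calls in either clade.

Gaps count as a real fifth allele state (deletion alleles are diagnostic
sites too); N is treated as missing and dropped from tallies.  Monomorphism
is strict — a single discordant call demotes a site to mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import ALPHABET, AlignmentMatrix, GAP_CODE, N_CODE
from .annotate import (
    EffectCall,
    GenomeFeature,
    ReferenceGenome,
    locate_feature,
    predict_effect,
)

CATEGORIES = (
    "invariant", "fixed_difference", "mixed", "very_mixed", "uninformative"
)

#: verdicts that count a fixed difference as functionally relevant
FUNCTIONAL_VERDICTS = ("nonsynonymous", "tRNA_change")


@dataclass(frozen=True)
class SiteClassification:
    """Per-column tallies for the two clades and the resulting verdict."""

    column_index: int                      # 1-based alignment column
    reference_position: Optional[int]      # 1-based, None if reference gapped
    counts_A: dict[str, int]
    counts_B: dict[str, int]
    category: str
    effect: Optional[EffectCall] = None

    def majority_allele(self, clade: str) -> str:
        counts = self.counts_A if clade == "A" else self.counts_B
        return max(counts, key=lambda a: (counts[a], -ALPHABET.index(a)))


#: rows of the polymorphism table are site classifications
PolymorphismRecord = SiteClassification


@dataclass
class ScanResult:
    """All non-invariant columns between the two clades."""

    records: list[SiteClassification]
    n_clade_A: int
    n_clade_B: int

    @property
    def n_functional_fixed(self) -> int:
        """Strict fixed differences altering a protein or tRNA sequence."""
        return sum(
            1 for r in self.records
            if r.category == "fixed_difference"
            and r.effect is not None
            and r.effect.verdict in FUNCTIONAL_VERDICTS
        )

    def record_at(self, reference_position: int) -> SiteClassification:
        for record in self.records:
            if record.reference_position == reference_position:
                return record
        raise KeyError(f"no record at reference position {reference_position}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            effect = r.effect
            rows.append(
                {
                    "position": r.reference_position,
                    "column": r.column_index,
                    "alleles_B_A": f"{r.majority_allele('B')}/{r.majority_allele('A')}",
                    "category": r.category,
                    "gene": effect.gene_name if effect and effect.gene_name else "-",
                    "effect": effect.describe() if effect else "-",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["position", "column", "alleles_B_A", "category", "gene", "effect"],
        )


def map_columns_to_reference(
    alignment: AlignmentMatrix, reference_id: str
) -> np.ndarray:
    """Map alignment columns to 1-based reference coordinates.

    Column *j* maps to the number of non-gap reference characters in
    columns ``1..j``; columns where the reference row is a gap map to ``-1``
    (no reference coordinate).
    """
    if reference_id not in alignment:
        raise ValueError(f"reference row {reference_id!r} missing from alignment")
    ref_row = alignment.row(reference_id)
    non_gap = ref_row != GAP_CODE
    positions = np.cumsum(non_gap).astype(np.int64)
    positions[~non_gap] = -1
    return positions


def classify_site(
    counts_A: Mapping[str, int], counts_B: Mapping[str, int]
) -> str:
    """Classify one column from its per-clade allele tallies (pure function)."""
    a = {k: v for k, v in counts_A.items() if k != "N" and v > 0}
    b = {k: v for k, v in counts_B.items() if k != "N" and v > 0}
    if sum(a.values()) < 2 or sum(b.values()) < 2:
        return "uninformative"
    poly_a, poly_b = len(a) > 1, len(b) > 1
    if not poly_a and not poly_b:
        return "invariant" if next(iter(a)) == next(iter(b)) else "fixed_difference"
    if poly_a != poly_b:
        return "mixed"
    return "very_mixed"


def _counts_by_code(block: np.ndarray) -> np.ndarray:
    """(6, n_columns) allele-code tallies for a clade's rows."""
    out = np.empty((len(ALPHABET), block.shape[1]), dtype=np.int64)
    for code in range(len(ALPHABET)):
        out[code] = (block == code).sum(axis=0)
    return out


def scan_alignment(
    alignment: AlignmentMatrix,
    metadata: pd.DataFrame,
    clade_assignment: Mapping[str, str],
    reference: ReferenceGenome,
    features: Sequence[GenomeFeature],
) -> ScanResult:
    """Scan all columns and classify them relative to clades A and B.

    ``clade_assignment`` maps accession ids to ``A``/``B``/``other``; only
    A and B rows enter the tallies.  Fixed-difference and mixed records get
    an :class:`~chloroclade.annotate.EffectCall` against the reference.
    Records come back ordered by reference position.
    """
    labels = dict(getattr(clade_assignment, "labels", clade_assignment))
    missing = sorted(a for a in labels if a not in alignment)
    if missing:
        raise ValueError(
            f"clade assignment names accessions absent from the alignment: "
            f"{missing[:10]}"
        )
    meta_missing = sorted(
        a for a in metadata["accession_id"] if a not in alignment
    )
    if meta_missing:
        raise ValueError(
            f"metadata names accessions absent from the alignment: "
            f"{meta_missing[:10]}"
        )
    ids_a = [a for a in alignment.ids if labels.get(a) == "A"]
    ids_b = [a for a in alignment.ids if labels.get(a) == "B"]
    if not ids_a or not ids_b:
        raise ValueError("both clades need at least one assigned accession")

    if reference.id in alignment:
        col_to_ref = map_columns_to_reference(alignment, reference.id)
    elif alignment.n_columns == reference.length:
        col_to_ref = np.arange(1, alignment.n_columns + 1, dtype=np.int64)
    else:
        raise ValueError(
            "reference row absent and alignment width differs from the "
            "reference length; cannot map columns to coordinates"
        )

    counts_a = _counts_by_code(alignment.rows(ids_a))
    counts_b = _counts_by_code(alignment.rows(ids_b))

    real_a = counts_a[:5]          # A,C,G,T,- tallies (N dropped)
    real_b = counts_b[:5]
    usable_a = real_a.sum(axis=0)
    usable_b = real_b.sum(axis=0)
    n_alleles_a = (real_a > 0).sum(axis=0)
    n_alleles_b = (real_b > 0).sum(axis=0)
    mono_allele_a = real_a.argmax(axis=0)
    mono_allele_b = real_b.argmax(axis=0)

    uninformative = (usable_a < 2) | (usable_b < 2)
    both_mono = (n_alleles_a == 1) & (n_alleles_b == 1)
    invariant = both_mono & (mono_allele_a == mono_allele_b)
    fixed = both_mono & ~invariant
    one_poly = (n_alleles_a > 1) != (n_alleles_b > 1)
    both_poly = (n_alleles_a > 1) & (n_alleles_b > 1)

    category = np.full(alignment.n_columns, "invariant", dtype=object)
    category[fixed] = "fixed_difference"
    category[one_poly] = "mixed"
    category[both_poly] = "very_mixed"
    varies = (n_alleles_a + n_alleles_b) > 0
    varies &= ~invariant
    category[uninformative] = "uninformative"

    keep = np.nonzero(
        (~uninformative & (fixed | one_poly | both_poly))
        | (uninformative & ~invariant & ((n_alleles_a > 1) | (n_alleles_b > 1)
                                         | (mono_allele_a != mono_allele_b)))
    )[0]

    records: list[SiteClassification] = []
    for col in keep:
        cA = {
            ALPHABET[code]: int(real_a[code, col])
            for code in range(5) if real_a[code, col] > 0
        }
        cB = {
            ALPHABET[code]: int(real_b[code, col])
            for code in range(5) if real_b[code, col] > 0
        }
        cat = str(category[col])
        ref_pos = int(col_to_ref[col])
        effect = None
        if cat in ("fixed_difference", "mixed") and ref_pos > 0:
            ref_base = reference.base(ref_pos)
            union = {}
            for allele, n in list(cA.items()) + list(cB.items()):
                union[allele] = union.get(allele, 0) + n
            union.pop(ref_base, None)
            if union:
                alt = max(
                    union, key=lambda a: (union[a], -ALPHABET.index(a))
                )
                effect = predict_effect(
                    reference, features, ref_pos, ref_base, alt
                )
        records.append(
            SiteClassification(
                column_index=int(col) + 1,
                reference_position=ref_pos if ref_pos > 0 else None,
                counts_A=cA,
                counts_B=cB,
                category=cat,
                effect=effect,
            )
        )

    records.sort(
        key=lambda r: (
            r.reference_position is None,
            r.reference_position or 0,
            r.column_index,
        )
    )
    return ScanResult(records=records, n_clade_A=len(ids_a), n_clade_B=len(ids_b))
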