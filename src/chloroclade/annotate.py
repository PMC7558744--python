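"""Reference genome model, feature map, and point-variant effect prediction.

The reference genome is a plain ACGT string with 1-based coordinates, the
convention used for organelle variant tables.  Features (CDS, tRNA, rRNA,
introns) are interval annotations against that coordinate frame; anything
not covered is intergenic.  For a single-position allele change the module
reconstructs the affected codon (strand- and phase-aware) and reports
whether the change is nonsynonymous, synonymous, an RNA-gene change, or an
indel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable

#: distinguished symbol for a stop codon in single-letter amino-acid output
STOP = "*"

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "intron", "intergenic")
#: overlap resolution order: a CDS call beats an overlapping RNA or intron call
FEATURE_PRIORITY = {cls: rank for rank, cls in enumerate(FEATURE_CLASSES)}

VERDICTS = (
    "nonsynonymous",
    "synonymous",
    "tRNA_change",
    "rRNA_change",
    "intron_change",
    "intergenic",
    "indel",
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)

#: full amino-acid names, for human-readable effect descriptions
AMINO_ACID_NAMES = {
    "A": "alanine", "R": "arginine", "N": "asparagine", "D": "aspartic acid",
    "C": "cysteine", "Q": "glutamine", "E": "glutamic acid", "G": "glycine",
    "H": "histidine", "I": "isoleucine", "L": "leucine", "K": "lysine",
    "M": "methionine", "F": "phenylalanine", "P": "proline", "S": "serine",
    "T": "threonine", "W": "tryptophan", "Y": "tyrosine", "V": "valine",
    STOP: "stop",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """The stated reference allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A chloroplast-style reference sequence (1-based coordinates)."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(f"reference contains non-ACGT characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature: a gene's exon set on the reference.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals stored in
    strand 5'->3' order (ascending for ``+``, descending for ``-``).
    ``phase`` is the codon offset of the first exonic base (CDS only).
    """

    gene_name: Optional[str]
    feature_class: str
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    phase: int = 0

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.phase <= 2:
            raise ValueError("phase must be 0, 1 or 2")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon start {start} > end {end}")
            key = start if self.strand == "+" else -start
            if prev_end is not None and key <= prev_end:
                raise ValueError("exons must be non-overlapping and in strand order")
            prev_end = (end if self.strand == "+" else -end)
        if self.feature_class == "CDS" and self.exons:
            if (self.exonic_length - self.phase) % 3 != 0:
                raise ValueError(
                    f"CDS {self.gene_name}: exonic length {self.exonic_length} "
                    f"minus phase {self.phase} is not a multiple of 3"
                )

    @property
    def exonic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.exons)

    def coding_index(self, position: int) -> int:
        """0-based index of a genomic position along the 5'->3' exonic walk."""
        offset = 0
        for start, end in self.exons:
            if start <= position <= end:
                if self.strand == "+":
                    return offset + (position - start)
                return offset + (end - position)
            offset += end - start + 1
        raise ValueError(f"position {position} not exonic in {self.gene_name}")

    def genomic_position(self, coding_index: int) -> int:
        """Inverse of :meth:`coding_index`."""
        offset = 0
        for start, end in self.exons:
            length = end - start + 1
            if coding_index < offset + length:
                within = coding_index - offset
                return start + within if self.strand == "+" else end - within
            offset += length
        raise IndexError(f"coding index {coding_index} beyond {self.gene_name}")


INTERGENIC = GenomeFeature(gene_name=None, feature_class="intergenic")


@dataclass(frozen=True)
class EffectCall:
    """Predicted impact of a single-position allele change."""

    position: int
    ref_allele: str
    alt_allele: str
    gene_name: Optional[str]
    feature_class: str
    verdict: str
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None

    def describe(self) -> str:
        """Human-readable effect, e.g. ``'Tryptophan to leucine'``."""
        if self.verdict == "nonsynonymous":
            return (
                f"{AMINO_ACID_NAMES[self.aa_ref].capitalize()} to "
                f"{AMINO_ACID_NAMES[self.aa_alt]}"
            )
        if self.verdict == "synonymous":
            return "no"
        if self.verdict in ("tRNA_change", "rRNA_change"):
            return "RNA"
        return "-"


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns a single-letter amino acid, or :data:`STOP` for a stop codon.
    """
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid codon {codon!r}: need 3 characters from ACGT")
    if codon in _STOP_CODONS:
        return STOP
    return _CODON_TABLE.forward_table[codon]


def locate_feature(
    features: Sequence[GenomeFeature], position: int, genome_length: int | None = None
) -> GenomeFeature:
    """Find the feature containing a position.

    Overlaps resolve by class priority (CDS > tRNA > rRNA > intron), then by
    leftmost feature start; positions covered by nothing are intergenic.
    """
    if position < 1 or (genome_length is not None and position > genome_length):
        raise IndexError(f"position {position} outside genome")
    hits = [f for f in features if f.contains(position)]
    if not hits:
        return INTERGENIC
    return min(
        hits,
        key=lambda f: (
            FEATURE_PRIORITY[f.feature_class],
            min(s for s, _ in f.exons),
            f.gene_name or "",
        ),
    )


def predict_effect(
    reference: ReferenceGenome,
    features: Sequence[GenomeFeature],
    position: int,
    ref_allele: str,
    alt_allele: str,
) -> EffectCall:
    """Predict the functional impact of ``ref_allele -> alt_allele``.

    For CDS substitutions the codon is rebuilt in coding orientation
    (reverse-complemented for minus-strand genes) and both versions are
    translated.  Any gap allele short-circuits to an indel verdict.
    """
    if not 1 <= position <= reference.length:
        raise IndexError(f"position {position} outside [1, {reference.length}]")
    for name, allele in (("ref", ref_allele), ("alt", alt_allele)):
        if allele not in ("A", "C", "G", "T", "-"):
            raise ValueError(f"{name} allele {allele!r} not in {{A,C,G,T,-}}")
    if ref_allele != "-" and ref_allele != reference.base(position):
        raise ReferenceMismatchError(
            f"position {position}: stated reference allele {ref_allele!r} "
            f"!= reference base {reference.base(position)!r}"
        )
    if ref_allele == alt_allele:
        raise ValueError(f"position {position}: ref and alt alleles are identical")

    feature = locate_feature(features, position, reference.length)
    gene = feature.gene_name
    fclass = feature.feature_class

    if "-" in (ref_allele, alt_allele):
        return EffectCall(position, ref_allele, alt_allele, gene, fclass, "indel")

    if fclass == "CDS":
        idx = feature.coding_index(position)
        if idx < feature.phase:
            raise ValueError(
                f"position {position} falls in the partial leading codon of "
                f"{gene} (phase {feature.phase})"
            )
        codon_number = (idx - feature.phase) // 3
        codon_offset = (idx - feature.phase) % 3
        start_idx = feature.phase + 3 * codon_number
        genomic = [feature.genomic_position(start_idx + k) for k in range(3)]
        bases = [reference.base(p) for p in genomic]
        if feature.strand == "-":
            bases = [b.translate(_COMPLEMENT) for b in bases]
            alt_coding = alt_allele.translate(_COMPLEMENT)
        else:
            alt_coding = alt_allele
        codon_ref = "".join(bases)
        codon_alt = (
            codon_ref[:codon_offset] + alt_coding + codon_ref[codon_offset + 1:]
        )
        aa_ref = translate_codon(codon_ref)
        aa_alt = translate_codon(codon_alt)
        verdict = "nonsynonymous" if aa_ref != aa_alt else "synonymous"
        return EffectCall(
            position, ref_allele, alt_allele, gene, fclass, verdict,
            codon_ref=codon_ref, codon_alt=codon_alt, aa_ref=aa_ref, aa_alt=aa_alt,
        )

    verdict = {
        "tRNA": "tRNA_change",
        "rRNA": "rRNA_change",
        "intron": "intron_change",
        "intergenic": "intergenic",
    }[fclass]
    return EffectCall(position, ref_allele, alt_allele, gene, fclass, verdict)


# -- feature map I/O ---------------------------------------------------------
# GFF3-like TSV, one row per exon:
#   gene  class  strand  exon_start  exon_end  phase

_FEATURE_COLUMNS = ("gene", "class", "strand", "exon_start", "exon_end", "phase")


def write_feature_map(features: Iterable[GenomeFeature], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_FEATURE_COLUMNS)
        for feat in features:
            for start, end in feat.exons:
                writer.writerow(
                    [feat.gene_name or ".", feat.feature_class, feat.strand,
                     start, end, feat.phase]
                )


def read_feature_map(path: str | Path) -> list[GenomeFeature]:
    grouped: dict[tuple, list[tuple[int, int]]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_FEATURE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"feature map missing columns: {sorted(missing)}")
        for row in reader:
            gene = None if row["gene"] in (".", "") else row["gene"]
            key = (gene, row["class"], row["strand"], int(row["phase"]))
            grouped.setdefault(key, []).append(
                (int(row["exon_start"]), int(row["exon_end"]))
            )
    features = []
    for (gene, fclass, strand, phase), exons in grouped.items():
        exons.sort(reverse=(strand == "-"))
        features.append(
            GenomeFeature(gene, fclass, strand, tuple(exons), phase)
        )
    return features
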