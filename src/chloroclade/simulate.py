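"""Seeded synthetic chloroplast populations with planted polymorphisms.

A population is generated on a fixed, non-recombining lineage topology::

    (((clade_A(+african), clade_B), wild_asian), australian), south_american, outgroup

Consensus sequences for each lineage are evolved from a random reference by
independent-site substitution (transition:transversion weighting 2:1), then
every planted diagnostic site is overwritten with exact alleles: the clade-A
consensus carries ``allele_A``, clade B carries ``allele_B``, and a seeded
sample of accessions inside each clade carries the opposite allele to
realise "mixed" sites with exact within-clade tallies.  Each accession
additionally receives private mutations at a configurable rate.

The packaged default configuration encodes the published polymorphism table
for the two domesticated rice chloroplast clades (clade sizes 1486 and 1532,
52 diagnostic positions including the psbB site with 88 of 1486 clade-A
accessions carrying the clade-B allele) together with the published
per-clade subspecies composition.  Sequences are emitted gap-free except for
planted deletion alleles, so alignment columns correspond to reference
coordinates by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import (
    ALPHABET,
    AlignmentMatrix,
    GAP_CODE,
    decode_sequence,
    encode_sequence,
    write_metadata,
)
from .annotate import (
    GenomeFeature,
    ReferenceGenome,
    reverse_complement,
    translate_codon,
    write_feature_map,
)

#: coordinate span of the real reference the default positions refer to
REFERENCE_SPAN = 135000

#: lineage branch names accepted in ``background_divergence`` (subs/site)
BRANCH_NAMES = (
    "outgroup",
    "south_american",
    "stem_australian",
    "australian",
    "stem_asian",
    "wild_asian",
    "stem_domesticated",
    "clade_A",
    "clade_B",
    "african",
)

# Within-clade diversity ~1e-4 subs/site, clade A-vs-B divergence 5e-3
# (clade_A + clade_B), progressively deeper toward the wild taxa and the
# outgroup.  These are defaults for tests and demonstrations, not estimates.
DEFAULT_BACKGROUND = {
    "outgroup": 0.020,
    "south_american": 0.015,
    "stem_australian": 0.002,
    "australian": 0.008,
    "stem_asian": 0.002,
    "wild_asian": 0.004,
    "stem_domesticated": 0.002,
    "clade_A": 0.0025,
    "clade_B": 0.0025,
    "african": 0.0005,
}
DEFAULT_PRIVATE_RATE = 1e-4

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero at the cut digit)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


class ConfigError(ValueError):
    """The population configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedSite:
    """One diagnostic alignment position planted into the population.

    ``allele_B`` is the reference-side allele (the clade-B consensus state);
    ``allele_A`` is the clade-A consensus state.  The ``within_*_alt_count``
    fields give how many accessions of a clade carry the *other* clade's
    allele, producing a "mixed" site with exact tallies.
    """

    position: int
    allele_A: str
    allele_B: str
    within_A_alt_count: int = 0
    within_B_alt_count: int = 0

    def __post_init__(self):
        for allele in (self.allele_A, self.allele_B):
            if allele not in ("A", "C", "G", "T", "-"):
                raise ConfigError(f"planted allele {allele!r} not in {{A,C,G,T,-}}")
        if self.allele_A == self.allele_B:
            raise ConfigError(
                f"planted site {self.position}: clade alleles must differ"
            )
        if self.position < 1:
            raise ConfigError("planted position must be >= 1")
        if min(self.within_A_alt_count, self.within_B_alt_count) < 0:
            raise ConfigError("within-clade alt counts must be >= 0")


class CodonDesign(NamedTuple):
    """Reference codon to install around a planted CDS site.

    ``codon`` is given in coding orientation; ``offset`` is the 0-based
    codon position of the planted site.
    """

    gene: str
    position: int
    codon: str
    offset: int


@dataclass
class PopulationConfig:
    """Everything needed to regenerate one synthetic population."""

    seed: int
    genome_length: int
    n_clade_A: int
    n_clade_B: int
    n_wild_asian: int = 0
    n_australian: int = 0
    n_african: int = 0
    n_south_american: int = 0
    n_outgroup: int = 0
    planted_sites: list[PlantedSite] = field(default_factory=list)
    background_divergence: dict[str, float] = field(default_factory=dict)
    private_mutation_rate: float = 0.0
    subspecies_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    feature_map: list[GenomeFeature] = field(default_factory=list)
    codon_designs: list[CodonDesign] = field(default_factory=list)
    reference_id: str = "REF"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = [
            self.n_clade_A, self.n_clade_B, self.n_wild_asian, self.n_australian,
            self.n_african, self.n_south_american, self.n_outgroup,
        ]
        if any(n < 0 for n in counts):
            raise ConfigError("group sizes must be >= 0")
        if self.genome_length < 1:
            raise ConfigError("genome_length must be >= 1")
        positions = [s.position for s in self.planted_sites]
        if len(set(positions)) != len(positions):
            raise ConfigError("planted positions must be unique")
        for site in self.planted_sites:
            if site.position > self.genome_length:
                raise ConfigError(
                    f"planted position {site.position} beyond genome length "
                    f"{self.genome_length}"
                )
            if site.within_A_alt_count > self.n_clade_A:
                raise ConfigError(
                    f"site {site.position}: within_A_alt_count exceeds clade A size"
                )
            if site.within_B_alt_count > self.n_clade_B:
                raise ConfigError(
                    f"site {site.position}: within_B_alt_count exceeds clade B size"
                )
        unknown = set(self.background_divergence) - set(BRANCH_NAMES)
        if unknown:
            raise ConfigError(f"unknown lineage branches: {sorted(unknown)}")
        for clade, table in self.subspecies_proportions.items():
            total = sum(table.values())
            if table and abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"subspecies proportions for clade {clade} sum to {total}"
                )
        for feat in self.feature_map:
            for start, end in feat.exons:
                if not 1 <= start <= end <= self.genome_length:
                    raise ConfigError(
                        f"feature {feat.gene_name} exon ({start},{end}) outside genome"
                    )

    @property
    def n_domesticated(self) -> int:
        return self.n_clade_A + self.n_clade_B

    @property
    def n_total(self) -> int:
        return (
            self.n_domesticated + self.n_wild_asian + self.n_australian
            + self.n_african + self.n_south_american + self.n_outgroup
        )

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "group_sizes": {
                "clade_A": self.n_clade_A, "clade_B": self.n_clade_B,
                "wild_asian": self.n_wild_asian, "australian": self.n_australian,
                "african": self.n_african, "south_american": self.n_south_american,
                "outgroup": self.n_outgroup,
            },
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "background_divergence": dict(self.background_divergence),
            "private_mutation_rate": self.private_mutation_rate,
            "subspecies_proportions": {
                k: dict(v) for k, v in self.subspecies_proportions.items()
            },
            "feature_map": [
                {
                    "gene": f.gene_name, "class": f.feature_class,
                    "strand": f.strand, "exons": [list(e) for e in f.exons],
                    "phase": f.phase,
                }
                for f in self.feature_map
            ],
            "codon_designs": [list(d) for d in self.codon_designs],
            "reference_id": self.reference_id,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationConfig":
        sizes = data.get("group_sizes", {})
        return cls(
            seed=int(data["seed"]),
            genome_length=int(data["genome_length"]),
            n_clade_A=int(sizes.get("clade_A", 0)),
            n_clade_B=int(sizes.get("clade_B", 0)),
            n_wild_asian=int(sizes.get("wild_asian", 0)),
            n_australian=int(sizes.get("australian", 0)),
            n_african=int(sizes.get("african", 0)),
            n_south_american=int(sizes.get("south_american", 0)),
            n_outgroup=int(sizes.get("outgroup", 0)),
            planted_sites=[PlantedSite(**s) for s in data.get("planted_sites", [])],
            background_divergence=dict(data.get("background_divergence", {})),
            private_mutation_rate=float(data.get("private_mutation_rate", 0.0)),
            subspecies_proportions={
                k: dict(v)
                for k, v in data.get("subspecies_proportions", {}).items()
            },
            feature_map=[
                GenomeFeature(
                    f["gene"], f["class"], f["strand"],
                    tuple(tuple(e) for e in f["exons"]), f.get("phase", 0),
                )
                for f in data.get("feature_map", [])
            ],
            codon_designs=[CodonDesign(*d) for d in data.get("codon_designs", [])],
            reference_id=data.get("reference_id", "REF"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


# ---------------------------------------------------------------------------
# The published polymorphism table between the two domesticated clades.
# Alleles are printed clade-B-first ("B/A"); the reference carries the
# clade-B state.  ``codon``/``offset`` give the reference codon (coding
# orientation) installed around CDS sites so the designed amino-acid effect
# is reproduced exactly; synonymous sites sit at the third position of a
# four-fold degenerate alanine codon.
# ---------------------------------------------------------------------------

class _Row(NamedTuple):
    positions: tuple[int, ...]
    alleles_B: str
    alleles_A: str
    gene: Optional[str]
    fclass: str
    strand: str = "+"
    codon: Optional[str] = None
    offset: int = 0
    mixing: str = "fixed"          # fixed | mixed | very_mixed


_TABLE3_ROWS: tuple[_Row, ...] = (
    _Row((412,), "T", "C", "psbA", "CDS", codon="GCT", offset=2),
    _Row((4547,), "G", "T", "rps16", "CDS", codon="GCG", offset=2),
    _Row((6282,), "T", "C", None, "intergenic"),
    _Row((6608,), "G", "T", None, "intergenic"),
    _Row((7134,), "T", "C", "psbK", "CDS", codon="GCT", offset=2),
    _Row((8127,), "A", "G", None, "intergenic"),
    _Row((8599,), "G", "A", None, "intergenic", mixing="mixed"),
    _Row((12496,), "A", "G", None, "intergenic"),
    _Row((12799,), "G", "A", "trnM-CAU", "intron"),
    _Row((12819, 12820), "TA", "CC", None, "intergenic"),
    _Row((13468,), "A", "T", None, "intergenic"),
    _Row((14231,), "A", "G", "trnl", "tRNA"),
    _Row((15908,), "T", "A", "trnY-GUA", "intron", mixing="mixed"),
    _Row((17203,), "A", "G", None, "intergenic"),
    _Row((17746, 17747), "GG", "AA", None, "intergenic"),
    _Row((18479,), "T", "G", None, "intergenic"),
    _Row((18520,), "G", "A", None, "intergenic"),
    _Row((20587,), "T", "A", "rpoB", "CDS", codon="GCT", offset=2),
    # Trp -> Leu: TGG -> TTG, site at codon position 2
    _Row((28019,), "G", "T", "rpoC2", "CDS", codon="TGG", offset=1),
    # Asn -> Asp: AAT -> GAT, site at codon position 1
    _Row((29113,), "A", "G", "rpoC2", "CDS", codon="AAT", offset=0),
    _Row((35382,), "G", "A", "atpA", "CDS", codon="GCG", offset=2),
    _Row((49856,), "C", "T", None, "intergenic"),
    _Row((50250,), "A", "C", None, "intergenic"),
    _Row((51349,), "T", "A", "trnS-ACU", "intron", mixing="mixed"),
    _Row((52147,), "C", "T", "atpB", "CDS", codon="GCC", offset=2, mixing="mixed"),
    _Row((53521,), "C", "T", None, "intergenic"),
    _Row((55788,), "G", "T", None, "intergenic"),
    _Row((56588,), "T", "C", "Acetyl-CoA", "CDS", codon="GCT", offset=2),
    _Row((56861,), "C", "T", "Acetyl-CoA", "CDS", codon="GCC", offset=2),
    _Row((60995,), "T", "G", None, "intergenic"),
    _Row((64166,), "C", "A", None, "intergenic"),
    # Ser -> Pro on the minus strand: coding TCT -> CCT, genomic A -> G
    _Row((66402,), "A", "G", "rpl20", "CDS", strand="-", codon="TCT", offset=0),
    # Ala -> Val: GCT -> GTT; polymorphic inside clade A (88 of 1486 carry C)
    _Row((69349,), "C", "T", "psbB", "CDS", codon="GCT", offset=1, mixing="mixed"),
    _Row((74268,), "A", "C", None, "intergenic", mixing="mixed"),
    _Row((77793,), "G", "A", "rpl16", "CDS", codon="GCG", offset=2),
    _Row((93081, 93082, 93083), "AAA", "TTT", None, "intergenic"),
    _Row((102927,), "C", "T", "ndhF", "CDS", codon="GCC", offset=2),
    _Row((104286,), "G", "A", None, "intergenic"),
    _Row((106348,), "G", "T", None, "intergenic"),
    _Row((108269,), "G", "A", None, "intergenic"),
    _Row((108662,), "C", "-", None, "intergenic"),
    _Row((109142,), "A", "G", None, "intergenic"),
    _Row((113077,), "G", "T", "ndhH", "CDS", codon="GCG", offset=2),
    _Row((122035, 122036, 122037), "TTT", "AAA", None, "intergenic"),
    _Row((125723,), "A", "G", None, "intergenic", mixing="very_mixed"),
    _Row((125779,), "G", "T", None, "intergenic", mixing="very_mixed"),
    _Row((125800,), "G", "A", None, "intergenic", mixing="very_mixed"),
)

#: the psbB-analog mixed site: 88 of 1486 clade-A accessions carry the
#: clade-B allele C, the other 1398 carry T; clade B is monomorphic C.
PSBB_POSITION = 69349
PSBB_WITHIN_A_ALT = 88

# published clade sizes and wild-group counts
CLADE_A_SIZE = 1486
CLADE_B_SIZE = 1532
WILD_GROUP_SIZES = {
    "wild_asian": 31, "australian": 33, "african": 5,
    "south_american": 3, "outgroup": 1,
}

# published per-clade subspecies counts; the remainder of each clade
# (1 in A, 19 in B) carries no subspecies assignment
CLADE_A_SUBSPECIES = {
    "intermediate": 61, "japonica": 8, "indica": 1203,
    "tropical_japonica": 24, "temperate_japonica": 37,
    "basmati": 10, "aus": 142, "none": 1,
}
CLADE_B_SUBSPECIES = {
    "intermediate": 74, "japonica": 124, "indica": 538,
    "tropical_japonica": 364, "temperate_japonica": 282,
    "basmati": 58, "aus": 73, "none": 19,
}

# fraction of the polymorphic clade carrying the minority allele at mixed /
# very-mixed sites whose exact tallies are not published
_UNSPECIFIED_MINOR_FRACTION = 0.1


class _SiteSpec(NamedTuple):
    """Internal, fully expanded per-column description of a planted site."""

    position: int
    allele_B: str
    allele_A: str
    gene: Optional[str]
    fclass: str
    strand: str
    codon: Optional[str]
    offset: int
    mixing: str


def _expand_rows(genome_length: int) -> list[_SiteSpec]:
    specs: list[_SiteSpec] = []
    for row in _TABLE3_ROWS:
        for k, pos in enumerate(row.positions):
            specs.append(
                _SiteSpec(
                    pos, row.alleles_B[k], row.alleles_A[k], row.gene,
                    row.fclass, row.strand, row.codon if len(row.positions) == 1
                    else None, row.offset, row.mixing,
                )
            )
    specs.sort(key=lambda s: s.position)
    if genome_length != REFERENCE_SPAN:
        margin, gap = 60, 40
        span = genome_length - 2 * margin
        needed = margin + gap * len(specs)
        if span <= 0 or needed > genome_length:
            raise ConfigError(
                f"genome length {genome_length} too short for "
                f"{len(specs)} planted sites"
            )
        scaled: list[int] = []
        for spec in specs:
            raw = margin + round(spec.position * span / REFERENCE_SPAN)
            if scaled and raw < scaled[-1] + gap:
                raw = scaled[-1] + gap
            scaled.append(raw)
        if scaled[-1] > genome_length - margin:
            raise ConfigError(
                f"genome length {genome_length} too short for the scaled layout"
            )
        specs = [s._replace(position=p) for s, p in zip(specs, scaled)]
    return specs


def _layout_features(specs: Sequence[_SiteSpec]) -> tuple[
    list[GenomeFeature], list[CodonDesign]
]:
    """Build a feature map placing every planted site in its feature class."""
    features: list[GenomeFeature] = []
    designs: list[CodonDesign] = []

    cds_sites: dict[str, list[_SiteSpec]] = {}
    for spec in specs:
        if spec.fclass == "CDS":
            cds_sites.setdefault(spec.gene, []).append(spec)
        elif spec.fclass == "tRNA":
            features.append(
                GenomeFeature(spec.gene, "tRNA", spec.strand,
                              ((spec.position - 10, spec.position + 10),))
            )
        elif spec.fclass == "rRNA":
            features.append(
                GenomeFeature(spec.gene, "rRNA", spec.strand,
                              ((spec.position - 10, spec.position + 10),))
            )
        elif spec.fclass == "intron":
            features.append(
                GenomeFeature(spec.gene, "intron", spec.strand,
                              ((spec.position - 5, spec.position + 5),))
            )

    for gene, sites in cds_sites.items():
        strand = sites[0].strand
        exons = []
        # one exon per site, each a multiple of 3 long, so cumulative coding
        # offsets stay congruent to the designed codon positions
        ordered = sorted(sites, key=lambda s: s.position, reverse=(strand == "-"))
        for spec in ordered:
            a = spec.offset + 3          # coding index of the site within its exon
            length = 3 * math.ceil((a + 3) / 3)
            if strand == "+":
                start = spec.position - a
                end = start + length - 1
            else:
                end = spec.position + a
                start = end - length + 1
            exons.append((start, end))
            designs.append(CodonDesign(gene, spec.position, spec.codon, spec.offset))
        exons.sort(reverse=(strand == "-"))
        features.append(GenomeFeature(gene, "CDS", strand, tuple(exons), phase=0))

    # sanity: features must not overlap one another
    intervals = sorted(
        (start, end, f.gene_name) for f in features for start, end in f.exons
    )
    for (s1, e1, g1), (s2, e2, g2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ConfigError(
                f"feature layout collision between {g1} and {g2} at {s2}"
            )
    return features, designs


def _scale_count(n: int, factor: float) -> int:
    if factor == 1:
        return n
    scaled = int(round_half_up(n / factor))
    return max(1, scaled) if n > 0 else 0


def default_table3_config(
    genome_length: int = REFERENCE_SPAN,
    scale: float = 1,
    zero_background: bool = False,
    seed: int = 1,
) -> PopulationConfig:
    """The packaged configuration encoding the published polymorphism table.

    Parameters
    ----------
    genome_length
        Reference length in bases.  At the default (135 kb) the planted
        sites sit at their printed coordinates; shorter genomes remap the
        positions order-preservingly onto the smaller span.
    scale
        Divide every group size (and the mixed-site carrier counts) by this
        factor, rounding half-up, for fast scaled-down runs.  Non-empty
        groups keep at least one member.
    zero_background
        Zero out all background divergence and private mutation, leaving
        the planted sites as the only variable columns.
    """
    specs = _expand_rows(genome_length)
    features, designs = _layout_features(specs)

    n_a = _scale_count(CLADE_A_SIZE, scale)
    n_b = _scale_count(CLADE_B_SIZE, scale)

    planted: list[PlantedSite] = []
    for spec in specs:
        within_a = within_b = 0
        if spec.mixing == "mixed":
            if spec.gene == "psbB":
                within_a = _scale_count(PSBB_WITHIN_A_ALT, scale)
            else:
                within_a = max(1, int(round_half_up(_UNSPECIFIED_MINOR_FRACTION * n_a)))
        elif spec.mixing == "very_mixed":
            within_a = max(1, int(round_half_up(_UNSPECIFIED_MINOR_FRACTION * n_a)))
            within_b = max(1, int(round_half_up(_UNSPECIFIED_MINOR_FRACTION * n_b)))
        planted.append(
            PlantedSite(
                position=spec.position,
                allele_A=spec.allele_A,
                allele_B=spec.allele_B,
                within_A_alt_count=within_a,
                within_B_alt_count=within_b,
            )
        )

    background = (
        {name: 0.0 for name in BRANCH_NAMES}
        if zero_background else dict(DEFAULT_BACKGROUND)
    )
    return PopulationConfig(
        seed=seed,
        genome_length=genome_length,
        n_clade_A=n_a,
        n_clade_B=n_b,
        n_wild_asian=_scale_count(WILD_GROUP_SIZES["wild_asian"], scale),
        n_australian=_scale_count(WILD_GROUP_SIZES["australian"], scale),
        n_african=_scale_count(WILD_GROUP_SIZES["african"], scale),
        n_south_american=_scale_count(WILD_GROUP_SIZES["south_american"], scale),
        n_outgroup=_scale_count(WILD_GROUP_SIZES["outgroup"], scale),
        planted_sites=planted,
        background_divergence=background,
        private_mutation_rate=0.0 if zero_background else DEFAULT_PRIVATE_RATE,
        subspecies_proportions={
            "A": {k: v / CLADE_A_SIZE for k, v in CLADE_A_SUBSPECIES.items()},
            "B": {k: v / CLADE_B_SIZE for k, v in CLADE_B_SUBSPECIES.items()},
        },
        feature_map=features,
        codon_designs=designs,
    )


def psbb_analog_position(config: PopulationConfig) -> int:
    """Planted position of the psbB-analog mixed site in a packaged config."""
    psbb = [d for d in config.codon_designs if d.gene == "psbB"]
    if not psbb:
        raise ValueError("config has no psbB design")
    return psbb[0].position


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng(config: PopulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_reference(
    config: PopulationConfig,
) -> tuple[ReferenceGenome, list[GenomeFeature]]:
    """Draw the seeded random reference consistent with the feature map.

    Planted positions carry the clade-B (reference-side) allele, designed
    codons are installed around planted CDS sites, and every other CDS codon
    is redrawn until stop-free, so each CDS translates without an internal
    stop.  Deterministic for a fixed config seed.
    """
    rng = _rng(config, 101)
    codes = rng.integers(0, 4, config.genome_length, dtype=np.uint8)

    planted_pos = {s.position for s in config.planted_sites}
    for site in config.planted_sites:
        base = site.allele_B if site.allele_B != "-" else site.allele_A
        codes[site.position - 1] = _CODE[base]

    designs = {d.position: d for d in config.codon_designs}
    designed_positions: set[int] = set()
    features_by_gene = {f.gene_name: f for f in config.feature_map
                        if f.feature_class == "CDS"}
    for design in config.codon_designs:
        feat = features_by_gene.get(design.gene)
        if feat is None:
            raise ConfigError(f"codon design for unknown CDS {design.gene!r}")
        idx = feat.coding_index(design.position)
        codon_start = feat.phase + 3 * ((idx - feat.phase) // 3)
        if (idx - feat.phase) % 3 != design.offset:
            raise ConfigError(
                f"{design.gene}: site {design.position} not at codon "
                f"offset {design.offset} under the feature layout"
            )
        if translate_codon(design.codon) == "*":
            raise ConfigError(f"designed codon {design.codon} is a stop")
        for k in range(3):
            pos = feat.genomic_position(codon_start + k)
            base = design.codon[k]
            if feat.strand == "-":
                base = reverse_complement(base)
            codes[pos - 1] = _CODE[base]
            designed_positions.add(pos)

    # consistency: the designed codon must carry the planted reference allele
    for design in config.codon_designs:
        site = next(
            (s for s in config.planted_sites if s.position == design.position), None
        )
        if site is not None and site.allele_B != "-":
            if decode_sequence(codes[design.position - 1: design.position]) != site.allele_B:
                raise ConfigError(
                    f"designed codon at {design.position} conflicts with the "
                    f"planted reference allele"
                )

    # stop-free CDS: redraw any remaining internal stop codon
    for feat in config.feature_map:
        if feat.feature_class != "CDS":
            continue
        coding_len = feat.exonic_length - feat.phase
        for codon_number in range(coding_len // 3):
            start_idx = feat.phase + 3 * codon_number
            genomic = [feat.genomic_position(start_idx + k) for k in range(3)]
            if any(p in designed_positions for p in genomic):
                continue
            fixed = {k: p for k, p in enumerate(genomic) if p in planted_pos}
            for _ in range(200):
                bases = [decode_sequence(codes[p - 1: p]) for p in genomic]
                if feat.strand == "-":
                    coding = "".join(reverse_complement(b) for b in bases)
                else:
                    coding = "".join(bases)
                if translate_codon(coding) != "*":
                    break
                new = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
                for k, p in enumerate(genomic):
                    if k in fixed:
                        continue
                    base = new[k]
                    if feat.strand == "-":
                        base = reverse_complement(base)
                    codes[p - 1] = _CODE[base]
            else:
                raise ConfigError(
                    f"could not make {feat.gene_name} stop-free around a "
                    f"planted codon"
                )

    reference = ReferenceGenome(config.reference_id, decode_sequence(codes))
    return reference, list(config.feature_map)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One lineage branch: independent-site substitution, ti:tv = 2:1."""
    out = codes.copy()
    if rate <= 0:
        return out
    prob = -np.expm1(-rate)
    hit = np.nonzero(rng.random(out.shape[-1]) < prob)[0]
    if hit.size == 0:
        return out
    base = out[hit]
    # only substitute proper bases (planted gaps are left alone)
    ok = base < 4
    hit, base = hit[ok], base[ok]
    transition = base ^ 2                      # A<->G (0,2), C<->T (1,3)
    tv1 = (base & 1) ^ 1                       # the two cross-class bases
    tv2 = tv1 + 2
    draw = rng.random(hit.size)
    new = np.where(draw < 2 / 3, transition, np.where(draw < 5 / 6, tv1, tv2))
    out[hit] = new.astype(np.uint8)
    return out


def _mutate_block(
    block: np.ndarray, rate: float, rng: np.random.Generator, chunk: int = 256
) -> None:
    """Private mutations applied in place, row-chunked to bound memory."""
    if rate <= 0 or block.size == 0:
        return
    prob = -np.expm1(-rate)
    n, L = block.shape
    for lo in range(0, n, chunk):
        sub = block[lo: lo + chunk]
        mask = (rng.random(sub.shape) < prob) & (sub < 4)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        base = sub[rows, cols]
        transition = base ^ 2
        tv1 = (base & 1) ^ 1
        tv2 = tv1 + 2
        draw = rng.random(rows.size)
        new = np.where(draw < 2 / 3, transition, np.where(draw < 5 / 6, tv1, tv2))
        sub[rows, cols] = new.astype(np.uint8)


def accession_ids(config: PopulationConfig) -> dict[str, list[str]]:
    """Stable accession identifiers per group (A0001..., B0001..., WAS...)."""
    def make(prefix: str, n: int) -> list[str]:
        width = max(4, len(str(n)))
        return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]

    return {
        "A": make("A", config.n_clade_A),
        "B": make("B", config.n_clade_B),
        "WAS": make("WAS", config.n_wild_asian),
        "AUS": make("AUS", config.n_australian),
        "AFR": make("AFR", config.n_african),
        "SAM": make("SAM", config.n_south_american),
        "OUT": make("OUT", config.n_outgroup),
    }


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    if not proportions or n == 0:
        return {k: 0 for k in proportions}
    labels = list(proportions)
    quotas = [proportions[k] * n for k in labels]
    counts = [int(math.floor(q + 1e-9)) for q in quotas]
    short = n - sum(counts)
    order = sorted(
        range(len(labels)), key=lambda i: (-(quotas[i] - counts[i]), labels[i])
    )
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(labels, counts))


def build_metadata(config: PopulationConfig) -> pd.DataFrame:
    """Accession metadata with group, subspecies and generating clade.

    Subspecies labels are assigned per clade by exact largest-remainder
    quota on the configured proportions (so configured compositions are
    reproduced exactly), shuffled over accessions with the config seed.
    """
    rng = _rng(config, 303)
    ids = accession_ids(config)
    rows: list[tuple[str, str, str, str]] = []
    for clade, group_ids in (("A", ids["A"]), ("B", ids["B"])):
        props = config.subspecies_proportions.get(clade, {})
        counts = _largest_remainder(props, len(group_ids))
        labels: list[str] = []
        for sub in sorted(counts):
            labels.extend([sub] * counts[sub])
        while len(labels) < len(group_ids):
            labels.append("none")
        labels_arr = np.array(labels, dtype=object)
        rng.shuffle(labels_arr)
        for acc, sub in zip(group_ids, labels_arr):
            rows.append((acc, "domesticated", sub, clade))
    for key, group in (
        ("WAS", "wild_asian"), ("AUS", "australian"), ("AFR", "african"),
        ("SAM", "south_american"), ("OUT", "outgroup"),
    ):
        for acc in ids[key]:
            rows.append((acc, group, "none", ""))
    return pd.DataFrame(rows, columns=["accession_id", "group", "subspecies", "clade"])


def planted_clade_labels(metadata: pd.DataFrame) -> dict[str, str]:
    """Ground-truth clade labels ('A'/'B'/'other') from simulator metadata."""
    if "clade" not in metadata.columns:
        raise ValueError("metadata lacks the simulator's 'clade' truth column")
    return {
        acc: (clade if clade in ("A", "B") else "other")
        for acc, clade in zip(metadata["accession_id"], metadata["clade"])
    }


def simulate_population(
    config: PopulationConfig,
) -> tuple[AlignmentMatrix, pd.DataFrame, ReferenceGenome, list[GenomeFeature]]:
    """Generate the full aligned population for one configuration.

    Returns the alignment (with the reference as its first row), the
    metadata table, the reference genome, and the feature map.  The output
    is byte-deterministic for a fixed config.
    """
    reference, features = generate_reference(config)
    ref_codes = encode_sequence(reference.sequence)
    rng = _rng(config, 202)
    rate = dict.fromkeys(BRANCH_NAMES, 0.0) | dict(config.background_divergence)

    # consensus sequences along the fixed lineage topology
    anc_aus = _mutate(ref_codes, rate["stem_australian"], rng)
    out_cons = _mutate(ref_codes, rate["outgroup"], rng)
    sam_cons = _mutate(ref_codes, rate["south_american"], rng)
    aus_cons = _mutate(anc_aus, rate["australian"], rng)
    anc_asian = _mutate(anc_aus, rate["stem_asian"], rng)
    was_cons = _mutate(anc_asian, rate["wild_asian"], rng)
    anc_dom = _mutate(anc_asian, rate["stem_domesticated"], rng)
    cons_a = _mutate(anc_dom, rate["clade_A"], rng)
    cons_b = _mutate(anc_dom, rate["clade_B"], rng)
    afr_cons = _mutate(cons_a, rate["african"], rng)

    for site in config.planted_sites:
        cons_a[site.position - 1] = _CODE[site.allele_A]
        cons_b[site.position - 1] = _CODE[site.allele_B]

    ids = accession_ids(config)
    blocks: list[tuple[list[str], np.ndarray]] = []
    for key, consensus in (
        ("A", cons_a), ("B", cons_b), ("WAS", was_cons), ("AUS", aus_cons),
        ("AFR", afr_cons), ("SAM", sam_cons), ("OUT", out_cons),
    ):
        n = len(ids[key])
        block = np.tile(consensus, (n, 1)) if n else np.empty((0, len(consensus)), np.uint8)
        _mutate_block(block, config.private_mutation_rate, rng)
        blocks.append((ids[key], block))

    # exact planted tallies: reset the planted columns, then flip the seeded
    # carrier subsets to the opposite clade's allele
    block_a, block_b = blocks[0][1], blocks[1][1]
    for site in config.planted_sites:
        col = site.position - 1
        if block_a.shape[0]:
            block_a[:, col] = _CODE[site.allele_A]
            if site.within_A_alt_count:
                carriers = rng.choice(
                    block_a.shape[0], size=site.within_A_alt_count, replace=False
                )
                block_a[carriers, col] = _CODE[site.allele_B]
        if block_b.shape[0]:
            block_b[:, col] = _CODE[site.allele_B]
            if site.within_B_alt_count:
                carriers = rng.choice(
                    block_b.shape[0], size=site.within_B_alt_count, replace=False
                )
                block_b[carriers, col] = _CODE[site.allele_A]

    all_ids = [reference.id]
    for group_ids, _ in blocks:
        all_ids.extend(group_ids)
    data = np.vstack([ref_codes[None, :]] + [b for _, b in blocks])
    alignment = AlignmentMatrix(all_ids, data)
    metadata = build_metadata(config)
    return alignment, metadata, reference, features


def write_population(
    outdir: str | Path,
    alignment: AlignmentMatrix,
    metadata: pd.DataFrame,
    reference: ReferenceGenome,
    features: Sequence[GenomeFeature],
    config: PopulationConfig | None = None,
) -> dict[str, Path]:
    """Write the FASTA/TSV bundle for one simulated population."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "reference": outdir / "reference.fasta",
        "features": outdir / "features.tsv",
    }
    alignment.write_fasta(paths["alignment"])
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    SeqIO.write(
        [SeqRecord(Seq(reference.sequence), id=reference.id, description="")],
        str(paths["reference"]), "fasta",
    )
    write_feature_map(features, paths["features"])
    if config is not None:
        paths["config"] = outdir / "config.yaml"
        config.to_yaml(paths["config"])
    return paths
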