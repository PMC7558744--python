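"""Aligned-sequence matrix and accession-metadata containers.

The whole pipeline works on one in-memory representation: an
:class:`AlignmentMatrix` (accessions x aligned columns, encoded as small
integers over the six-letter state alphabet ``A C G T - N``) plus a pandas
metadata table carrying, per accession, its population group and subspecies
type.  FASTA round-tripping goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: state alphabet; index in this string == integer code in the matrix
ALPHABET = "ACGT-N"
A_CODE, C_CODE, G_CODE, T_CODE, GAP_CODE, N_CODE = range(6)

#: population groups recognised in metadata
GROUP_LABELS = (
    "domesticated",
    "wild_asian",
    "australian",
    "african",
    "south_american",
    "outgroup",
)

#: subspecies / rice-type labels recognised in metadata
SUBSPECIES_LABELS = (
    "indica",
    "japonica",
    "tropical_japonica",
    "temperate_japonica",
    "basmati",
    "aus",
    "intermediate",
    "none",
)

METADATA_COLUMNS = ("accession_id", "group", "subspecies")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes (A=0 ... N=5)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(f"invalid sequence characters: {bad}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


class AlignmentMatrix:
    """A multiple sequence alignment held as an integer matrix.

    Parameters
    ----------
    ids
        Ordered, unique accession identifiers (one per row).
    data
        ``(n_sequences, n_columns)`` uint8 matrix of state codes.
    """

    def __init__(self, ids: Sequence[str], data: np.ndarray):
        ids = [str(i) for i in ids]
        data = np.ascontiguousarray(data, dtype=np.uint8)
        if data.ndim != 2:
            raise ValueError("alignment data must be a 2-D matrix")
        if data.shape[0] != len(ids):
            raise ValueError(
                f"{len(ids)} ids but {data.shape[0]} alignment rows"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids in alignment")
        if data.size and data.max() >= len(ALPHABET):
            raise ValueError("alignment codes outside the ACGT-N alphabet")
        self.ids: list[str] = ids
        self.data: np.ndarray = data
        self._index: dict[str, int] = {a: i for i, a in enumerate(ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def __len__(self) -> int:
        return self.n_sequences

    def row(self, accession: str) -> np.ndarray:
        """Return the code row for one accession (a view, do not mutate)."""
        try:
            return self.data[self._index[accession]]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in alignment") from None

    def sequence(self, accession: str) -> str:
        return decode_sequence(self.row(accession))

    def rows(self, accessions: Iterable[str]) -> np.ndarray:
        idx = [self._index[a] for a in accessions]
        return self.data[idx]

    def subset(self, accessions: Iterable[str]) -> "AlignmentMatrix":
        accessions = list(accessions)
        return AlignmentMatrix(accessions, self.rows(accessions).copy())

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_sequences(
        cls, records: Iterable[tuple[str, str]] | Mapping[str, str]
    ) -> "AlignmentMatrix":
        if isinstance(records, Mapping):
            records = list(records.items())
        else:
            records = list(records)
        if not records:
            raise ValueError("no sequences supplied")
        ids = [r[0] for r in records]
        lengths = {len(r[1]) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        data = np.vstack([encode_sequence(r[1]) for r in records])
        return cls(ids, data)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_sequences(records)

    def write_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(decode_sequence(row)), id=acc, description="")
            for acc, row in zip(self.ids, self.data)
        )
        SeqIO.write(records, str(path), "fasta")


# -- metadata ----------------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, label vocabulary and id uniqueness."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata["accession_id"].duplicated().any():
        dups = metadata.loc[metadata["accession_id"].duplicated(), "accession_id"]
        raise ValueError(f"duplicate accession ids in metadata: {sorted(dups)[:5]}")
    bad_groups = set(metadata["group"]) - set(GROUP_LABELS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    bad_sub = set(metadata["subspecies"]) - set(SUBSPECIES_LABELS)
    if bad_sub:
        raise ValueError(f"unknown subspecies labels: {sorted(bad_sub)}")
    return metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata)
    metadata.to_csv(path, sep="\t", index=False)


# -- clade assignment table --------------------------------------------------

def read_clade_assignment(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession_id", "clade"}.issubset(df.columns):
        raise ValueError("clade assignment TSV needs columns accession_id, clade")
    return dict(zip(df["accession_id"], df["clade"]))


def write_clade_assignment(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"accession_id": list(labels.keys()), "clade": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
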