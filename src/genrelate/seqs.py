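"""Nucleotide sequence containers and FASTA input/output.

A :class:`GenomeSequence` is a named, ordered collection of contigs over the
alphabet ``{A, C, G, T, N}``.  All coordinates used throughout the package are
0-based half-open on the forward strand of the contig they refer to.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Encoding used by the aligner: A=0, C=1, G=2, T=3, N (and anything else)=4.
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate IDs, bad residues)."""


@dataclass
class GenomeSequence:
    """A named nucleotide sequence: an assembly, i.e. an ordered contig set.

    Parameters
    ----------
    id
        Genome (assembly) identifier.
    contigs
        Ordered mapping contig name -> uppercase sequence over ``ACGTN``.
    """

    id: str
    contigs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_string(cls, id: str, sequence: str) -> "GenomeSequence":
        """Single-contig genome whose sole contig is named after the genome."""
        return cls(id=id, contigs={id: sequence.upper()})

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def sequence(self) -> str:
        """Concatenation of all contigs, in order (no separators)."""
        return "".join(self.contigs.values())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.length

    def iter_contigs(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs.items())

    def validate(self) -> None:
        if not self.contigs or self.length == 0:
            raise FastaError(f"genome {self.id!r} is empty")
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FastaError(
                    f"illegal character {seq[pos]!r} at position {pos} "
                    f"of contig {name!r}"
                )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name, seq in self.contigs.items():
            h.update(name.encode())
            h.update(b"\x00")
            h.update(seq.encode())
        return h.hexdigest()


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeSequence:
    """Read a (multi-record) FASTA file into one :class:`GenomeSequence`.

    Record IDs are the first whitespace-delimited token of each header;
    sequences are upper-cased; characters outside ``ACGTN`` are rejected with
    their position.  Empty files and duplicate IDs are errors.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FastaError(f"duplicate sequence ID {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    gs = GenomeSequence(id=genome_id or path.stem, contigs=contigs)
    gs.validate()
    return gs


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as a list of (id, uppercase sequence) pairs, validated."""
    gs = read_fasta(path)
    return list(gs.contigs.items())


def write_fasta(
    records: Iterable[tuple[str, str]] | GenomeSequence, path: str | Path
) -> None:
    """Write records (or a genome's contigs) as FASTA wrapped at 80 columns."""
    if isinstance(records, GenomeSequence):
        records = records.iter_contigs()
    seqrecs = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqrecs)
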