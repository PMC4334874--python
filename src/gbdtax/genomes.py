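"""Genome assemblies and composition statistics.

A :class:`GenomeRecord` holds one strain's assembly as an ordered list of
replicons (chromosome plus optional plasmids/contigs).  All whole-genome
statistics (length, G+C content) are computed over the concatenation of the
replicons, so a strain with a chromosome and a plasmid is summarised by a
single length and a single G+C fraction, as is conventional for genome
reports.

G+C content is computed over unambiguous bases only: IUPAC ambiguity codes
(including N) are excluded from both the numerator and the denominator, so
unknown bases do not bias the composition estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "GenomeFormatError",
    "read_fasta",
    "write_fasta",
    "gc_fraction",
    "gc_difference",
]

# Upper-case IUPAC nucleotide alphabet; U is tolerated on input and mapped to T.
_UNAMBIGUOUS = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")


class GenomeFormatError(ValueError):
    """Raised for malformed or empty genome input."""


# byte-level code table used by the matcher: A,C,G,T -> 0..3, anything else -> 255
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i

_COMPLEMENT = np.full(256, 255, dtype=np.uint8)
_COMPLEMENT[:4] = [3, 2, 1, 0]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other IUPAC -> 255)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


@dataclass
class GenomeRecord:
    """One strain's assembly: ordered replicons with derived statistics."""

    strain_id: str
    replicons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for name, seq in self.replicons:
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - _IUPAC
            if bad:
                raise GenomeFormatError(
                    f"record {name!r} of strain {self.strain_id!r} contains "
                    f"non-nucleotide symbols: {sorted(bad)}"
                )
            cleaned.append((name, seq))
        if not cleaned:
            raise GenomeFormatError(f"strain {self.strain_id!r} has no replicons")
        self.replicons = cleaned

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.replicons)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self)

    def concatenated(self, spacer: int = 0) -> str:
        """Replicons joined in order, optionally separated by runs of N.

        The spacer prevents alignment seeds from spanning replicon joins when
        the concatenation is fed to the fragment matcher; it contributes to
        coordinates but never to length or composition statistics.
        """
        return ("N" * spacer).join(seq for _, seq in self.replicons)


def read_fasta(path: str | Path, strain_id: str | None = None) -> GenomeRecord:
    """Read a (multi-)FASTA assembly into a :class:`GenomeRecord`.

    Replicons keep file order; sequences are uppercased (soft-masked input is
    accepted) and U is mapped to T.  The strain id defaults to the file stem.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    sid = strain_id if strain_id is not None else path.stem
    return GenomeRecord(sid, [(r.id, str(r.seq)) for r in records])


def read_fasta_dir(paths: Iterable[str | Path]) -> list[GenomeRecord]:
    """Read one assembly per path; strain ids are the file stems."""
    genomes = [read_fasta(p) for p in paths]
    seen: set[str] = set()
    for g in genomes:
        if g.strain_id in seen:
            raise GenomeFormatError(f"duplicate strain id {g.strain_id!r}")
        seen.add(g.strain_id)
    return genomes


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in record.replicons
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def gc_fraction(record: GenomeRecord) -> float:
    """(#G + #C) / (#unambiguous A,C,G,T) over all replicons.

    Ambiguous IUPAC symbols are excluded from numerator and denominator.
    """
    gc = 0
    acgt = 0
    for _, seq in record.replicons:
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise GenomeFormatError(
            f"strain {record.strain_id!r}: no unambiguous bases; "
            "G+C content undefined"
        )
    return gc / acgt


def gc_difference(a: GenomeRecord, b: GenomeRecord) -> float:
    """Absolute G+C content difference in percentage points."""
    return abs(gc_fraction(a) - gc_fraction(b)) * 100.0


def gc_table(genomes: Sequence[GenomeRecord]) -> dict[str, float]:
    """strain_id -> G+C fraction, for classification's G+C-difference check."""
    return {g.strain_id: gc_fraction(g) for g in genomes}
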