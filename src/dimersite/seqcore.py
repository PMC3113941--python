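"""Nucleotide alphabet semantics: IUPAC sets, reverse complementation,
mismatch counting, and FASTA input.

All patterns are strings over the 15-letter IUPAC nucleotide alphabet,
written 5'->3'.  Genome sequences are restricted to {A, C, G, T, N}.
A genomic ``N`` (unknown base) never satisfies any pattern letter —
including pattern ``N`` — so stretches of assembly gap can only be
matched by spending mismatch budget.  Soft-masked (lowercase) genome
bases are case-folded and searched by default; ``read_fasta`` can
optionally convert them to ``N`` to exclude masked regions.

Internal coordinates are 0-based half-open throughout; conversion to
1-based inclusive happens only in the report layer.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "AlphabetError",
    "Genome",
    "GenomeRecord",
    "reverse_complement",
    "iupac_matches",
    "count_mismatches",
    "degenerate_count",
    "validate_iupac",
    "read_fasta",
    "encode",
    "pattern_table",
    "mismatch_profile",
]

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)

#: Order used for 8-bit base encoding; N and anything unknown map to 4.
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE["N"] = 4


class AlphabetError(ValueError):
    """A sequence contains a character outside the expected alphabet."""


def validate_iupac(seq: str, *, what: str = "pattern") -> str:
    """Uppercase *seq* and check every character is a valid IUPAC code.

    Raises :class:`AlphabetError` naming the first offending character
    and its 1-based position.
    """
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i + 1} in {what} {seq!r}"
            )
    return up


def degenerate_count(seq: str) -> int:
    """Number of characters outside the concrete alphabet {A,C,G,T}."""
    return sum(1 for ch in seq if ch not in "ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    up = validate_iupac(seq)
    return up.translate(_COMP_TABLE)[::-1]


def iupac_matches(pattern_base: str, genome_base: str) -> bool:
    """True iff *genome_base* is a member of *pattern_base*'s set.

    A genomic ``N`` matches nothing, by policy (see module docstring).
    """
    try:
        pset = IUPAC_SETS[pattern_base.upper()]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC pattern character {pattern_base!r}")
    gb = genome_base.upper()
    if gb == "N":
        return False
    if gb not in "ACGT":
        raise AlphabetError(f"invalid genome character {genome_base!r}")
    return gb in pset


def count_mismatches(pattern: str, window: str) -> int:
    """Hamming-style mismatch count of a genome window against an IUPAC
    pattern.

    A genome base inside a degenerate position's set contributes 0;
    outside it (or an ``N``) contributes 1.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    return sum(0 if iupac_matches(p, b) else 1 for p, b in zip(pattern, window))


# ---------------------------------------------------------------------------
# Genome container and FASTA input


@dataclass
class GenomeRecord:
    id: str
    seq: str


@dataclass
class Genome:
    """An ordered collection of named sequences over {A,C,G,T,N}."""

    records: list[GenomeRecord] = field(default_factory=list)
    species_code: str = "NA"

    def __iter__(self) -> Iterable[GenomeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, record_id: str) -> GenomeRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    @classmethod
    def from_dict(cls, d: dict[str, str], species_code: str = "NA") -> "Genome":
        return cls(
            records=[GenomeRecord(k, v.upper()) for k, v in d.items()],
            species_code=species_code,
        )


def _open_maybe_gzip(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(source, species_code: str = "NA", *, mask_lowercase: bool = False) -> Genome:
    """Load a (possibly gzip-compressed) multi-record FASTA file.

    Record ids are the first whitespace-delimited header token and must be
    unique.  Lowercase (soft-masked) bases are folded to uppercase, or
    converted to ``N`` when *mask_lowercase* is set.  Characters outside
    {A,C,G,T,N} are rejected with the record and position named.
    """
    handle = _open_maybe_gzip(source)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in FASTA input")
        raw = str(rec.seq)
        if mask_lowercase:
            raw = "".join("N" if c.islower() else c for c in raw)
        seq = raw.upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        for i, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise AlphabetError(
                    f"illegal character {ch!r} at position {i + 1} "
                    f"of record {rec.id!r}"
                )
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise ValueError("FASTA input contains no records")
    return Genome(records=records, species_code=species_code)


# ---------------------------------------------------------------------------
# Vectorized primitives used by the scanning paths


def encode(seq: str) -> np.ndarray:
    """Encode a genome string as uint8 codes (A,C,G,T -> 0..3, N -> 4)."""
    out = np.full(len(seq), 4, dtype=np.uint8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def pattern_table(pattern: str) -> np.ndarray:
    """Boolean (L, 5) membership table for an IUPAC pattern.

    Column 4 (genomic N) is always False, implementing the N policy.
    """
    up = validate_iupac(pattern)
    table = np.zeros((len(up), 5), dtype=bool)
    for i, ch in enumerate(up):
        for base in IUPAC_SETS[ch]:
            table[i, _CODE[base]] = True
    return table


def mismatch_profile(coded: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of *pattern* against every window of a coded sequence.

    Returns an int16 array of length ``len(coded) - L + 1`` (empty when the
    sequence is shorter than the pattern).
    """
    L = len(pattern)
    n = len(coded) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    table = pattern_table(pattern)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(L):
        mm += ~table[j, coded[j : j + n]]
    return mm
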