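"""Exhaustive half-site matching: per-nucleotide word index and direct scan.

Two independent engines implement the same result contract — every
genomic window within the per-half-site mismatch budget, on both
strands, with no misses:

``indexed``
    A word index with one entry for every position whose window contains
    only A/C/G/T.  The degenerate, budgeted query is expanded into
    concrete tags (:mod:`.tags`) and each tag is looked up exactly.
    Windows overlapping a genomic N cannot be indexed as exact words but
    can still match by spending budget (every N costs one mismatch), so
    the index records their positions and the indexed engine scores that
    residue of windows directly — both engines therefore honor the same
    "no match missed" contract.

``direct``
    A vectorized sliding-window IUPAC mismatch profile over every
    position.  Slower on large genomes but expansion-free; it serves as
    the independent oracle for the exhaustiveness contract.

A minus-strand match at forward offset ``start`` means the reverse
complement of the window matches the half-site pattern; its mismatch
count is always given in half-site orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqcore, tags
from .query import HalfSite
from .seqcore import Genome

__all__ = ["KmerIndex", "HalfSiteMatch", "build_index", "lookup",
           "find_halfsite_matches", "scan_direct"]


@dataclass(frozen=True, order=True)
class HalfSiteMatch:
    record_id: str
    start: int  # 0-based forward-strand offset of the window
    strand: str  # "+" | "-"
    role: str  # "left" | "right"
    mismatches: int


class KmerIndex:
    """Word index with one entry per A/C/G/T-only window of length W."""

    def __init__(self, genome: Genome, word_length: int):
        if word_length < 1:
            raise ValueError("word length must be >= 1")
        if all(len(rec.seq) < word_length for rec in genome.records):
            raise ValueError(
                f"word length {word_length} exceeds every record length"
            )
        self.word_length = word_length
        self.n_entries = 0
        # record id -> {word -> [positions]}
        self._table: dict[str, dict[str, list[int]]] = {}
        # record id -> window starts that overlap an N (not indexable)
        self.n_window_starts: dict[str, list[int]] = {}
        W = word_length
        for rec in genome.records:
            seq = rec.seq
            entries: dict[str, list[int]] = {}
            coded = seqcore.encode(seq)
            ok = coded < 4
            n_starts: list[int] = []
            if len(seq) >= W:
                valid = np.lib.stride_tricks.sliding_window_view(ok, W).all(axis=1)
                for pos in np.flatnonzero(valid):
                    entries.setdefault(seq[pos : pos + W], []).append(int(pos))
                n_starts = [int(p) for p in np.flatnonzero(~valid)]
                self.n_entries += int(valid.sum())
            self._table[rec.id] = entries
            self.n_window_starts[rec.id] = n_starts

    def lookup(self, record_id: str, word: str) -> list[int]:
        if len(word) != self.word_length:
            raise ValueError(
                f"word length {len(word)} != index word length {self.word_length}"
            )
        return self._table.get(record_id, {}).get(word, [])

    def entries(self, record_id: str):
        """All (word, position) pairs of one record, sorted by word then position."""
        for word in sorted(self._table.get(record_id, {})):
            for pos in self._table[record_id][word]:
                yield word, pos


def build_index(genome: Genome, word_length: int) -> KmerIndex:
    return KmerIndex(genome, word_length)


def lookup(index: KmerIndex, record_id: str, word: str) -> list[int]:
    return index.lookup(record_id, word)


def _sorted(matches: list[HalfSiteMatch], genome: Genome) -> list[HalfSiteMatch]:
    order = {rec.id: i for i, rec in enumerate(genome.records)}
    return sorted(matches, key=lambda m: (order[m.record_id], m.start, m.strand))


def find_halfsite_matches(
    genome: Genome,
    halfsite: HalfSite,
    k: int,
    *,
    engine: str = "indexed",
    index: KmerIndex | None = None,
    tag_cap: int | None = tags.DEFAULT_TAG_CAP,
) -> list[HalfSiteMatch]:
    """Every occurrence of *halfsite* within *k* mismatches, both strands.

    With ``engine="indexed"`` an existing :class:`KmerIndex` of matching
    word length may be passed to amortize index construction across
    queries.
    """
    if engine == "direct":
        return scan_direct(genome, halfsite, k)
    if engine != "indexed":
        raise ValueError(f"unknown engine {engine!r}")

    fwd = tags.expand_with_mismatches(halfsite.seq, k, cap=tag_cap)
    rev = fwd.reverse_complement()
    if index is None:
        index = build_index(genome, len(halfsite))
    elif index.word_length != len(halfsite):
        raise ValueError("index word length does not match the half-site length")

    out: list[HalfSiteMatch] = []
    rc_pattern = rev.pattern
    for rec in genome.records:
        for strand, tagset in (("+", fwd), ("-", rev)):
            for tag, mm in tagset.tags.items():
                for pos in index.lookup(rec.id, tag):
                    out.append(
                        HalfSiteMatch(rec.id, pos, strand, halfsite.role, mm)
                    )
        # windows overlapping an N are absent from the index but may still
        # match within budget (each N is one mismatch): score them directly
        W = index.word_length
        for pos in index.n_window_starts.get(rec.id, []):
            window = rec.seq[pos : pos + W]
            for strand, pat in (("+", halfsite.seq), ("-", rc_pattern)):
                mm = seqcore.count_mismatches(pat, window)
                if mm <= k:
                    out.append(HalfSiteMatch(rec.id, pos, strand, halfsite.role, mm))
    return _sorted(out, genome)


def scan_direct(genome: Genome, halfsite: HalfSite, k: int) -> list[HalfSiteMatch]:
    """Sliding-window mismatch profile at every position on both strands."""
    out: list[HalfSiteMatch] = []
    rc = seqcore.reverse_complement(halfsite.seq)
    for rec in genome.records:
        coded = seqcore.encode(rec.seq)
        for strand, pat in (("+", halfsite.seq), ("-", rc)):
            mm = seqcore.mismatch_profile(coded, pat)
            for pos in np.flatnonzero(mm <= k):
                out.append(
                    HalfSiteMatch(rec.id, int(pos), strand, halfsite.role, int(mm[pos]))
                )
    return _sorted(out, genome)
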