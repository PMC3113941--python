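"""Pairing of half-site matches into spacing-constrained dimeric sites.

A dimeric site exists wherever the first half-site matches on the minus
strand immediately upstream of a plus-strand match of the second
half-site, separated by an allowed spacer length.  Enumerating the
ordered pairs

    (L, R) -> hetero site, reported strand '+'
    (R, L) -> hetero site, reported strand '-'
    (L, L), (R, R) -> homo sites, reported strand '+' by convention

captures every orientation exactly once: a homo-dimeric query is its own
reverse complement, so scanning its ordered pair once yields each
genomic interval once, and the strand label is a pure convention.

Per-half mismatch counts ``mm_first``/``mm_second`` always refer to the
mode's ordered halves in site orientation (for LR: first = left half,
second = right half, on either strand), so they compare directly with
planned counts from the synthetic implanter.

:func:`scan_full_patterns` is an independent oracle: it slides each
composed full-site query over the genome scoring the two half blocks
per position, with no tag expansion, no index and no pairing, and must
produce the identical site list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as engine_mod
from . import seqcore
from .query import FullSitePattern, SearchConfig, compose_patterns
from .seqcore import Genome

__all__ = ["DimericSite", "pair_matches", "filter_total_mismatches",
           "find_sites", "scan_full_patterns"]

#: below this total genome size a direct scan beats building an index
_AUTO_DIRECT_MAX = 5_000


@dataclass(frozen=True)
class DimericSite:
    mode: str  # "LR" | "LL" | "RR"
    record_id: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str  # "+" | "-"
    spacing: int
    upstream_block: str  # forward-strand substrings
    spacer_seq: str
    downstream_block: str
    mm_first: int  # first half of the mode's ordered pair, site orientation
    mm_second: int

    @property
    def mm_total(self) -> int:
        return self.mm_first + self.mm_second

    def oriented_sequence(self) -> str:
        """Full site read in query orientation (revcomp'ed for '-' sites)."""
        seq = self.upstream_block + self.spacer_seq + self.downstream_block
        return seq if self.strand == "+" else seqcore.reverse_complement(seq)


_MODE_ROLES = {"LR": ("left", "right"), "LL": ("left", "left"), "RR": ("right", "right")}


def _site_sort_key(genome: Genome):
    order = {rec.id: i for i, rec in enumerate(genome.records)}
    return lambda s: (order[s.record_id], s.start, s.mode, s.strand, s.spacing)


def pair_matches(
    matches: list[engine_mod.HalfSiteMatch],
    cfg: SearchConfig,
    genome: Genome,
) -> list[DimericSite]:
    """Combine half-site matches into every spacing-constrained dimer.

    Pairing probes a hash of plus-strand match positions from each
    minus-strand match (linear time, no quadratic join).
    """
    halves = {"left": cfg.left, "right": cfg.right}
    # (record, strand, role) -> {start: mismatches}
    by_key: dict[tuple[str, str, str], dict[int, int]] = {}
    for m in matches:
        by_key.setdefault((m.record_id, m.strand, m.role), {})[m.start] = m.mismatches

    ordered_pairs: list[tuple[str, str, str, str]]  # (roleA, roleB, mode, strand)
    ordered_pairs = [("left", "right", "LR", "+"), ("right", "left", "LR", "-")]
    if cfg.homodimer:
        ordered_pairs += [("left", "left", "LL", "+"), ("right", "right", "RR", "+")]

    sites: list[DimericSite] = []
    for rec in genome.records:
        for role_a, role_b, mode, strand in ordered_pairs:
            len_a = len(halves[role_a])
            len_b = len(halves[role_b])
            minus_a = by_key.get((rec.id, "-", role_a), {})
            plus_b = by_key.get((rec.id, "+", role_b), {})
            if not minus_a or not plus_b:
                continue
            for s in sorted(cfg.spacings):
                for i, mm_a in minus_a.items():
                    j = i + len_a + s
                    mm_b = plus_b.get(j)
                    if mm_b is None:
                        continue
                    end = j + len_b
                    # orient per-half counts onto the mode's ordered halves
                    if mode == "LR" and strand == "-":
                        mm_first, mm_second = mm_b, mm_a  # left matched on '+'
                    else:
                        mm_first, mm_second = mm_a, mm_b
                    sites.append(
                        DimericSite(
                            mode=mode,
                            record_id=rec.id,
                            start=i,
                            end=end,
                            strand=strand,
                            spacing=s,
                            upstream_block=rec.seq[i : i + len_a],
                            spacer_seq=rec.seq[i + len_a : j],
                            downstream_block=rec.seq[j:end],
                            mm_first=mm_first,
                            mm_second=mm_second,
                        )
                    )
    sites.sort(key=_site_sort_key(genome))
    return sites


def filter_total_mismatches(sites: list[DimericSite], cap: int) -> list[DimericSite]:
    """Keep sites with at most *cap* total mismatches, order preserved."""
    if cap < 0:
        raise ValueError("total-mismatch cap must be >= 0")
    return [s for s in sites if s.mm_total <= cap]


def find_sites(
    genome: Genome,
    cfg: SearchConfig,
    *,
    engine: str = "auto",
) -> list[DimericSite]:
    """Full pipeline: half-site matching, dimer assembly, total-mm filter."""
    if engine == "auto":
        total = sum(len(rec.seq) for rec in genome.records)
        engine = "direct" if total < _AUTO_DIRECT_MAX else "indexed"
    if engine not in ("indexed", "direct"):
        raise ValueError(f"unknown engine {engine!r}")

    matches: list[engine_mod.HalfSiteMatch] = []
    indexes: dict[int, engine_mod.KmerIndex] = {}
    for half in (cfg.left, cfg.right):
        idx = None
        if engine == "indexed":
            if len(half) not in indexes:
                indexes[len(half)] = engine_mod.build_index(genome, len(half))
            idx = indexes[len(half)]
        matches.extend(
            engine_mod.find_halfsite_matches(
                genome, half, cfg.budget(half.role), engine=engine, index=idx
            )
        )
    sites = pair_matches(matches, cfg, genome)
    if cfg.total_mismatch_cap is not None:
        sites = filter_total_mismatches(sites, cfg.total_mismatch_cap)
    return sites


# ---------------------------------------------------------------------------
# Independent oracle: direct composed-pattern scan


def scan_full_patterns(genome: Genome, cfg: SearchConfig) -> list[DimericSite]:
    """Slide every composed full-site query over the genome directly.

    Scores the upstream and downstream half blocks at every position
    against their per-half budgets; hetero queries are also scanned as
    their reverse complement for minus-strand sites, homo queries are
    palindromic and scanned once.  Produces the identical site list to
    :func:`find_sites` by construction of the method's contract.
    """
    sites: list[DimericSite] = []
    for fsp in compose_patterns(cfg):
        sites.extend(_scan_one_pattern(genome, cfg, fsp))
    if cfg.total_mismatch_cap is not None:
        sites = filter_total_mismatches(sites, cfg.total_mismatch_cap)
    sites.sort(key=_site_sort_key(genome))
    return sites


def _scan_one_pattern(
    genome: Genome, cfg: SearchConfig, fsp: FullSitePattern
) -> list[DimericSite]:
    len_a, len_b, s = len(fsp.first), len(fsp.second), fsp.spacing
    plen = len_a + s + len_b
    k_first = cfg.budget(fsp.first.role)
    k_second = cfg.budget(fsp.second.role)
    out: list[DimericSite] = []

    for rec in genome.records:
        n = len(rec.seq) - plen + 1
        if n <= 0:
            continue
        coded = seqcore.encode(rec.seq)

        def emit(start: int, strand: str, mm_first: int, mm_second: int):
            # forward-strand block boundaries depend on which half sits upstream
            if strand == "+":
                up, sp, down = (
                    rec.seq[start : start + len_a],
                    rec.seq[start + len_a : start + len_a + s],
                    rec.seq[start + len_a + s : start + plen],
                )
            else:
                up, sp, down = (
                    rec.seq[start : start + len_b],
                    rec.seq[start + len_b : start + len_b + s],
                    rec.seq[start + len_b + s : start + plen],
                )
            out.append(
                DimericSite(
                    mode=fsp.mode,
                    record_id=rec.id,
                    start=start,
                    end=start + plen,
                    strand=strand,
                    spacing=s,
                    upstream_block=up,
                    spacer_seq=sp,
                    downstream_block=down,
                    mm_first=mm_first,
                    mm_second=mm_second,
                )
            )

        # plus strand: revcomp(first) upstream, second downstream
        mm_up = seqcore.mismatch_profile(coded, seqcore.reverse_complement(fsp.first.seq))
        mm_down = seqcore.mismatch_profile(coded, fsp.second.seq)
        hit = (mm_up[:n] <= k_first) & (mm_down[len_a + s : len_a + s + n] <= k_second)
        for i in np.flatnonzero(hit):
            emit(int(i), "+", int(mm_up[i]), int(mm_down[i + len_a + s]))

        if fsp.mode == "LR":
            # minus strand: revcomp(second) upstream, first downstream
            mm_up2 = seqcore.mismatch_profile(
                coded, seqcore.reverse_complement(fsp.second.seq)
            )
            mm_down2 = seqcore.mismatch_profile(coded, fsp.first.seq)
            hit2 = (mm_up2[:n] <= k_second) & (
                mm_down2[len_b + s : len_b + s + n] <= k_first
            )
            for i in np.flatnonzero(hit2):
                emit(int(i), "-", int(mm_down2[i + len_b + s]), int(mm_up2[i]))
    return out
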