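"""Synthetic genomes with implanted dimeric sites at known positions.

Every test of the search pipeline rests on fixtures whose ground truth
is known by construction: a random background genome into which full
sites are written with planned per-half mismatch counts.  Implanting
concretizes the composed query (degenerate positions drawn uniformly
from their sets, spacer bases drawn uniformly), then corrupts exactly
the planned number of non-degenerate positions per half — so the
planned counts are unambiguous and re-scoring each implant reproduces
them exactly.  Implants are kept at least one full-site length apart,
making truth comparison trivial.

The generator emulates composition and site placement only; it has no
repeats, isochores or masking.  Chance background hits are expected and
are confirmed against the direct-scan oracle rather than excluded by
construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import seqcore
from .query import SearchConfig, FullSitePattern
from .seqcore import Genome, GenomeRecord

__all__ = ["TruthRecord", "generate_genome", "implant_site", "make_fixture",
           "PlacementError", "read_truth_tsv"]

_BASES = "ACGT"

TRUTH_COLUMNS = ["record", "start", "end", "mode", "spacing", "strand",
                 "mm_first", "mm_second"]


class PlacementError(ValueError):
    """An implant would overlap (or sit too close to) a previous one."""


@dataclass(frozen=True)
class TruthRecord:
    record_id: str
    start: int  # 0-based half-open
    end: int
    mode: str
    spacing: int
    strand: str
    mm_first: int
    mm_second: int

    @property
    def mm_total(self) -> int:
        return self.mm_first + self.mm_second


def generate_genome(
    length: int,
    base_probs=(0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
    record_id: str = "chr1",
    species_code: str = "SYN",
) -> Genome:
    """A single-record random genome, reproducible given the seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"base probabilities must be 4 values summing to 1: {base_probs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_BASES), size=length, p=p))
    return Genome([GenomeRecord(record_id, seq)], species_code=species_code)


def _concretize_half(half_seq: str, mm: int, rng: np.random.Generator) -> str:
    """One concrete realization of a half-site with exactly *mm* mismatches.

    Degenerate positions are drawn uniformly from their sets (never a
    mismatch); the mismatches corrupt randomly chosen non-degenerate
    positions to one of the three other bases.
    """
    chars = []
    nondeg = [i for i, ch in enumerate(half_seq) if ch in _BASES]
    if mm > len(nondeg):
        raise ValueError(
            f"cannot plan {mm} mismatches in {half_seq!r}: only "
            f"{len(nondeg)} non-degenerate positions"
        )
    for ch in half_seq:
        members = sorted(seqcore.IUPAC_SETS[ch])
        chars.append(members[rng.integers(len(members))])
    for i in rng.choice(nondeg, size=mm, replace=False):
        others = [b for b in _BASES if b != half_seq[i]]
        chars[i] = others[rng.integers(3)]
    return "".join(chars)


def implant_site(
    genome: Genome,
    cfg: SearchConfig,
    mode: str,
    spacing: int,
    strand: str,
    mm_plan: tuple[int, int],
    position: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[Genome, TruthRecord]:
    """Overwrite the genome with one concrete full site; return the truth.

    ``mm_plan`` gives (first-half, second-half) mismatch counts in site
    orientation.  A '-' implant writes the reverse complement of the
    concrete site.  Homo-dimeric implants are canonicalized in the truth
    record to strand '+' (swapping the planned counts for a '-' implant),
    matching the search convention that homo sites carry strand '+'.
    """
    halves = {"left": cfg.left, "right": cfg.right}
    roles = {"LR": ("left", "right"), "LL": ("left", "left"), "RR": ("right", "right")}
    if mode not in roles:
        raise ValueError(f"unknown mode {mode!r}")
    a, b = (halves[r] for r in roles[mode])
    full_len = len(a) + spacing + len(b)
    rec = genome.records[0]
    if not 0 <= position <= len(rec.seq) - full_len:
        raise PlacementError(
            f"position {position} leaves no room for a {full_len} nt site"
        )
    if occupied is not None:
        lo, hi = position - full_len, position + 2 * full_len
        for s0, e0 in occupied:
            if s0 < hi and lo < e0:
                raise PlacementError(f"implant at {position} too close to [{s0}, {e0})")

    first = _concretize_half(a.seq, mm_plan[0], rng)
    second = _concretize_half(b.seq, mm_plan[1], rng)
    spacer = "".join(_BASES[rng.integers(4)] for _ in range(spacing))
    oriented = seqcore.reverse_complement(first) + spacer + second
    insert = oriented if strand == "+" else seqcore.reverse_complement(oriented)

    new_seq = rec.seq[:position] + insert + rec.seq[position + full_len :]
    genome = Genome(
        [GenomeRecord(rec.id, new_seq), *genome.records[1:]],
        species_code=genome.species_code,
    )
    mm_first, mm_second = mm_plan
    truth_strand = strand
    if mode in ("LL", "RR") and strand == "-":
        # palindromic query: the '-' implant is a '+' site with halves swapped
        truth_strand = "+"
        mm_first, mm_second = mm_second, mm_first
    truth = TruthRecord(
        record_id=rec.id,
        start=position,
        end=position + full_len,
        mode=mode,
        spacing=spacing,
        strand=truth_strand,
        mm_first=mm_first,
        mm_second=mm_second,
    )
    if occupied is not None:
        occupied.append((position, position + full_len))
    return genome, truth


def make_fixture(
    cfg: SearchConfig,
    n_exact: int,
    n_offtarget: int,
    genome_length: int,
    seed: int,
    fasta_path=None,
    truth_path=None,
) -> tuple[Genome, list[TruthRecord]]:
    """Random genome with exact and off-target implants, plus truth table.

    Off-target implants draw a mode (homo modes only when enabled), a
    spacing, a strand and per-half mismatch counts within the budget but
    not (0, 0).  Deterministic given the seed; optionally writes
    ``fasta_path`` and a TSV truth table to ``truth_path``.
    """
    rng = np.random.default_rng(seed)
    genome = generate_genome(genome_length, seed=rng)
    full_max = max(len(cfg.left), len(cfg.right)) * 2 + max(cfg.spacings)
    if genome_length < (n_exact + n_offtarget) * 3 * full_max:
        raise ValueError("genome too small for the requested number of implants")

    modes = ["LR", "LL", "RR"] if cfg.homodimer else ["LR"]
    truths: list[TruthRecord] = []
    occupied: list[tuple[int, int]] = []
    k = cfg.max_mismatches

    def plan_offtarget() -> tuple[int, int]:
        while True:
            pair = (int(rng.integers(k + 1)), int(rng.integers(k + 1)))
            if pair != (0, 0):
                return pair

    jobs = [("exact", (0, 0))] * n_exact + [
        ("off", None) for _ in range(n_offtarget)
    ]
    for kind, plan in jobs:
        mode = modes[rng.integers(len(modes))]
        spacing = int(cfg.spacings[rng.integers(len(cfg.spacings))])
        strand = "+-"[rng.integers(2)] if mode == "LR" else "+"
        mm_plan = plan if plan is not None else plan_offtarget()
        for _ in range(1000):
            pos = int(rng.integers(0, genome_length - full_max))
            try:
                genome, truth = implant_site(
                    genome, cfg, mode, spacing, strand, mm_plan, pos, rng, occupied
                )
                truths.append(truth)
                break
            except PlacementError:
                continue
        else:
            raise RuntimeError("could not place an implant after 1000 attempts")

    truths.sort(key=lambda t: t.start)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            rec = genome.records[0]
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")
    if truth_path is not None:
        with open(truth_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(TRUTH_COLUMNS)
            for t in truths:
                w.writerow([t.record_id, t.start, t.end, t.mode, t.spacing,
                            t.strand, t.mm_first, t.mm_second])
    return genome, truths


def read_truth_tsv(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    record_id=row["record"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    mode=row["mode"],
                    spacing=int(row["spacing"]),
                    strand=row["strand"],
                    mm_first=int(row["mm_first"]),
                    mm_second=int(row["mm_second"]),
                )
            )
    return out
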