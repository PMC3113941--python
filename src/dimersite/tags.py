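"""Expansion of a degenerate half-site into its concrete tag neighborhood.

The exact-match index can only look up concrete {A,C,G,T} strings, so a
degenerate, mismatch-budgeted query is first expanded into every
concrete "tag" within the budget: exactly the strings ``t`` with
``count_mismatches(pattern, t) <= k``.  Mismatches are permitted at
degenerate positions as well.  Each tag is annotated with its exact
mismatch count at expansion time, so downstream reporting never
recomputes it against the wrong orientation.

The neighborhood size grows combinatorially with the budget and the
number of ambiguity codes; ``count_tags`` gives the exact closed-form
count used for a resource pre-flight before any enumeration happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seqcore

__all__ = ["TagSet", "TagCountError", "expand_exact", "expand_with_mismatches", "count_tags",
           "DEFAULT_TAG_CAP"]

#: Refuse to enumerate neighborhoods larger than this unless forced.
DEFAULT_TAG_CAP = 5_000_000

_BASES = "ACGT"


class TagCountError(RuntimeError):
    """Projected tag count exceeds the configured cap."""


@dataclass
class TagSet:
    """Concrete tags of one pattern with their mismatch annotations."""

    pattern: str
    budget: int
    tags: dict[str, int] = field(default_factory=dict)  # tag -> mismatch count

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def reverse_complement(self) -> "TagSet":
        """The tag set of the reverse-complemented pattern.

        Mismatch counts are invariant under joint reverse complementation,
        so the annotations carry over tag by tag.
        """
        return TagSet(
            pattern=seqcore.reverse_complement(self.pattern),
            budget=self.budget,
            tags={seqcore.reverse_complement(t): c for t, c in self.tags.items()},
        )


def count_tags(set_sizes: list[int], k: int) -> int:
    """Exact neighborhood size for per-position IUPAC set sizes and budget k.

    Computed as the truncated product of per-position generating
    polynomials ``m_i + (4 - m_i) x`` where the coefficient of ``x^j``
    counts tags with exactly j mismatches.
    """
    if any(m not in (1, 2, 3, 4) for m in set_sizes):
        raise ValueError(f"per-position set sizes must be in 1..4: {set_sizes}")
    coeff = [1] + [0] * k  # polynomial truncated at degree k
    for m in set_sizes:
        new = [0] * (k + 1)
        for j, c in enumerate(coeff):
            if c == 0:
                continue
            new[j] += c * m  # match at this position
            if j + 1 <= k:
                new[j + 1] += c * (4 - m)  # mismatch
        coeff = new
    return sum(coeff)


def _set_sizes(pattern: str) -> list[int]:
    return [len(seqcore.IUPAC_SETS[ch]) for ch in pattern]


def expand_with_mismatches(
    pattern: str, k: int, *, cap: int | None = DEFAULT_TAG_CAP
) -> TagSet:
    """Enumerate every concrete string within *k* mismatches of *pattern*.

    Raises :class:`TagCountError` before enumeration if the closed-form
    count exceeds *cap* (pass ``cap=None`` to force).
    """
    pat = seqcore.validate_iupac(pattern)
    if not 0 <= k <= len(pat):
        raise ValueError(f"budget {k} outside [0, {len(pat)}]")
    projected = count_tags(_set_sizes(pat), k)
    if cap is not None and projected > cap:
        raise TagCountError(
            f"pattern {pat!r} with {k} mismatches expands to {projected:,} tags, "
            f"above the cap of {cap:,}; consider breaking the search into parts"
        )
    sets = [seqcore.IUPAC_SETS[ch] for ch in pat]
    tags: dict[str, int] = {}
    L = len(pat)

    # depth-first with pruning on the running mismatch count
    stack = [("", 0)]
    while stack:
        prefix, mm = stack.pop()
        i = len(prefix)
        if i == L:
            tags[prefix] = mm
            continue
        allowed = sets[i]
        for b in _BASES:
            cost = 0 if b in allowed else 1
            if mm + cost <= k:
                stack.append((prefix + b, mm + cost))

    assert len(tags) == projected
    return TagSet(pattern=pat, budget=k, tags=tags)


def expand_exact(pattern: str) -> TagSet:
    """All concretizations of a degenerate pattern (budget 0)."""
    return expand_with_mismatches(pattern, 0)


def dump_tags(tagset: TagSet, stream) -> None:
    """Write one ``tag<TAB>mismatches`` line per tag, sorted by (count, tag)."""
    for tag, mm in sorted(tagset.tags.items(), key=lambda kv: (kv[1], kv[0])):
        stream.write(f"{tag}\t{mm}\n")
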