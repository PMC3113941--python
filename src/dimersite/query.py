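"""Half-site validation, search configuration and dimeric query composition.

A dimeric nuclease target consists of two half-sites bound on opposite
strands with a short spacer between them.  Each half-site is entered
5'->3' in its protein-binding orientation; the composed full-site query
on the forward strand is therefore

    reverse_complement(first half-site) + N^spacing + second half-site

Hetero-dimeric cleavage gives the LR query; when homo-dimerization is
allowed, LL and RR queries are generated as well, so that two spacings
with homo-dimerization yield six query patterns in the deterministic
order (LR, LL, RR) x spacings ascending.

Strict mode enforces web-deployment-friendly resource caps: at most two
mismatches per half-site, and — when scanning with two mismatches —
fewer than three degenerate letters across the pair of half-sites (both
bound the tag-neighborhood blow-up).  Local runs may disable the caps
(``strict_limits=False``), in which case violations are logged as
warnings instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import seqcore

__all__ = [
    "HalfSite",
    "SearchConfig",
    "FullSitePattern",
    "ValidationError",
    "ResourceLimitError",
    "validate_halfsite",
    "parse_spacings",
    "validate_config",
    "compose_patterns",
    "MIN_HALFSITE_LENGTH",
    "MAX_SPACING",
]

log = logging.getLogger(__name__)

MIN_HALFSITE_LENGTH = 6
MAX_SPACING = 20


class ValidationError(ValueError):
    """Invalid user input (half-site, spacing list, or configuration)."""


class ResourceLimitError(ValidationError):
    """A strict-mode resource cap was violated."""


@dataclass(frozen=True)
class HalfSite:
    """One monomer's binding sequence, 5'->3'."""

    role: str  # "left" | "right"
    seq: str
    n_degenerate: int = 0

    def __post_init__(self):
        object.__setattr__(self, "n_degenerate", seqcore.degenerate_count(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


def validate_halfsite(raw: str, role: str) -> HalfSite:
    """Uppercase, IUPAC-validate and wrap a raw half-site string."""
    if role not in ("left", "right"):
        raise ValidationError(f"half-site role must be 'left' or 'right', got {role!r}")
    if not raw:
        raise ValidationError(f"{role} half-site is empty")
    seq = seqcore.validate_iupac(raw, what=f"{role} half-site")
    if len(seq) < MIN_HALFSITE_LENGTH:
        raise ValidationError(
            f"{role} half-site {seq!r} is shorter than "
            f"{MIN_HALFSITE_LENGTH} nt — too unspecific to search"
        )
    return HalfSite(role=role, seq=seq)


def parse_spacings(raw: str) -> list[int]:
    """Parse a comma-separated spacing list, e.g. ``"5,6"`` -> [5, 6].

    One or two distinct non-negative integers are allowed; repeat the
    search with other values if more spacings are needed.
    """
    parts = [p.strip() for p in str(raw).split(",") if p.strip()]
    if not parts:
        raise ValidationError("no spacing given")
    if len(parts) > 2:
        raise ValidationError(
            f"at most two spacings may be searched at once, got {len(parts)}; "
            "repeat the search for additional spacings"
        )
    try:
        vals = [int(p) for p in parts]
    except ValueError as exc:
        raise ValidationError(f"spacings must be integers: {raw!r}") from exc
    if any(v < 0 for v in vals):
        raise ValidationError(f"spacings must be non-negative: {vals}")
    if any(v > MAX_SPACING for v in vals):
        raise ValidationError(f"spacings above {MAX_SPACING} nt are not supported: {vals}")
    if len(set(vals)) != len(vals):
        raise ValidationError(f"duplicate spacing in {vals}")
    return vals


@dataclass(frozen=True)
class SearchConfig:
    left: HalfSite
    right: HalfSite
    spacings: tuple[int, ...] = (5, 6)
    max_mismatches: int = 0
    homodimer: bool = False
    strict_limits: bool = True
    total_mismatch_cap: int | None = None
    #: optional asymmetric budgets; default to max_mismatches for both halves
    max_mismatches_left: int | None = None
    max_mismatches_right: int | None = None

    def budget(self, role: str) -> int:
        if role == "left" and self.max_mismatches_left is not None:
            return self.max_mismatches_left
        if role == "right" and self.max_mismatches_right is not None:
            return self.max_mismatches_right
        return self.max_mismatches

    @classmethod
    def build(
        cls,
        left: str,
        right: str,
        spacings="5,6",
        max_mismatches: int = 0,
        homodimer: bool = False,
        strict_limits: bool = True,
        total_mismatch_cap: int | None = None,
    ) -> "SearchConfig":
        """Validate raw strings and assemble a checked configuration."""
        if isinstance(spacings, str):
            sp = parse_spacings(spacings)
        else:
            sp = parse_spacings(",".join(str(s) for s in spacings))
        cfg = cls(
            left=validate_halfsite(left, "left"),
            right=validate_halfsite(right, "right"),
            spacings=tuple(sp),
            max_mismatches=int(max_mismatches),
            homodimer=homodimer,
            strict_limits=strict_limits,
            total_mismatch_cap=total_mismatch_cap,
        )
        return validate_config(cfg)


def validate_config(cfg: SearchConfig) -> SearchConfig:
    """Enforce (strict) or warn about (non-strict) the resource caps.

    Caps: per-half-site mismatch budget in {0,1,2}; combined degenerate
    count across the pair of half-sites at most 2 when scanning with two
    mismatches.
    """
    if not cfg.spacings or len(cfg.spacings) > 2:
        raise ValidationError("1 or 2 spacings required")
    for s in cfg.spacings:
        if not 0 <= s <= MAX_SPACING:
            raise ValidationError(f"spacing {s} outside [0, {MAX_SPACING}]")
    if cfg.max_mismatches < 0:
        raise ValidationError("mismatch budget must be non-negative")

    budgets = [cfg.budget("left"), cfg.budget("right")]
    n_ambig = cfg.left.n_degenerate + cfg.right.n_degenerate
    problems = []
    if max(budgets) > 2:
        problems.append(
            f"mismatch budget {max(budgets)} exceeds the cap of 2 per half-site"
        )
    if max(budgets) >= 2 and n_ambig > 2:
        problems.append(
            f"{n_ambig} degenerate nucleotides across the half-site pair "
            "exceed the cap of 2 allowed with a 2-mismatch budget"
        )
    if problems:
        if cfg.strict_limits:
            raise ResourceLimitError(
                "; ".join(problems) + " (use strict_limits=False / --no-strict to override)"
            )
        for p in problems:
            log.warning("resource cap exceeded: %s", p)
    return cfg


@dataclass(frozen=True)
class FullSitePattern:
    """A composed dimeric query: revcomp(first half) + N^spacing + second half."""

    mode: str  # "LR" | "LL" | "RR"
    spacing: int
    first: HalfSite
    second: HalfSite
    pattern: str = field(init=False)

    def __post_init__(self):
        pat = (
            seqcore.reverse_complement(self.first.seq)
            + "N" * self.spacing
            + self.second.seq
        )
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)


_MODE_HALVES = {"LR": ("left", "right"), "LL": ("left", "left"), "RR": ("right", "right")}


def compose_patterns(cfg: SearchConfig) -> list[FullSitePattern]:
    """All full-site query patterns for a configuration.

    One LR pattern per spacing; LL and RR added when homo-dimerization is
    enabled.  Order is (LR, LL, RR) x spacings ascending, so two spacings
    with homo-dimerization give exactly six patterns.
    """
    halves = {"left": cfg.left, "right": cfg.right}
    modes = ["LR", "LL", "RR"] if cfg.homodimer else ["LR"]
    out = []
    for mode in modes:
        a, b = _MODE_HALVES[mode]
        for s in sorted(cfg.spacings):
            out.append(FullSitePattern(mode=mode, spacing=s, first=halves[a], second=halves[b]))
    return out
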