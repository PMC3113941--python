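"""Ranking of found sites with SELEX-derived position weight matrices.

In-vitro selection (SELEX) yields, for each position of a half-site, the
frequency with which each base was bound.  Those raw frequencies become
a position weight matrix after replacing exact zeros with a small
pseudocount (so a single unobserved base does not annihilate a product);
no renormalization is applied — the pseudocount is a minimal
intervention, and scale equivariance of the product score makes any
silent renormalization detectable.

A half-site score is the product over positions of the weight of the
observed base, accumulated in log space for numerical safety.  A site's
ranking score is the product of its two half-site scores, each computed
on the block read in half-site orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqcore
from .assembly import DimericSite

__all__ = ["FrequencyMatrix", "PWM", "build_pwm", "score_halfsite", "rank_sites",
           "read_frequency_tsv", "DEFAULT_PSEUDOCOUNT"]

DEFAULT_PSEUDOCOUNT = 1e-4
_BASES = "ACGT"
_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base frequencies; rows (positions) sum to 1."""

    freqs: np.ndarray  # shape (L, 4), columns A C G T

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError(f"frequency matrix must be (L, 4), got {f.shape}")
        if (f < 0).any():
            raise ValueError("negative frequency")
        sums = f.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
        if bad.size:
            raise ValueError(
                f"row {bad[0] + 1} sums to {sums[bad[0]]:.6g}, expected 1"
            )

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class PWM:
    weights: np.ndarray  # (L, 4), strictly positive
    pseudocount: float

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=1))


def build_pwm(freqs: FrequencyMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    """Replace zero frequencies with *pseudocount*; no renormalization."""
    if not 0 < pseudocount < 0.01:
        raise ValueError(f"pseudocount must be in (0, 0.01), got {pseudocount}")
    w = freqs.freqs.copy()
    w[w == 0] = pseudocount
    return PWM(weights=w, pseudocount=pseudocount)


def read_frequency_tsv(source) -> FrequencyMatrix:
    """Load a ``pos A C G T`` TSV (1-based positions, ascending)."""
    df = pd.read_csv(source, sep="\t")
    required = ["pos", *_BASES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table is missing columns {missing}")
    df = df.sort_values("pos")
    if list(df["pos"]) != list(range(1, len(df) + 1)):
        raise ValueError("positions must be 1..L without gaps")
    return FrequencyMatrix(df[list(_BASES)].to_numpy(dtype=float))


def score_halfsite(pwm: PWM, seq: str) -> float:
    """Product of per-position weights of the observed bases."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.length}")
    idx = []
    for i, ch in enumerate(seq.upper()):
        if ch not in _BASES:
            raise ValueError(
                f"cannot score ambiguous base {ch!r} at position {i + 1}"
            )
        idx.append(_BASES.index(ch))
    return float(np.exp(np.log(pwm.weights[np.arange(pwm.length), idx]).sum()))


_MODE_PWMS = {"LR": ("left", "right"), "LL": ("left", "left"), "RR": ("right", "right")}


def rank_sites(
    sites: list[DimericSite], pwm_left: PWM, pwm_right: PWM
) -> list[tuple[DimericSite, float]]:
    """Score and order sites by descending PWM ranking score.

    Each site's two half blocks are read in half-site orientation (the
    oriented sequence's upstream block reverse-complemented) and scored
    against the PWMs its mode calls for; the ranking score is the
    product of the two half scores.  Ties break by increasing total
    mismatches, then record and start.
    """
    pwms = {"left": pwm_left, "right": pwm_right}
    scored = []
    for site in sites:
        a_name, b_name = _MODE_PWMS[site.mode]
        pa, pb = pwms[a_name], pwms[b_name]
        oriented = site.oriented_sequence()
        first_block = seqcore.reverse_complement(oriented[: pa.length])
        second_block = oriented[len(oriented) - pb.length :]
        if pa.length + site.spacing + pb.length != len(oriented):
            raise ValueError(
                f"PWM lengths ({pa.length}, {pb.length}) do not fit site "
                f"{site.record_id}:{site.start}-{site.end}"
            )
        score = score_halfsite(pa, first_block) * score_halfsite(pb, second_block)
        scored.append((site, score))
    scored.sort(key=lambda t: (-t[1], t[0].mm_total, t[0].record_id, t[0].start))
    return scored
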