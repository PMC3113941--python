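"""Result rendering: two-line text blocks, TSV/BED tables, browser links.

The classic text layout prints each found site as a pair of lines: the
top line is the site sequence in query orientation with half-site
blocks in uppercase and the spacer in lowercase; the bottom line has
one character per sequence column — blank where the genome satisfies
the query pattern, the genomic base where it does not, and one ``N``
per spacer nucleotide — followed by the mismatch count, species code,
1-based inclusive coordinates ``[start..end]``, and strand.

Reported coordinates are 1-based inclusive; BED output follows the BED
convention (0-based half-open).  Internally everything is 0-based
half-open.
"""

from __future__ import annotations

import logging

import pandas as pd
import yaml

from . import seqcore
from .assembly import DimericSite
from .query import SearchConfig

__all__ = ["format_two_line", "sort_sites", "write_tsv", "read_tsv",
           "write_bed", "browser_links", "load_species_config", "write_text"]

log = logging.getLogger(__name__)

_MODE_HALVES = {"LR": ("left", "right"), "LL": ("left", "left"), "RR": ("right", "right")}

TSV_COLUMNS = [
    "record", "start_1based", "end_1based", "strand", "mode", "spacing",
    "upstream_block", "spacer", "downstream_block",
    "mm_first", "mm_second", "mm_total",
]


def _oriented_pattern(site: DimericSite, cfg: SearchConfig) -> str:
    halves = {"left": cfg.left, "right": cfg.right}
    a, b = (halves[r] for r in _MODE_HALVES[site.mode])
    return seqcore.reverse_complement(a.seq) + "N" * site.spacing + b.seq


def format_two_line(
    site: DimericSite,
    cfg: SearchConfig,
    species_code: str = "NA",
    links: list[str] | None = None,
) -> str:
    """Render one site as its two-line text block."""
    pattern = _oriented_pattern(site, cfg)
    oriented = site.oriented_sequence()
    halves = {"left": cfg.left, "right": cfg.right}
    len_a = len(halves[_MODE_HALVES[site.mode][0]])
    spacer_lo = len_a
    spacer_hi = len_a + site.spacing

    line1 = (
        oriented[:spacer_lo]
        + oriented[spacer_lo:spacer_hi].lower()
        + oriented[spacer_hi:]
    )
    marks = []
    for i, (p, b) in enumerate(zip(pattern, oriented)):
        if spacer_lo <= i < spacer_hi:
            marks.append("N")
        elif seqcore.iupac_matches(p, b):
            marks.append(" ")
        else:
            marks.append(b)
    line2 = "".join(marks)
    meta = (
        f"  {site.mm_total}  {species_code}  "
        f"[{site.start + 1}..{site.end}]  {site.strand}"
    )
    if links:
        meta += "  " + "  ".join(links)
    return line1 + "\n" + line2 + meta


def sort_sites(sites: list[DimericSite], order: str = "position") -> list[DimericSite]:
    """Stable total ordering by genome position or by mismatch count."""
    pos_key = lambda s: (s.record_id, s.start, s.mode)
    if order == "position":
        return sorted(sites, key=pos_key)
    if order == "mismatches":
        return sorted(sites, key=lambda s: (s.mm_total, *pos_key(s)))
    raise ValueError(f"unknown sort order {order!r}; use 'position' or 'mismatches'")


def sites_to_frame(
    sites: list[DimericSite],
    scores: list[float] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sites):
        row = {
            "record": s.record_id,
            "start_1based": s.start + 1,
            "end_1based": s.end,
            "strand": s.strand,
            "mode": s.mode,
            "spacing": s.spacing,
            "upstream_block": s.upstream_block,
            "spacer": s.spacer_seq,
            "downstream_block": s.downstream_block,
            "mm_first": s.mm_first,
            "mm_second": s.mm_second,
            "mm_total": s.mm_total,
        }
        if scores is not None:
            row["score"] = scores[i]
            row["rank"] = i + 1
        rows.append(row)
    cols = TSV_COLUMNS + (["score", "rank"] if scores is not None else [])
    return pd.DataFrame(rows, columns=cols)


def write_tsv(sites: list[DimericSite], stream, scores: list[float] | None = None) -> None:
    sites_to_frame(sites, scores).to_csv(stream, sep="\t", index=False)


def read_tsv(source) -> list[DimericSite]:
    """Re-parse a site TSV into site records (lossless round-trip)."""
    df = pd.read_csv(source, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            DimericSite(
                mode=r["mode"],
                record_id=str(r["record"]),
                start=int(r["start_1based"]) - 1,
                end=int(r["end_1based"]),
                strand=r["strand"],
                spacing=int(r["spacing"]),
                upstream_block=r["upstream_block"],
                spacer_seq=r["spacer"],
                downstream_block=r["downstream_block"],
                mm_first=int(r["mm_first"]),
                mm_second=int(r["mm_second"]),
            )
        )
    return out


def write_bed(sites: list[DimericSite], stream) -> None:
    """BED6: 0-based half-open, name mode:spacing:mmTotal, score scaled by mm."""
    for s in sites:
        score = max(0, 1000 - 250 * s.mm_total)
        stream.write(
            f"{s.record_id}\t{s.start}\t{s.end}\t"
            f"{s.mode}:{s.spacing}:{s.mm_total}\t{score}\t{s.strand}\n"
        )


def write_text(
    sites: list[DimericSite],
    cfg: SearchConfig,
    stream,
    species_code: str = "NA",
    templates: dict | None = None,
) -> None:
    for s in sites:
        links = browser_links(s, templates, species_code) if templates else []
        stream.write(format_two_line(s, cfg, species_code, links) + "\n")


def load_species_config(source) -> dict:
    """Load a YAML mapping: species code -> {assembly, templates: [url, ...]}."""
    if hasattr(source, "read"):
        return yaml.safe_load(source) or {}
    with open(source) as fh:
        return yaml.safe_load(fh) or {}


def browser_links(
    site: DimericSite, config: dict | None, species_code: str
) -> list[str]:
    """Fill per-species URL templates with 1-based inclusive coordinates.

    Template placeholders: ``{assembly}``, ``{record}``, ``{start}``,
    ``{end}``.  An unconfigured species yields no links and a warning.
    """
    entry = (config or {}).get(species_code)
    if not entry:
        log.warning("no browser templates configured for species %r", species_code)
        return []
    assembly = entry.get("assembly", "")
    return [
        t.format(
            assembly=assembly,
            record=site.record_id,
            start=site.start + 1,
            end=site.end,
        )
        for t in entry.get("templates", [])
    ]
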