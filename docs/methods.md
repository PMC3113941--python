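# Methods

## The search problem

A dimeric nuclease site is fully specified by two half-site patterns over
the 15-letter IUPAC alphabet, a spacer length, and an orientation: the
forward-strand site is `revcomp(first half) · N^s · second half`.  Matching
is pure fixed-length Hamming-style comparison — no alignment, no indels —
with set-wise semantics at degenerate positions: a genome base inside the
position's set costs nothing, outside it costs one mismatch.  The result
contract is exhaustiveness: for a per-half-site budget *k*, every genomic
window on either strand whose two half blocks are each within *k*
mismatches is reported, and nothing else.

## Genomic N policy

Assemblies use `N` for unknown sequence.  A genomic `N` satisfies **no**
pattern letter, including pattern `N`; treating it as a wildcard would
inflate off-target lists with windows in assembly gaps.  Consequently a
window overlapping *j* Ns can still match, but only by spending *j* of its
mismatch budget.  Soft-masked (lowercase) bases are case-folded and searched
by default; `read_fasta(..., mask_lowercase=True)` converts them to `N`
instead, which excludes masked windows under the same policy.

## Engines and the exhaustiveness contract

Two independent implementations share the result contract:

* **indexed** — the half-site query is expanded into its complete tag
  neighborhood (below) and each concrete tag is looked up in a word index
  holding one entry for every window of the half-site's length composed
  purely of A/C/G/T.  Windows overlapping an `N` cannot be exact words, so
  the index records their positions and the engine scores that (small)
  residue with direct mismatch counts — without this the two engines would
  disagree exactly on N-adjacent, within-budget windows.
* **direct** — a vectorized sliding-window mismatch profile (numpy, one
  boolean table lookup per pattern position) at every offset on both
  strands.

Engine selection defaults to `auto`: direct below 5 kb of total sequence
(an index would cost more to build than it saves), indexed above.  The word
length equals the half-site length, so one index is built per distinct
half-site length and shared between queries.

A third, deliberately separate path — `scan_full_patterns` — slides each
*composed* full-site pattern over the genome, scoring the upstream and
downstream half blocks per offset with no tag expansion, no index and no
pairing step.  It is the end-to-end oracle: the test suite and the
acceptance script assert its output is identical to the indexed pipeline
across budgets, spacings and dimerization modes on random genomes.

## Tag expansion

`expand_with_mismatches(p, k)` enumerates exactly `{t ∈ {A,C,G,T}^L :
d(p,t) ≤ k}` by depth-first search with pruning on the running mismatch
count; mismatches are allowed at degenerate positions too.  Each tag is
annotated with its exact mismatch count at expansion time.  The count has a
closed form (truncated product of per-position generating polynomials
`m_i + (4−m_i)x`), evaluated before enumeration as a resource pre-flight:
expansions projected above 5,000,000 tags raise an error suggesting the
search be split (pass `cap=None` to force).  The closed form and the
enumeration are tested against brute-force filtering of all `4^L` strings
for patterns up to length 8.

## Dimer assembly and strand conventions

Half-site match lists are paired per record by hashing plus-strand match
starts and probing from each minus-strand match (linear time).  The ordered
modes enumerated are (L,R) → hetero site on `+`, (R,L) → hetero site on
`−`, and (L,L)/(R,R) once each when homo-dimerization is on.  A homo-dimer
query is its own reverse complement, so its ordered pair fires exactly once
per genomic interval; homo sites are labelled `+` by convention (the dimer
is orientation-symmetric).  Per-half counts `mm_first`/`mm_second` always
refer to the mode's ordered halves read in site orientation, so they are
directly comparable across strands and with implant plans.  Overlapping
sites (e.g. spacings 5 and 6 sharing bases) are reported independently.

Strict mode applies web-deployment-friendly resource caps — budgets limited
to 2 per half-site, and at most 2 degenerate letters across the *pair* of
half-sites when scanning with 2 mismatches.  The pair-wise reading was a
genuinely open choice (a per-half reading is also defensible); pair-wise is
the more conservative bound on tag-count blow-up and is what the cap
exists to control.  `strict_limits=False` downgrades violations to log
warnings for local runs.  Spacings: one or two distinct values in [0, 20].

## PWM ranking

SELEX-style per-position base frequencies (rows summing to 1, tolerance
1e-6) become weights by replacing exact zeros with a pseudocount
(default 1e-4, valid range (0, 0.01)); deliberately **no renormalization**
follows — the pseudocount is a minimal intervention, and the resulting
scale equivariance (scaling one position's weights by *c* scales every
score by *c*) is a tested property that would expose silent renormalization.
A half-site score is the product of per-position weights, accumulated in
log space and exponentiated for display; a site's ranking score is the
product of its two half-site scores, each half block read in half-site
orientation and scored against the PWM its mode calls for.  Product (rather
than sum) of half scores was an open choice; it keeps the site score a
single joint likelihood-like quantity and makes consensus maximality hold
site-wide.  Ties in the descending score order break by (total mismatches,
record, start), giving a total deterministic order.  Ambiguous bases in a
scored block are an error rather than silently approximated.

## Synthetic fixtures

The generator emulates only what the tests need: i.i.d. background sequence
with configurable base composition, and implanted sites with *planned*
per-half mismatch counts.  Implanting concretizes the composed query
(degenerate positions drawn uniformly within their sets — never a
mismatch; spacer bases uniform), then corrupts exactly the planned number
of randomly chosen non-degenerate positions per half, so re-scoring an
implant reproduces its plan exactly.  Implants stay at least one full-site
length apart.  Minus-strand homo implants are canonicalized in the truth
table (strand `+`, half counts swapped) to match the search convention.
The generator has no repeats, isochores, masking or N runs, so passing
tests demonstrate the combinatorial correctness of the search on realistic
composition — not robustness to repeat structure, which only affects how
*many* background sites exist, not whether they are found.  Chance
background hits are expected and are confirmed against the oracle rather
than excluded by construction.

## Problem sizes and numerical choices

The equivalence sweep uses 50 random 20 kb genomes crossed with budgets
{0,1,2}, spacing sets {5},{6},{5,6} and homo-dimerization on/off (900
pipeline runs); fixture recovery uses five 100 kb genomes with 2 exact and
5 off-target implants each.  These sizes give thousands of background
half-site matches and hundreds of assembled sites per sweep, which is ample
to exercise every pairing and strand path; results are byte-deterministic
given the seed.  Coordinates are 0-based half-open internally and converted
to 1-based inclusive only at report time (BED output stays 0-based
half-open per the BED standard).  Report rendering carries match/spacer/
mismatch roles as case and annotation characters rather than color.

## Known limitations

* Whole mammalian genomes are within the algorithm's reach (the index is
  linear in genome size) but the pure-Python index build is slow at that
  scale; the direct engine's numpy path is the practical choice there.
* No cleavage-activity model: spacer sequence, linker biophysics and
  chromatin context are out of scope; the tool enumerates sequence-
  compatible sites only.
* Genome-browser URL templates are configuration, not contract; none ship
  enabled by default.
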