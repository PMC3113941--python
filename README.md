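# dimersite

Exhaustive genome search for dimeric nuclease target and off-target sites.

Engineered nucleases such as zinc-finger nucleases (ZFNs) and TALE nucleases
cleave DNA as dimers: two monomers (designated *left* and *right*) bind
half-sites on opposite strands, separated by a short spacer (usually 5–6 nt),
and the fused FokI domains dimerize between them.  Because binding tolerates
some sequence variation, a genome typically contains *off-target* sites —
loci similar enough to the intended target to risk unintended cleavage.
Finding **every** such locus matters: local-alignment heuristics (BLAST and
kin) use seeded word matching and E-value thresholds that do not map onto a
"number of mismatches" contract and can silently miss sites.

`dimersite` is for researchers choosing nuclease target sites or compiling
candidate off-target lists for experimental cleavage assays.  Given two
half-sites written 5'→3' in protein-binding orientation (IUPAC ambiguity
codes allowed, e.g. to encode SELEX-derived relaxed specificity), allowed
spacer lengths, and a per-half-site mismatch budget *k*, it returns the
complete list of matching sites — guaranteed, not heuristic.

## Method

For half-sites *L* and *R* and spacing *s* the forward-strand query is

```
revcomp(L) · N^s · R            (hetero-dimer, "LR")
revcomp(L) · N^s · L            (homo-dimer,  "LL")
revcomp(R) · N^s · R            (homo-dimer,  "RR")
```

so two spacings with homo-dimerization enabled give six query patterns.
Each half-site query is expanded into its complete Hamming neighborhood of
concrete tags — exactly the strings *t* with `d(pattern, t) ≤ k`, where
degenerate positions match set-wise and cost nothing (unless the genome base
falls outside the set).  The neighborhood size has the closed form

```
|T(k)| = Σ_{j≤k} Σ_{|S|=j} Π_{i∈S}(4−m_i) Π_{i∉S} m_i
```

(*m_i* = IUPAC set size at position *i*; e.g. a concrete 12-mer at *k*=2
expands to 1 + 36 + 594 = 631 tags).  Tags are looked up in a word index
with **one entry per genomic nucleotide**, so no occurrence can be missed;
an independent sliding-window scan engine implements the identical contract
and is used to verify it.  Half-site matches on both strands are then paired
into spacing-constrained dimeric sites, with per-half and total mismatch
counts, and can be capped at a total-mismatch threshold (e.g. ≤ 3) to narrow
long lists.  Optionally, sites are ranked by a position-weight-matrix score:
per-position SELEX base frequencies with zeros replaced by a small
pseudocount, half-site score = product of per-position weights, site score =
product of the two half-site scores.

## Worked example

The classic three-finger-pair target reads
`5'-CGGAGCCGCTTTaacccACTCTGTGGAAG-3'`: the left half-site is entered as
`AAAGCGGCTCCG` (the reverse complement of the bold upstream block), the
right as `ACTCTGTGGAAG`, with a 5 nt spacer.  Implant one exact site in a
random 5 kb genome and search for it:

```sh
dimersite simulate --length 5000 --left AAAGCGGCTCCG --right ACTCTGTGGAAG \
    --spacings 5,6 --mismatches 0 --n-exact 1 --n-offtarget 0 --seed 42 -o demo
dimersite search --genome demo.fa --left AAAGCGGCTCCG --right ACTCTGTGGAAG \
    --spacings 5,6 --mismatches 1 --homodimer
```

The truth table `demo.truth.tsv` records the implant at 0-based interval
[2586, 2615); the search prints exactly that site:

```
CGGAGCCGCTTTgctgaACTCTGTGGAAG
            NNNNN              0  NA  [2587..2615]  +
```

Top line: the genomic sequence, half-site blocks uppercase, spacer
lowercase.  Bottom line: one `N` per spacer nucleotide, a base letter under
every mismatched column (none here), then the total mismatch count (0), the
species code, 1-based inclusive coordinates `[start..end]`, and the strand.
`--format tsv` / `--format bed` emit machine-readable tables;
`--sort mismatches` orders output by increasing total mismatches;
`--pwm-left/--pwm-right` rank sites by PWM score; `--species-config`
attaches genome-browser URLs.

The same pipeline is available as a library:

```python
from dimersite import SearchConfig, find_sites, read_fasta

cfg = SearchConfig.build("AAAGCGGCTCCG", "ACTCTGTGGAAG", "5,6",
                         max_mismatches=2, homodimer=True)
sites = find_sites(read_fasta("genome.fa"), cfg)
```

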