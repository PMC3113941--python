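"""Dimer assembly: pairing, strand conventions, oracle equivalence."""

import pytest

from dimersite import (
    Genome,
    SearchConfig,
    filter_total_mismatches,
    find_sites,
    generate_genome,
    reverse_complement,
    scan_full_patterns,
)

from conftest import IL2RG_TARGET, LEFT, RIGHT, implant


def one_record(seq: str) -> Genome:
    return Genome.from_dict({"chr1": seq})


class TestWorkedExample:
    """The three-finger pair's printed 29-mer target with a 5 nt spacer."""

    def test_exact_lr_site_recovered(self, il2rg_cfg, random_genome_5kb):
        seq = implant(random_genome_5kb.records[0].seq, IL2RG_TARGET, 1000)
        sites = find_sites(one_record(seq), il2rg_cfg, engine="indexed")
        assert len(sites) == 1
        s = sites[0]
        assert (s.mode, s.strand, s.spacing, s.mm_total) == ("LR", "+", 5, 0)
        assert (s.start, s.end) == (1000, 1029)
        assert s.upstream_block == "CGGAGCCGCTTT"
        assert s.spacer_seq == "AACCC"
        assert s.downstream_block == RIGHT

    def test_reverse_complement_insert_reported_minus(self, il2rg_cfg,
                                                      random_genome_5kb):
        rc = reverse_complement(IL2RG_TARGET)
        seq = implant(random_genome_5kb.records[0].seq, rc, 1000)
        sites = find_sites(one_record(seq), il2rg_cfg, engine="indexed")
        assert len(sites) == 1
        s = sites[0]
        assert (s.mode, s.strand, s.spacing) == ("LR", "-", 5)
        assert (s.start, s.end) == (1000, 1029)
        assert s.oriented_sequence() == IL2RG_TARGET

    def test_rr_homodimer_site(self, random_genome_5kb):
        cfg = SearchConfig.build(LEFT, "AAACTGCAAAAG", "6", homodimer=True)
        insert = "CTTTTGCAGTTT" + "ACGTAC" + "AAACTGCAAAAG"
        seq = implant(random_genome_5kb.records[0].seq, insert, 2000)
        sites = find_sites(one_record(seq), cfg, engine="indexed")
        rr = [s for s in sites if s.mode == "RR"]
        assert len(rr) == 1
        assert (rr[0].strand, rr[0].spacing, rr[0].mm_total) == ("+", 6, 0)

    def test_homodimer_site_reported_exactly_once(self, random_genome_5kb):
        # the homo query is palindromic; the site must not be double-counted
        cfg = SearchConfig.build(LEFT, RIGHT, "5", homodimer=True)
        insert = reverse_complement(LEFT) + "TTTTT" + LEFT
        seq = implant(random_genome_5kb.records[0].seq, insert, 700)
        sites = [s for s in find_sites(one_record(seq), cfg) if s.mode == "LL"]
        assert len(sites) == 1 and sites[0].strand == "+"


class TestFilterTotalMismatches:
    def test_cap_three_keeps_at_most_three(self):
        cfg = SearchConfig.build(LEFT, RIGHT, "5", max_mismatches=2)
        g = generate_genome(2_000, seed=5)
        seq = g.records[0].seq
        # implant sites with per-half (0,0), (1,1), (2,1), (2,2)
        inserts = {
            0: IL2RG_TARGET,
            1: "CGGAGCCGCTTA" + "AACCC" + "TCTCTGTGGAAG",  # 1+1
            2: "CGGAGCCGCTAA" + "AACCC" + "TCTCTGTGGAAG",  # 2+1
            3: "CGGAGCCGCTAA" + "AACCC" + "TCTCTGTGGAAC",  # 2+2
        }
        for i, ins in inserts.items():
            seq = implant(seq, ins, 100 + 200 * i)
        sites = find_sites(one_record(seq), cfg, engine="direct")
        totals = sorted(s.mm_total for s in sites)
        assert totals == [0, 2, 3, 4]
        kept = filter_total_mismatches(sites, 3)
        assert sorted(s.mm_total for s in kept) == [0, 2, 3]
        assert filter_total_mismatches(sites, 0) == [s for s in sites if s.mm_total == 0]
        assert filter_total_mismatches(sites, 4) == sites


@pytest.mark.parametrize("homodimer", [False, True])
@pytest.mark.parametrize("k", [0, 1, 2])
def test_pipeline_equals_full_pattern_oracle(k, homodimer):
    """Indexed pipeline vs independent composed-pattern sliding scan."""
    for seed in (0, 1, 2):
        g = generate_genome(20_000, seed=seed)
        cfg = SearchConfig.build(LEFT, RIGHT, "5,6", max_mismatches=k,
                                 homodimer=homodimer)
        assert find_sites(g, cfg, engine="indexed") == scan_full_patterns(g, cfg)


def test_pipeline_oracle_equivalence_with_background_hits():
    """Short, degenerate half-sites produce real background hits; the
    engines and the oracle must agree on every one of them."""
    cfg = SearchConfig.build("ACGTRA", "TWGCAC", "5", max_mismatches=2,
                             homodimer=True, strict_limits=False)
    g = generate_genome(20_000, seed=0)
    a = find_sites(g, cfg, engine="indexed")
    b = find_sites(g, cfg, engine="direct")
    c = scan_full_patterns(g, cfg)
    assert len(a) > 50  # the check is non-vacuous
    assert a == b == c


def test_no_duplicate_sites():
    cfg = SearchConfig.build("ACGTRA", "TWGCAC", "5,6", max_mismatches=2,
                             homodimer=True, strict_limits=False)
    g = generate_genome(20_000, seed=7)
    sites = find_sites(g, cfg)
    keys = [(s.record_id, s.start, s.end, s.mode, s.strand) for s in sites]
    assert len(keys) == len(set(keys))


def test_hetero_strand_symmetry_under_genome_revcomp():
    cfg = SearchConfig.build("ACGTRA", "TWGCAC", "5", max_mismatches=2,
                             strict_limits=False)
    g = generate_genome(20_000, seed=4)
    L = len(g.records[0].seq)
    grc = one_record(reverse_complement(g.records[0].seq))
    fwd = find_sites(g, cfg)
    rev = find_sites(grc, cfg)
    flip = {"+": "-", "-": "+"}
    mirrored = sorted((L - s.end, L - s.start, flip[s.strand], s.mm_first,
                       s.mm_second, s.spacing) for s in rev)
    assert mirrored == sorted((s.start, s.end, s.strand, s.mm_first,
                               s.mm_second, s.spacing) for s in fwd)
    assert fwd  # non-vacuous
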