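"""PWM construction and product-score ranking of found sites."""

import io

import numpy as np
import pytest

from dimersite import SearchConfig, find_sites, generate_genome
from dimersite.pwm import (
    DEFAULT_PSEUDOCOUNT,
    FrequencyMatrix,
    build_pwm,
    rank_sites,
    read_frequency_tsv,
    score_halfsite,
)

from conftest import IL2RG_TARGET, LEFT, RIGHT, implant


def deterministic_freqs(seq: str) -> FrequencyMatrix:
    """Rows putting probability 1 on the consensus base at each position."""
    f = np.zeros((len(seq), 4))
    for i, ch in enumerate(seq):
        f[i, "ACGT".index(ch)] = 1.0
    return FrequencyMatrix(f)


class TestFrequencyMatrix:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            FrequencyMatrix(np.array([[0.5, 0.5, 0.1, 0.0]]))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FrequencyMatrix(np.array([[1.2, -0.2, 0.0, 0.0]]))

    def test_tsv_round_trip(self):
        tsv = "pos\tA\tC\tG\tT\n1\t1\t0\t0\t0\n2\t0.25\t0.25\t0.25\t0.25\n"
        fm = read_frequency_tsv(io.StringIO(tsv))
        assert fm.length == 2
        assert fm.freqs[0, 0] == 1.0

    def test_tsv_requires_contiguous_positions(self):
        tsv = "pos\tA\tC\tG\tT\n1\t1\t0\t0\t0\n3\t1\t0\t0\t0\n"
        with pytest.raises(ValueError, match="1..L"):
            read_frequency_tsv(io.StringIO(tsv))


class TestBuildPwm:
    def test_zeros_replaced_by_pseudocount(self):
        pwm = build_pwm(deterministic_freqs("A"), 1e-4)
        assert list(pwm.weights[0]) == [1.0, 1e-4, 1e-4, 1e-4]

    def test_uniform_rows_unchanged(self):
        fm = FrequencyMatrix(np.full((3, 4), 0.25))
        pwm = build_pwm(fm)
        assert (pwm.weights == 0.25).all()

    @pytest.mark.parametrize("eps", [0.0, -1e-4, 0.5])
    def test_pseudocount_bounds(self, eps):
        with pytest.raises(ValueError):
            build_pwm(deterministic_freqs("A"), eps)


class TestScoreHalfsite:
    def test_consensus_scores_one_on_deterministic_pwm(self):
        pwm = build_pwm(deterministic_freqs("ACGT"))
        assert score_halfsite(pwm, "ACGT") == pytest.approx(1.0)

    def test_uniform_pwm_closed_form(self):
        pwm = build_pwm(FrequencyMatrix(np.full((3, 4), 0.25)))
        assert score_halfsite(pwm, "GAT") == pytest.approx(0.25 ** 3)

    def test_single_off_consensus_base_costs_one_pseudocount_factor(self):
        pwm = build_pwm(deterministic_freqs("ACGT"), 1e-4)
        assert score_halfsite(pwm, "ACGA") == pytest.approx(1e-4)

    def test_ambiguous_base_rejected(self):
        pwm = build_pwm(deterministic_freqs("ACGT"))
        with pytest.raises(ValueError, match="ambiguous"):
            score_halfsite(pwm, "ACGN")

    def test_length_contract(self):
        pwm = build_pwm(deterministic_freqs("ACGT"))
        with pytest.raises(ValueError, match="length"):
            score_halfsite(pwm, "ACG")


def random_freqs(rng, length) -> FrequencyMatrix:
    f = rng.dirichlet(np.ones(4), size=length)
    return FrequencyMatrix(f)


class TestScoreProperties:
    def test_consensus_maximality(self):
        rng = np.random.default_rng(12)
        fm = random_freqs(rng, 8)
        pwm = build_pwm(fm)
        consensus = pwm.consensus()
        best = score_halfsite(pwm, consensus)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), 8))
            assert score_halfsite(pwm, seq) <= best

    def test_single_substitution_monotonicity(self):
        pwm = build_pwm(FrequencyMatrix(np.array([[0.5, 0.3, 0.2, 0.0]] * 4)))
        base = score_halfsite(pwm, "AAAA")
        worse = score_halfsite(pwm, "AACA")  # C has weight 0.3 < 0.5
        assert worse < base

    def test_scale_equivariance(self):
        # multiplying one position's weights by c scales every score by c;
        # guards against silent renormalization
        fm = random_freqs(np.random.default_rng(5), 5)
        pwm = build_pwm(fm)
        scaled = type(pwm)(weights=pwm.weights * np.array([[2.0], [1], [1], [1], [1]]),
                           pseudocount=pwm.pseudocount)
        for seq in ("ACGTA", "TTTTT", "GATCA"):
            assert score_halfsite(scaled, seq) == pytest.approx(
                2.0 * score_halfsite(pwm, seq))


class TestRankSites:
    def _sites_with_implants(self):
        cfg = SearchConfig.build(LEFT, RIGHT, "5", max_mismatches=2)
        g = generate_genome(3_000, seed=21)
        seq = g.records[0].seq
        seq = implant(seq, IL2RG_TARGET, 200)
        seq = implant(seq, "CGGAGCCGCTTA" + "AACCC" + RIGHT, 600)  # 1 mm
        seq = implant(seq, "CGGAGCCGCTAA" + "AACCC" + RIGHT, 1100)  # 2 mm
        from dimersite import Genome
        sites = find_sites(Genome.from_dict({"chr1": seq}), cfg)
        return cfg, sites

    def test_exact_site_ranks_first(self):
        cfg, sites = self._sites_with_implants()
        rng = np.random.default_rng(3)
        # any valid frequency matrix biased to the half-sites ranks the
        # exact implant first; use the deterministic (consensus) matrices
        pl = build_pwm(deterministic_freqs(LEFT))
        pr = build_pwm(deterministic_freqs(RIGHT))
        ranked = rank_sites(sites, pl, pr)
        assert ranked[0][0].mm_total == 0
        assert [s.mm_total for s, _ in ranked] == sorted(s.mm_total for s in sites)

    def test_scores_decrease_with_off_consensus_bases(self):
        cfg, sites = self._sites_with_implants()
        pl = build_pwm(deterministic_freqs(LEFT), 1e-3)
        pr = build_pwm(deterministic_freqs(RIGHT), 1e-3)
        ranked = dict((s.start, sc) for s, sc in rank_sites(sites, pl, pr))
        assert ranked[200] == pytest.approx(1.0)
        assert ranked[600] == pytest.approx(1e-3)
        assert ranked[1100] == pytest.approx(1e-6)

    def test_empty_site_list(self):
        pl = build_pwm(deterministic_freqs(LEFT))
        pr = build_pwm(deterministic_freqs(RIGHT))
        assert rank_sites([], pl, pr) == []

    def test_length_mismatch_rejected(self):
        _, sites = self._sites_with_implants()
        short = build_pwm(deterministic_freqs("ACGTAC"))
        with pytest.raises(ValueError):
            rank_sites(sites, short, short)
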