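"""Antisense alignment against an independent oracle; table import."""

import numpy as np
import pytest

from srnanet.errors import ParseError, RegionError, ValidationError
from srnanet.predict import (
    AlignParams,
    antisense_align,
    network_from_interactions,
    parse_intarna_table,
    predict_network,
    rescore_trace,
)
from srnanet.sequence_io import reverse_complement
from srnanet.synthgen import generate_antisense_case

DEFAULTS = AlignParams()


def oracle_best_score(srna: str, utr: str, p: AlignParams = DEFAULTS) -> float:
    """Independent quadratic Smith-Waterman oracle, formulated directly in
    duplex space: the sRNA is aligned against the UTR read 3'->5' and a
    pair scores match if Watson-Crick, wobble if G-U."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}
    b = utr[::-1]
    n, m = len(srna), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pair = (srna[i - 1], b[j - 1])
            s = p.match if pair in wc else p.wobble if pair in wob else p.mismatch
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + s, H[i - 1][j] + p.gap, H[i][j - 1] + p.gap
            )
            best = max(best, H[i][j])
    return best


class TestAntisenseAlign:
    def test_perfect_duplex_example(self):
        hits = antisense_align("ACCGU", "ACGGU", DEFAULTS)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.score == 10.0
        assert (hit.srna_region.start, hit.srna_region.end) == (1, 5)
        assert (hit.mrna_region.start, hit.mrna_region.end) == (1, 5)

    def test_self_pairing_below_threshold(self):
        assert antisense_align("AAAAA", "AAAAA", DEFAULTS) == []

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGU"))
        for _ in range(200):
            ls = int(rng.integers(5, 31))
            lu = int(rng.integers(5, 31))
            srna = "".join(rng.choice(bases, size=ls))
            utr = "".join(rng.choice(bases, size=lu))
            expected = oracle_best_score(srna, utr)
            hits = antisense_align(srna, utr, DEFAULTS)
            got = hits[0].score if hits else 0.0
            if expected >= DEFAULTS.min_score:
                assert got == expected, (srna, utr)
            else:
                assert hits == []

    def test_hits_sorted_and_regions_in_bounds(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGU"))
        checked = 0
        for _ in range(60):
            srna = "".join(rng.choice(bases, size=40))
            utr = "".join(rng.choice(bases, size=120))
            hits = antisense_align(srna, utr, AlignParams(min_score=6, max_hits=5))
            scores = [h.score for h in hits]
            assert scores == sorted(scores, reverse=True)
            for h in hits:
                assert 1 <= h.srna_region.start <= h.srna_region.end <= 40
                assert 1 <= h.mrna_region.start <= h.mrna_region.end <= 120
                checked += 1
        assert checked > 0

    def test_rescoring_trace_reproduces_score(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGU"))
        checked = 0
        for _ in range(50):
            srna = "".join(rng.choice(bases, size=35))
            utr = "".join(rng.choice(bases, size=90))
            for h in antisense_align(srna, utr, AlignParams(min_score=6)):
                assert rescore_trace(h.paired_string, AlignParams(min_score=6)) == h.score
                checked += 1
        assert checked > 0

    def test_role_swap_symmetry_without_wobble(self):
        """Best score is invariant under swapping query and target (with
        the appropriate reverse complement) when wobble pairs cannot
        contribute asymmetrically."""
        p = AlignParams(wobble=-1.0, min_score=6)  # wobble scored as mismatch
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGU"))
        for _ in range(40):
            a = "".join(rng.choice(bases, size=25))
            b = "".join(rng.choice(bases, size=25))
            ha = antisense_align(a, b, p)
            hb = antisense_align(b, a, p)
            sa = ha[0].score if ha else 0.0
            sb = hb[0].score if hb else 0.0
            assert sa == sb

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            antisense_align("", "ACGU")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ParseError):
            antisense_align("ACZU", "ACGU")


class TestPredictNetwork:
    def test_single_complementary_pair(self):
        srna = "ACCGUACCGU"
        utr = reverse_complement(srna)
        net = predict_network([("s1", srna)], [("g1", utr)])
        assert len(net.nodes) == 2 and len(net.interactions) == 1
        assert net.interactions[0].method == "antisense_align"

    def test_no_hits_keeps_all_nodes(self):
        net = predict_network(
            [("s1", "ACGUACGUAC")], [("g1", "AAAAAAAAAA"), ("g2", "CCCCCCCCCC"), ("g3", "AAAACCCCAA")]
        )
        assert len(net.nodes) == 4 and len(net.interactions) == 0

    def test_planted_seeds_recovered_exactly(self):
        # stringent seed-detection scoring: only near-perfect
        # complementarity clears the threshold
        strict = AlignParams(match=2, wobble=1, mismatch=-4, gap=-6, min_score=32)
        (sid, sseq), utrs, with_seed = generate_antisense_case(seed=11, n_utrs=12, k_with_seed=5)
        net = predict_network([(sid, sseq)], utrs, strict)
        hit_genes = {it.mrna_id for it in net.interactions}
        assert hit_genes == with_seed

    def test_id_collision_rejected(self):
        with pytest.raises(ValidationError, match="collision"):
            predict_network([("x", "ACGU")], [("x", "ACGU")])


class TestIntarnaTable:
    def test_row_parsing(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id1;start1;end1;id2;start2;end2;E\nm1;10;30;s1;5;20;-7.3\n")
        (it,) = parse_intarna_table(p)
        assert it.srna_id == "s1" and it.mrna_id == "m1"
        assert (it.srna_region.start, it.srna_region.end) == (5, 20)
        assert (it.mrna_region.start, it.mrna_region.end) == (10, 30)
        assert it.score == -7.3 and it.method == "intarna"

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id1;start1;end1;id2;start2;end2\nm1;10;30;s1;5;20\n")
        with pytest.raises(ParseError, match="E"):
            parse_intarna_table(p)

    def test_inverted_region_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id1;start1;end1;id2;start2;end2;E\nm1;30;10;s1;5;20;-7.3\n")
        with pytest.raises(RegionError, match="row 0"):
            parse_intarna_table(p)

    def test_comma_dialect_and_network_assembly(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "id1,start1,end1,id2,start2,end2,E\n"
            "m1,10,30,s1,5,20,-7.3\nm2,1,25,s1,4,22,-4.1\n"
        )
        net = network_from_interactions(parse_intarna_table(p))
        assert sorted(net.srna_ids()) == ["s1"]
        assert sorted(net.mrna_ids()) == ["m1", "m2"]
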