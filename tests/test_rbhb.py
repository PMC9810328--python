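"""PSL parsing, reciprocal best hits, ECNC, filters, binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoclade import rbhb, simulate
from oncoclade.rbhb import (
    GeneFilterConfig,
    PslAlignment,
    PslError,
    apply_exclusion_filters,
    binarize_copy_number,
    ecnc,
    gene_copy_number,
    merge_loci,
    parse_psl,
    reciprocal_best_hits,
    score_alignment,
    write_psl,
)


def make_alignment(qname="q1", qsize=100, blocks=((0, 100),), tname="scaf1",
                   tstart=500, matches=None, mism=0, q_ins=0, t_ins=0, rep=0):
    sizes = tuple(e - s for s, e in blocks)
    total = sum(sizes)
    tstarts = []
    pos = tstart
    for b in sizes:
        tstarts.append(pos)
        pos += b + 10  # small target gaps between blocks
    return PslAlignment(
        matches=total - mism if matches is None else matches,
        misMatches=mism, repMatches=rep, nCount=0,
        qNumInsert=q_ins, qBaseInsert=0, tNumInsert=t_ins, tBaseInsert=0,
        strand="+", qName=qname, qSize=qsize,
        qStart=blocks[0][0], qEnd=blocks[-1][1],
        tName=tname, tSize=10_000_000, tStart=tstarts[0],
        tEnd=tstarts[-1] + sizes[-1],
        blockCount=len(blocks), blockSizes=sizes,
        qStarts=tuple(s for s, _ in blocks), tStarts=tuple(tstarts),
    )


def rbh_hit(blocks, tname="s", qname="q", gene="g", qsize=100):
    aligns = [make_alignment(qname=qname, qsize=qsize, blocks=(b,), tname=tname)
              for b in blocks]
    locus = merge_loci(aligns)[0]
    return rbhb.RbhHit(gene, qname, locus, locus.score, gene)


class TestPslIO:
    def test_single_block_perfect_hit(self, tmp_path):
        rec = make_alignment()
        path = tmp_path / "a.psl"
        write_psl([rec], path)
        [back] = parse_psl(path)
        assert back.qStart == 0 and back.qEnd == 100 and back.matches == 100

    def test_header_and_headerless_parse_identically(self, tmp_path):
        rec = make_alignment(blocks=((0, 40), (50, 100)))
        plain = tmp_path / "plain.psl"
        write_psl([rec], plain)
        headered = tmp_path / "head.psl"
        headered.write_text(
            "psLayout version 3\n\nmatch\tmis- \trep. \n     \t     \n"
            "---------------------------------\n" + plain.read_text()
        )
        assert parse_psl(plain) == parse_psl(headered)

    def test_round_trip_preserves_all_fields(self, tmp_path):
        rec = make_alignment(blocks=((5, 30), (40, 90)), mism=3, q_ins=1, t_ins=1)
        path = tmp_path / "b.psl"
        write_psl([rec], path)
        assert parse_psl(path) == [rec]

    def test_wrong_column_count_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.psl"
        path.write_text("1\t2\t3\n")
        with pytest.raises(PslError, match="line 1"):
            parse_psl(path)

    def test_inconsistent_block_arithmetic_rejected(self, tmp_path):
        rec = make_alignment()
        bad = rec.__class__(**{**rec.__dict__, "qEnd": 90})
        path = tmp_path / "c.psl"
        write_psl([bad], path)
        with pytest.raises(PslError, match="qEnd"):
            parse_psl(path)


class TestScore:
    def test_clean_hit(self):
        assert score_alignment(make_alignment()) == 100

    def test_penalty_arithmetic(self):
        a = make_alignment(matches=90, mism=5, q_ins=1, t_ins=1)
        assert score_alignment(a) == 83

    def test_monotone_in_mismatches(self):
        scores = [score_alignment(make_alignment(matches=100 - m, mism=m))
                  for m in range(0, 50, 5)]
        assert scores == sorted(scores, reverse=True)


class TestReciprocalBestHits:
    def _recip(self, locus_id, target, score=90):
        return PslAlignment(
            matches=score, misMatches=0, repMatches=0, nCount=0,
            qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
            strand="+", qName=locus_id, qSize=1000, qStart=0, qEnd=score,
            tName=target, tSize=100, tStart=0, tEnd=score,
            blockCount=1, blockSizes=(score,), qStarts=(0,), tStarts=(0,),
        )

    def test_reciprocal_match_retained(self):
        fwd = [make_alignment(qname="g1.1")]
        locus_id = "scaf1:500-600"
        hits, diag = reciprocal_best_hits(fwd, [self._recip(locus_id, "g1.1")],
                                          {"g1.1": "g1"})
        assert len(hits) == 1 and hits[0].query_gene == "g1"

    def test_non_reciprocal_dropped(self):
        fwd = [make_alignment(qname="g1.1")]
        hits, diag = reciprocal_best_hits(
            fwd, [self._recip("scaf1:500-600", "g2.1")],
            {"g1.1": "g1", "g2.1": "g2"},
        )
        assert hits == [] and diag["non_reciprocal"] == 1

    def test_two_reciprocal_loci_signal_duplication(self):
        fwd = [make_alignment(qname="g1.1", tname="scafA"),
               make_alignment(qname="g1.1", tname="scafB")]
        recip = [self._recip("scafA:500-600", "g1.1"),
                 self._recip("scafB:500-600", "g1.1")]
        hits, _ = reciprocal_best_hits(fwd, recip, {"g1.1": "g1"})
        assert len(hits) == 2

    def test_missing_reciprocal_counted(self):
        fwd = [make_alignment(qname="g1.1")]
        hits, diag = reciprocal_best_hits(fwd, [], {"g1.1": "g1"})
        assert hits == [] and diag["missing_reciprocal"] == 1

    def test_best_hit_chosen_by_score_then_ties(self):
        fwd = [make_alignment(qname="g1.1")]
        locus_id = "scaf1:500-600"
        recip = [self._recip(locus_id, "g2.1", score=80),
                 self._recip(locus_id, "g1.1", score=90)]
        hits, _ = reciprocal_best_hits(fwd, recip, {"g1.1": "g1", "g2.1": "g2"})
        assert len(hits) == 1


class TestEcnc:
    def test_single_full_coverage_hit(self):
        res = ecnc(100, [rbh_hit([(0, 100)])])
        assert res.ecnc == pytest.approx(1.0)
        assert res.covered_fraction == pytest.approx(1.0)

    def test_two_full_coverage_hits(self):
        res = ecnc(100, [rbh_hit([(0, 100)], "s1"), rbh_hit([(0, 100)], "s2")])
        assert res.ecnc == pytest.approx(2.0)

    def test_partial_overlap_worked_example(self):
        # positions 1-60 and 41-100 (1-based): 120 coverage over 100 positions
        res = ecnc(100, [rbh_hit([(0, 60)], "s1"), rbh_hit([(40, 100)], "s2")])
        assert res.ecnc == pytest.approx(1.2)

    def test_fragmentation_correction(self):
        # one full copy + one copy split across two scaffolds: ECNC = 2
        hits = [rbh_hit([(0, 100)], "s1"), rbh_hit([(0, 50)], "s2"),
                rbh_hit([(50, 100)], "s3")]
        res = ecnc(100, hits)
        assert res.ecnc == pytest.approx(2.0)
        assert res.n_hits == 3

    def test_no_coverage_flagged_undefined(self):
        res = ecnc(100, [])
        assert not res.defined and np.isnan(res.ecnc)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_position_counts(self, data):
        L = data.draw(st.integers(10, 200))
        n_hits = data.draw(st.integers(1, 6))
        hits, cover = [], np.zeros(L, dtype=int)
        for i in range(n_hits):
            n_blocks = data.draw(st.integers(1, 3))
            edges = sorted(
                data.draw(
                    st.lists(st.integers(0, L), min_size=2 * n_blocks,
                             max_size=2 * n_blocks, unique=True)
                )
            )
            blocks = [(edges[2 * j], edges[2 * j + 1]) for j in range(n_blocks)
                      if edges[2 * j + 1] > edges[2 * j]]
            if not blocks:
                blocks = [(0, L)]
            hits.append(rbh_hit(blocks, f"s{i}"))
            seen = set()
            for s, e in blocks:
                seen.update(range(s, e))
            for p in seen:
                cover[p] += 1
        res = ecnc(L, hits)
        covered = cover > 0
        expected = cover.sum() / covered.sum()
        assert res.ecnc == pytest.approx(expected)
        assert 1.0 <= res.ecnc <= len(hits) + 1e-12


class TestGeneAggregation:
    def test_max_rule(self):
        results = [
            ("g1.1", ecnc(100, [rbh_hit([(0, 100)])]), 1),
            ("g1.2", ecnc(100, [rbh_hit([(0, 100)], "sA"),
                                rbh_hit([(0, 90)], "sB")]), 2),
        ]
        df, _ = gene_copy_number(results, {"g1.1": "g1", "g1.2": "g1"})
        assert len(df) == 1
        assert df.iloc[0]["n_loci"] == 2
        assert df.iloc[0]["ecnc"] > 1.8

    def test_unscored_gene_in_diagnostics(self):
        results = [("g1.1", ecnc(100, []), 0)]
        df, diag = gene_copy_number(results, {"g1.1": "g1"})
        assert len(df) == 0
        assert diag["genes_without_scored_isoforms"] == ["g1"]

    def test_unmapped_isoform_errors(self):
        with pytest.raises(KeyError):
            gene_copy_number([("gX.1", ecnc(10, [rbh_hit([(0, 10)], qsize=10)]), 1)], {})


class TestFilters:
    def test_empty_patterns_identity(self):
        genes = ["TP53", "LOC12345"]
        kept, counts = apply_exclusion_filters(genes, GeneFilterConfig(patterns={}))
        assert kept == sorted(genes)

    def test_loc_gene_removed_and_counted(self):
        kept, counts = apply_exclusion_filters(["TP53", "LOC12345"])
        assert kept == ["TP53"]
        assert counts["loc"] == 1

    def test_order_independent(self):
        genes = ["TP53", "LOC1", "HLA-A", "ZNF91", "BRCA1"]
        a, ca = apply_exclusion_filters(genes)
        b, cb = apply_exclusion_filters(list(reversed(genes)))
        assert a == b and ca == cb


class TestBinarize:
    @pytest.mark.parametrize(
        "n_loci,ecnc_val,expected",
        [(1, 1.0, 0), (2, 2.0, 1), (2, 1.2, 0), (3, 1.6, 1)],
    )
    def test_threshold_rules(self, n_loci, ecnc_val, expected):
        import pandas as pd

        table = pd.DataFrame({"gene": ["g"], "ecnc": [ecnc_val], "n_loci": [n_loci]})
        out = binarize_copy_number(table)
        assert out.iloc[0]["state"] == expected

    def test_planted_copy_numbers_recovered(self):
        correct = total = 0
        for seed in range(3):
            bundle = simulate.simulate_psl(
                simulate.PslParams(n_genes=120, fragmentation_prob=0.25), seed=seed
            )
            hits, _ = reciprocal_best_hits(
                bundle["forward"], bundle["reciprocal"], bundle["isoform_to_gene"]
            )
            by_iso = {}
            for h in hits:
                by_iso.setdefault(h.query_isoform, []).append(h)
            results = [
                (iso, ecnc(bundle["query_sizes"][iso], hs, iso), len(hs))
                for iso, hs in by_iso.items()
            ]
            table, _ = gene_copy_number(results, bundle["isoform_to_gene"])
            called = binarize_copy_number(table).set_index("gene")
            for gene, info in bundle["truth"].items():
                total += 1
                if int(called.loc[gene, "state"]) == int(info["duplicated"]):
                    correct += 1
        assert correct / total >= 0.95
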