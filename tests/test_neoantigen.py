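"""Consensus filtering, score integration, ranking, construct assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from livmet import (
    RankConfig,
    VariantCallSet,
    assemble_construct,
    consensus_filter,
    construct_objective,
    integrate_scores,
    junction_kmers,
    mock_junction_scorer,
    rank_candidates,
    read_vcf,
    select_top,
    write_vcf,
)

SET_NAMES = ["WES_invivo", "WES_invitro", "RNA_invivo", "RNA_invitro"]


def variant(pos, effect="missense", gene="GeneA", germline=False):
    return {
        "chrom": "chr1",
        "pos": pos,
        "ref": "A",
        "alt": "T",
        "effect": effect,
        "gene": gene,
        "germline": germline,
    }


def make_sets(rows_per_set):
    return [
        VariantCallSet(name, pd.DataFrame(rows, columns=list(variant(1).keys())))
        for name, rows in zip(SET_NAMES, rows_per_set)
    ]


class TestConsensusFilter:
    @pytest.mark.parametrize(
        "n_sets,kept", [(4, True), (3, True), (2, False), (1, False)]
    )
    def test_minimal_occupancy_three_of_four(self, n_sets, kept):
        rows = [[variant(100)] if k < n_sets else [] for k in range(4)]
        out = consensus_filter(make_sets(rows))
        assert (len(out) == 1) is kept
        if kept:
            assert out.n_sets.iloc[0] == n_sets

    def test_non_missense_never_passes(self):
        rows = [[variant(100, effect="synonymous")] for _ in range(4)]
        assert consensus_filter(make_sets(rows)).empty

    def test_germline_flagged_dropped(self):
        # flagged in one set; present (unflagged) in three others
        rows = [[variant(100, germline=True)]] + [[variant(100)] for _ in range(3)]
        assert consensus_filter(make_sets(rows)).empty

    def test_monotone_in_occupancy(self):
        # adding an occurrence to another set never removes a variant
        rows = [[variant(100)], [variant(100)], [variant(100)], []]
        base = consensus_filter(make_sets(rows))
        rows_more = [[variant(100)] for _ in range(4)]
        more = consensus_filter(make_sets(rows_more))
        assert set(map(tuple, base[["chrom", "pos"]].values)) <= set(
            map(tuple, more[["chrom", "pos"]].values)
        )

    def test_exactly_four_sets_required(self):
        with pytest.raises(ValueError, match="4"):
            consensus_filter(make_sets([[variant(1)]] * 3))

    def test_duplicate_records_within_set_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            VariantCallSet("x", pd.DataFrame([variant(1), variant(1)]))


def predictor_rows(*rows):
    return pd.DataFrame(
        rows,
        columns=["peptide", "allele", "affinity_nM", "agretopicity", "foreignness", "gene"],
    )


@pytest.fixture
def consensus_variants():
    return pd.DataFrame([variant(100, gene="GeneA"), variant(200, gene="GeneB")]).assign(
        n_sets=4
    )


class TestIntegrateScores:
    def test_dedup_keeps_lower_affinity(self, consensus_variants):
        t1 = predictor_rows(("PEPTIDEA", "H2-Kb", 60.0, 2.0, 0.5, "GeneA"))
        t2 = predictor_rows(("PEPTIDEA", "H2-Kb", 40.0, 2.0, 0.5, "GeneA"))
        out = integrate_scores(consensus_variants, [t1, t2], {"GeneA": 10.0})
        assert len(out) == 1
        assert out.affinity_nM.iloc[0] == 40.0
        assert out.provenance.iloc[0] == "predictor_2"

    def test_absent_gene_gets_tpm_zero(self, consensus_variants):
        t1 = predictor_rows(("PEPTIDEA", "H2-Kb", 60.0, 2.0, 0.5, "GeneA"))
        out = integrate_scores(consensus_variants, [t1, predictor_rows()], {})
        assert out.tpm.iloc[0] == 0.0

    def test_off_consensus_genes_excluded(self, consensus_variants):
        t1 = predictor_rows(("XXXXXXXXX", "H2-Kb", 60.0, 2.0, 0.5, "GeneZ"))
        out = integrate_scores(consensus_variants, [t1, predictor_rows()], {})
        assert out.empty

    def test_malformed_row_reported(self, consensus_variants):
        bad = predictor_rows(("PEPTIDEA", "H2-Kb", -5.0, 2.0, 0.5, "GeneA"))
        with pytest.raises(ValueError, match="affinity_nM.*row 0"):
            integrate_scores(consensus_variants, [bad, predictor_rows()], {})

    def test_two_tables_required(self, consensus_variants):
        with pytest.raises(ValueError, match="2 predictor tables"):
            integrate_scores(consensus_variants, [predictor_rows()], {})


def candidates(*rows):
    return pd.DataFrame(
        rows,
        columns=["peptide", "allele", "affinity_nM", "agretopicity", "foreignness", "gene", "tpm"],
    )


class TestRanking:
    def test_ascending_affinity_first(self):
        c = candidates(
            ("AAAAAAAA", "kb", 300.0, 2.0, 0.5, "g", 10.0),
            ("CCCCCCCC", "kb", 30.0, 2.0, 0.5, "g", 10.0),
        )
        assert rank_candidates(c).peptide.tolist() == ["CCCCCCCC", "AAAAAAAA"]

    def test_tpm_breaks_affinity_ties(self):
        c = candidates(
            ("AAAAAAAA", "kb", 30.0, 2.0, 0.5, "g", 5.0),
            ("CCCCCCCC", "kb", 30.0, 2.0, 0.5, "g", 100.0),
        )
        assert rank_candidates(c).peptide.tolist() == ["CCCCCCCC", "AAAAAAAA"]

    def test_default_filters(self):
        c = candidates(
            ("AAAAAAAA", "kb", 600.0, 2.0, 0.5, "g", 10.0),  # affinity too weak
            ("CCCCCCCC", "kb", 30.0, 2.0, 0.5, "g", 0.0),  # not expressed
            ("DDDDDDDD", "kb", 30.0, 0.5, 0.5, "g", 10.0),  # agretopicity < 1
            ("EEEEEEEE", "kb", 30.0, 2.0, 0.5, "g", 10.0),  # passes
        )
        assert rank_candidates(c).peptide.tolist() == ["EEEEEEEE"]

    def test_equals_bruteforce_comparator(self):
        rng = np.random.default_rng(17)
        n = 100
        c = candidates(
            *[
                (
                    "".join(rng.choice(list("ACDEFGHIK"), 9)),
                    "kb",
                    float(rng.choice([30.0, 50.0, 500.0])),
                    float(rng.uniform(0.5, 3.0)),
                    float(rng.random()),
                    "g",
                    float(rng.choice([0.0, 5.0, 100.0])),
                )
                for _ in range(n)
            ]
        )
        cfg = RankConfig()
        got = rank_candidates(c, cfg)
        # independent reference: python sorted() with an explicit key tuple
        kept = [
            r
            for r in c.itertuples(index=False)
            if r.affinity_nM <= 500 and r.tpm > 0 and r.agretopicity >= 1 and r.foreignness >= 0
        ]
        ref = sorted(
            kept, key=lambda r: (r.affinity_nM, -r.tpm, -r.foreignness, r.peptide)
        )
        assert got.peptide.tolist() == [r.peptide for r in ref]
        # output is a permutation of the filtered input
        assert sorted(got.peptide) == sorted(r.peptide for r in ref)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            RankConfig(affinity_max=-1.0)

    def test_select_top(self):
        c = rank_candidates(
            candidates(
                *[
                    (f"PEP{i:02d}AAA", "kb", 30.0 + i, 2.0, 0.5, "g", 10.0)
                    for i in range(40)
                ]
            )
        )
        assert len(select_top(c, 33)) == 33
        assert select_top(c, 33)[0] == "PEP00AAA"
        assert len(select_top(c.head(10), 33)) == 10
        with pytest.raises(ValueError):
            select_top(c, 0)


PEPTIDES = ["SIINFEKLM", "KAVYNFATC", "GLEQLESIM", "AYQRLFNAL", "RGPGRAFVT"]


class TestAssembly:
    def test_single_peptide(self):
        c = assemble_construct(["SIINFEKLM"])
        assert c.sequence == "SIINFEKLM"
        assert c.junctions == []
        assert c.objective == math.inf

    def test_sequence_reconstruction_exact(self):
        c = assemble_construct(PEPTIDES, linker="GGSGG")
        assert c.sequence == "GGSGG".join(c.peptides)
        assert sorted(c.peptides) == sorted(PEPTIDES)
        assert len(c.junctions) == len(PEPTIDES) - 1

    def test_leader_sequence_prepended(self):
        c = assemble_construct(["AAAWWWKKK"], leader_sequence="MHRRRNS")
        assert c.sequence == "MHRRRNS" + "GGSGG" + "AAAWWWKKK"

    def test_junction_report_covers_adjacent_pairs(self):
        c = assemble_construct(PEPTIDES[:3])
        for i, j in enumerate(c.junctions):
            assert (j["left"], j["right"]) == (c.peptides[i], c.peptides[i + 1])
            assert j["kmers"]
            assert j["min_affinity_nM"] == min(a for _, a in j["kmers"])

    def test_junction_kmers_span_junction(self):
        kmers = junction_kmers("AAAAAAAAA", "CCCCCCCCC", "GGSGG")
        # every window must include linker or cross between the peptides
        assert all(set(k) - set("A") and set(k) - set("C") for k in kmers)
        assert {len(k) for k in kmers} == {8, 9, 10, 11}

    def test_greedy_equals_exhaustive_for_three(self):
        best = max(
            itertools.permutations(PEPTIDES[:3]),
            key=lambda o: construct_objective(o, "GGSGG", mock_junction_scorer),
        )
        got = assemble_construct(PEPTIDES[:3])
        assert got.objective == construct_objective(best, "GGSGG", mock_junction_scorer)

    def test_greedy_not_worse_than_median_random(self):
        rng = np.random.default_rng(23)
        got = assemble_construct(PEPTIDES).objective
        objectives = []
        for _ in range(100):
            order = list(PEPTIDES)
            rng.shuffle(order)
            objectives.append(construct_objective(order, "GGSGG", mock_junction_scorer))
        assert got >= np.median(objectives)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_construct([])


class TestVcfRoundTrip:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            [variant(100), variant(250, effect="synonymous", germline=True)]
        )
        p = tmp_path / "v.vcf"
        write_vcf(df, p)
        back = read_vcf(p)
        assert back.pos.tolist() == [100, 250]
        assert back.effect.tolist() == ["missense", "synonymous"]
        assert back.germline.tolist() == [False, True]
        assert back.gene.tolist() == ["GeneA", "GeneA"]
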