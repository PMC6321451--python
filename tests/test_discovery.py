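"""discovery: Fisher enrichment, input resolution, DREME-style search, PFMs."""

import math

import pytest

from oracles import hypergeom_tail_exact
from premotif.datasets import ddx1_interacting_precursors
from premotif.discovery import (
    ContingencyTable,
    count_sequences_with_motif,
    discover_motifs,
    fisher_enrichment_p,
    matched_sites,
    motif_to_pfm,
    n_candidate_patterns,
    resolve_inputs,
    write_meme_minimal,
)
from premotif.fixtures import FixtureSpec, build_fixture, make_discovery_benchmark
from premotif.mirbase_io import Precursor, PrecursorDatabase


class TestFisherEnrichment:
    def test_small_table_by_hand(self):
        # C(2,2)*C(4,1)/C(6,3) = 4/20
        assert fisher_enrichment_p(ContingencyTable(2, 3, 0, 3)) == pytest.approx(0.2)

    def test_motif_everywhere_gives_one(self):
        assert fisher_enrichment_p(ContingencyTable(5, 5, 7, 7)) == 1.0

    def test_empty_upper_tail_is_whole_distribution(self):
        assert fisher_enrichment_p(ContingencyTable(0, 10, 3, 10)) == 1.0

    def test_agrees_with_exact_enumeration_on_spot_checks(self):
        for table in [(3, 8, 1, 12), (5, 5, 0, 20), (7, 15, 30, 100), (1, 2, 2, 2)]:
            t = ContingencyTable(*table)
            exact = float(hypergeom_tail_exact(*table))
            assert fisher_enrichment_p(t) == pytest.approx(exact, rel=1e-12)

    def test_monotone_in_p_with(self):
        prev = 1.1
        for p_with in range(0, 11):
            p = fisher_enrichment_p(ContingencyTable(p_with, 10, 5, 20))
            assert p <= prev + 1e-15
            prev = p

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(4, 3, 0, 3)


class TestSequenceCounting:
    def test_multiple_occurrences_count_once(self):
        assert count_sequences_with_motif(["UGUGU"], "UGU") == 1

    def test_empty_list(self):
        assert count_sequences_with_motif([], "UGU") == 0

    def test_planted_fraction_counted(self):
        data = build_fixture(
            FixtureSpec(n_precursors=10, planted_motif="GGAG", planted_fraction=0.7, seed=2)
        )
        seqs = [p.sequence for p in data.db]
        assert count_sequences_with_motif(seqs, "GGAG") >= 7
        loops = [p.sequence[20:28] for p in data.db]
        assert count_sequences_with_motif(loops, "GGAG") == 7

    def test_both_directions_counts_reversed_occurrence(self):
        assert count_sequences_with_motif(["CCGAGG"], "GAGC", "both") == 1
        assert count_sequences_with_motif(["CCGAGG"], "GAGC", "forward") == 0


class TestDiscoverMotifs:
    def test_top_motif_covers_planted_sites_with_consistent_statistics(self):
        bench = make_discovery_benchmark(
            pattern="GGAG", n_positives=8, n_planted=6, n_negatives=30, seed=13
        )
        (motif, *rest) = discover_motifs(
            bench.positives, bench.negatives, e_threshold=10.0, max_motifs=1
        )
        # every planted positive carries the reported motif
        planted = [bench.positives[i] for i in bench.planted_indices]
        assert count_sequences_with_motif(planted, motif.pattern) == len(planted)
        # the reported table is the true sequence-level table of the pattern
        assert motif.table == ContingencyTable(
            count_sequences_with_motif(bench.positives, motif.pattern),
            len(bench.positives),
            count_sequences_with_motif(bench.negatives, motif.pattern),
            len(bench.negatives),
        )
        # and p/E are the oracle-recomputed values for that table
        t = motif.table
        assert motif.p_value == pytest.approx(
            float(hypergeom_tail_exact(t.p_with, t.p_total, t.n_with, t.n_total)),
            rel=1e-12,
        )
        assert motif.e_value == pytest.approx(
            motif.p_value * n_candidate_patterns(len(motif.pattern))
        )

    def test_planted_motif_recovered_exactly_at_benchmark_scale(self):
        bench = make_discovery_benchmark(seed=4)  # 12/15 positives vs 100 negatives
        motifs = discover_motifs(bench.positives, bench.negatives, max_motifs=1)
        assert motifs and motifs[0].pattern == "GGAG"
        assert motifs[0].table == ContingencyTable(12, 15, 0, 100)
        assert motifs[0].p_value == pytest.approx(
            float(hypergeom_tail_exact(12, 15, 0, 100)), rel=1e-12
        )

    def test_deterministic(self):
        bench = make_discovery_benchmark(n_positives=8, n_planted=6, n_negatives=30, seed=13)
        a = discover_motifs(bench.positives, bench.negatives, e_threshold=10.0)
        b = discover_motifs(bench.positives, bench.negatives, e_threshold=10.0)
        assert a == b

    def test_erasure_removes_matching_sequences_before_next_round(self):
        bench = make_discovery_benchmark(n_positives=8, n_planted=6, n_negatives=30, seed=13)
        motifs = discover_motifs(bench.positives, bench.negatives, e_threshold=10.0, max_motifs=3)
        # after erasing GGAG carriers, later motifs are scored on <= 2 positives
        for m in motifs[1:]:
            assert m.table.p_total <= 2

    def test_max_motifs_bounds_output(self):
        bench = make_discovery_benchmark(n_positives=8, n_planted=6, n_negatives=30, seed=13)
        assert len(discover_motifs(bench.positives, bench.negatives,
                                   e_threshold=10.0, max_motifs=1)) == 1

    def test_empty_positive_set_is_an_error(self):
        with pytest.raises(ValueError):
            discover_motifs([], ["ACGU"])

    def test_no_seed_shared_by_two_positives_yields_no_motif(self):
        assert discover_motifs(["ACGUACGUAC"], ["UUUUUUUUUU"] * 3) == []


class TestResolveInputs:
    def db(self):
        db = PrecursorDatabase()
        for name in ("hsa-mir-96", "hsa-mir-200a", "hsa-mir-21"):
            db.add_precursor(Precursor(name, "", "GGGAGGAGAAACUCCUCCC"))
        return db

    def test_name_and_sequence_lines(self):
        res = resolve_inputs(["hsa-mir-21", "ACGUacgu", "", "# comment"], self.db())
        assert res.resolved_names == ["hsa-mir-21"]
        assert res.raw_sequences == 1
        assert res.sequences[1] == "ACGUACGU"

    def test_mature_style_capitalization_resolves_to_precursor(self):
        res = resolve_inputs(["hsa-miR-96"], self.db())
        assert res.resolved_names == ["hsa-mir-96"]

    def test_unresolvable_names_reported_without_aborting(self):
        res = resolve_inputs(["hsa-miR-96", "hsa-miR-9999"], self.db())
        assert res.unresolved == ["hsa-miR-9999"]
        assert len(res.sequences) == 1

    def test_zero_resolvable_inputs_is_an_error(self):
        with pytest.raises(ValueError, match="no resolvable"):
            resolve_inputs(["hsa-miR-9999"], self.db())

    def test_ddx1_interaction_list_has_25_entries(self):
        names = ddx1_interacting_precursors()
        assert len(names) == 25
        res = resolve_inputs(names, self.db())
        # legacy names that no longer resolve are reported, run continues
        assert "hsa-miR-82" in res.unresolved
        assert set(res.resolved_names) == {"hsa-mir-96", "hsa-mir-200a"}


class TestPfm:
    def test_counts_and_column_sums(self):
        pfm = motif_to_pfm("GGAG", ["GGAG", "GGAG"])
        assert pfm["G"] == [2, 2, 0, 2]
        for i in range(4):
            assert sum(pfm[b][i] for b in "ACGU") == 2

    def test_zero_sites_is_an_error(self):
        with pytest.raises(ValueError):
            motif_to_pfm("GGAG", [])

    def test_pfm_argmax_spells_an_instance_of_the_pattern(self):
        bench = make_discovery_benchmark(pattern="GRAG", n_positives=8, n_planted=6,
                                         n_negatives=30, seed=17)
        sites = matched_sites(bench.positives, "GRAG")
        pfm = motif_to_pfm("GRAG", sites)
        from premotif.motif_search import compile_motif

        consensus = "".join(
            max("ACGU", key=lambda b: pfm[b][i]) for i in range(4)
        )
        charsets = compile_motif("GRAG").charsets
        assert all(b in cs for b, cs in zip(consensus, charsets))

    def test_meme_minimal_output_shape(self, tmp_path):
        pfm = motif_to_pfm("GGAG", ["GGAG", "GGAG", "GGAG"])
        path = tmp_path / "m.meme"
        write_meme_minimal([("GGAG", pfm)], path)
        text = path.read_text()
        assert "MEME version 4" in text and "MOTIF GGAG" in text
        rows = [l for l in text.splitlines() if l and l[0].isdigit() or l.startswith("0")]
        probs = [list(map(float, r.split())) for r in rows]
        assert len(probs) == 4
        for row in probs:
            assert math.isclose(sum(row), 1.0, abs_tol=1e-6)
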