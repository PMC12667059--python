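"""Codon translation filters and the fixed-private-shared predicate."""

import pytest

from guenonflow.convergence import (
    CodonAlignment,
    convergent_sites,
    scan_genes,
    translate_and_filter,
    translate_codons,
)
from guenonflow.simulate import simulate_codon_alignments

GROUPS = {
    "focalA": ["a1", "a2"],
    "focalB": ["b1"],
    "background": ["c1", "c2", "c3"],
}


def aa_cols(*columns):
    """Build per-sample AA strings from per-column residue dicts."""
    samples = set().union(*columns)
    return {s: "".join(col[s] for col in columns) for s in samples}


class TestTranslation:
    def test_codon_translation(self):
        assert translate_codons("ATGAAATAA") == "MK*"
        assert translate_codons("---NNNATN") == "-XX"

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError):
            translate_codons("ATGA")


class TestTranslateAndFilter:
    def _aln(self, seqs):
        return CodonAlignment("g", seqs)

    def test_internal_stop_excluded_terminal_allowed(self):
        seqs = {s: "ATGAAAGGG" for s in GROUPS["background"]}
        seqs |= {"a1": "ATGTAAGGG", "a2": "ATGAAAGGG",  # TAA internal
                 "b1": "ATGAAATAA"}                      # TAA terminal
        rep = translate_and_filter(self._aln(seqs), GROUPS)
        assert rep.excluded == {"a1": "internal_stop"}
        assert "b1" in rep.retained and not rep.gene_dropped

    def test_majority_missing_excluded(self):
        n = 100
        good = "ATG" * n
        bad51 = "NNN" * 51 + "ATG" * 49
        bad50 = "NNN" * 50 + "ATG" * 50  # exactly 50%: retained
        seqs = {s: good for s in ("a1", "a2", "b1", "c1", "c2")}
        seqs |= {"c3": bad51}
        rep = translate_and_filter(CodonAlignment("g", seqs), GROUPS)
        assert rep.excluded == {"c3": "missing_gt_50pct"}
        seqs["c3"] = bad50
        rep = translate_and_filter(CodonAlignment("g", seqs), GROUPS)
        assert rep.excluded == {}

    def test_gene_dropped_when_majority_of_group_filtered(self):
        groups = {"focalA": ["a1", "a2", "a3", "a4"], "focalB": ["b1"],
                  "background": ["c1"]}
        seqs = {s: ("TAAAAA" if s in ("a1", "a2", "a3") else "ATGAAA")
                for s in ("a1", "a2", "a3", "a4", "b1", "c1")}
        rep = translate_and_filter(CodonAlignment("g", seqs), groups)
        assert rep.gene_dropped and "focalA" in rep.drop_reason

    def test_gene_kept_at_exactly_half_filtered(self):
        groups = {"focalA": ["a1", "a2", "a3", "a4"], "focalB": ["b1"],
                  "background": ["c1"]}
        seqs = {s: ("TAAAAA" if s in ("a1", "a2") else "ATGAAA")
                for s in ("a1", "a2", "a3", "a4", "b1", "c1")}
        rep = translate_and_filter(CodonAlignment("g", seqs), groups)
        assert not rep.gene_dropped


class TestConvergentSites:
    def test_fixed_private_shared_called(self):
        aa = aa_cols({"a1": "M", "a2": "M", "b1": "M",
                      "c1": "A", "c2": "A", "c3": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1", "c2", "c3"])
        assert res.convergent_columns == [(0, "M", ("A",))]

    def test_shared_state_in_background_not_private(self):
        aa = aa_cols({"a1": "M", "a2": "M", "b1": "M",
                      "c1": "A", "c2": "M", "c3": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1", "c2", "c3"])
        assert res.n_convergent == 0

    def test_polymorphic_background_without_x_still_private(self):
        aa = aa_cols({"a1": "M", "a2": "M", "b1": "M",
                      "c1": "A", "c2": "G", "c3": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1", "c2", "c3"])
        assert res.convergent_columns == [(0, "M", ("A", "G"))]

    def test_missing_focal_residue_tolerated(self):
        aa = aa_cols({"a1": "M", "a2": "-", "b1": "M", "c1": "A", "c2": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1", "c2"])
        assert res.n_convergent == 1

    def test_group_entirely_missing_column_skipped(self):
        aa = aa_cols({"a1": "-", "a2": "X", "b1": "M", "c1": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1"])
        assert res.n_convergent == 0 and res.n_columns_skipped == 1

    def test_discordant_focal_groups_not_called(self):
        aa = aa_cols({"a1": "M", "a2": "M", "b1": "L", "c1": "A"})
        res = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1"])
        assert res.n_convergent == 0

    def test_adding_background_sample_anti_monotone(self):
        aa = aa_cols(
            {"a1": "M", "b1": "M", "c1": "A", "c2": "M"},
            {"a1": "L", "b1": "L", "c1": "A", "c2": "A"},
        )
        small = convergent_sites(aa, ["a1"], ["b1"], ["c1"])
        big = convergent_sites(aa, ["a1"], ["b1"], ["c1", "c2"])
        small_cols = {c for c, _, _ in small.convergent_columns}
        big_cols = {c for c, _, _ in big.convergent_columns}
        assert big_cols <= small_cols and len(small_cols) == 2

    def test_invariant_under_sample_reordering(self):
        aa = aa_cols({"a1": "M", "a2": "M", "b1": "M", "c1": "A", "c2": "G"})
        r1 = convergent_sites(aa, ["a1", "a2"], ["b1"], ["c1", "c2"])
        r2 = convergent_sites(aa, ["a2", "a1"], ["b1"], ["c2", "c1"])
        assert r1.convergent_columns == r2.convergent_columns

    def test_empty_group_raises(self):
        aa = aa_cols({"a1": "M"})
        with pytest.raises(ValueError):
            convergent_sites(aa, ["a1"], [], ["a1"])


class TestPlantedRecovery:
    def test_planted_columns_recovered_exactly(self):
        planted = [("gene0001", 3, "M"), ("gene0001", 7, "W"),
                   ("gene0003", 0, "C")]
        alns, truth = simulate_codon_alignments(
            seed=1, n_genes=3, n_codons=10, groups=GROUPS, planted=planted,
        )
        results = scan_genes(alns, GROUPS)
        found = {(g, c) for g, r in results.items()
                 for (c, _, _) in r.convergent_columns}
        assert found == set(truth.convergent_columns)

    def test_no_planted_no_calls(self):
        alns, _ = simulate_codon_alignments(seed=2, n_genes=4, n_codons=20,
                                            groups=GROUPS)
        results = scan_genes(alns, GROUPS)
        assert sum(r.n_convergent for r in results.values()) == 0

    def test_single_group_noise_not_called(self):
        alns, _ = simulate_codon_alignments(
            seed=3, n_genes=1, n_codons=10, groups=GROUPS,
            noise_substitutions=[("gene0001", 4, "focalA", "M")],
        )
        results = scan_genes(alns, GROUPS)
        assert results["gene0001"].n_convergent == 0

    def test_gappy_sequence_excluded_by_filter(self):
        alns, _ = simulate_codon_alignments(
            seed=4, n_genes=1, n_codons=20, groups=GROUPS,
            missing_sequences=[("gene0001", "c1", 0.6)],
        )
        rep = translate_and_filter(CodonAlignment("gene0001", alns["gene0001"]),
                                   GROUPS)
        assert rep.excluded.get("c1") == "missing_gt_50pct"

    def test_planted_stop_drops_sequence_and_can_drop_gene(self):
        alns, _ = simulate_codon_alignments(
            seed=5, n_genes=1, n_codons=10, groups=GROUPS,
            internal_stops=[("gene0001", "b1")],
        )
        results = scan_genes(alns, GROUPS)
        assert "gene0001" not in results  # sole focalB sample lost -> gene dropped
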