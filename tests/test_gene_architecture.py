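"""Exon/isoform statistics, polyA assignment and spacing, exact tests."""

import math

import numpy as np
import pandas as pd
import pytest

from lnckaryotype import gene_architecture as ga
from lnckaryotype.model import PolyAFeature


def genes_frame(rows):
    cols = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype", "length"]
    return pd.DataFrame(rows, columns=cols)


def tx_frame(rows):
    cols = ["transcript_id", "gene_id", "chrom", "start", "end", "strand", "exon_count", "mature_length"]
    return pd.DataFrame(rows, columns=cols)


class TestArchitectureSummary:
    def _fixture(self):
        genes = genes_frame([("G1", "A", "chr1", 1, 1000, "+", "lncRNA", 1000)])
        tx = tx_frame(
            [
                ("T1", "G1", "chr1", 1, 900, "+", 3, 300),
                ("T2", "G1", "chr1", 1, 500, "+", 1, 500),
            ]
        )
        return genes, tx

    def test_hand_counted_fixture(self):
        genes, tx = self._fixture()
        out = ga.architecture_summary(genes, tx).iloc[0]
        assert out["mean_transcripts_per_gene"] == 2
        assert out["mean_exons_per_gene"] == 4  # 3 + 1, not deduplicated
        assert out["n_monoexonic_genes"] == 0  # one isoform is multi-exon

    def test_monoexonic_modes(self):
        genes, tx = self._fixture()
        strict = ga.architecture_summary(genes, tx, monoexonic_mode="all_isoforms").iloc[0]
        loose = ga.architecture_summary(genes, tx, monoexonic_mode="any_isoform").iloc[0]
        assert strict["n_monoexonic_genes"] == 0 and loose["n_monoexonic_genes"] == 1

    def test_single_single_exon_isoform_is_monoexonic(self):
        genes = genes_frame([("G1", "A", "chr1", 1, 100, "+", "lncRNA", 100)])
        tx = tx_frame([("T1", "G1", "chr1", 1, 100, "+", 1, 100)])
        assert ga.architecture_summary(genes, tx).iloc[0]["n_monoexonic_genes"] == 1

    def test_transcript_count_identity(self, sim_bundle):
        """mean transcripts per gene x gene count = transcript count."""
        from lnckaryotype.model import genes_to_frame, transcripts_to_frame

        out = ga.architecture_summary(
            genes_to_frame(sim_bundle.genes), transcripts_to_frame(sim_bundle.transcripts)
        )
        for _, row in out.iterrows():
            assert row["mean_transcripts_per_gene"] * row["n_genes"] == pytest.approx(
                row["n_transcripts"]
            )

    def test_adding_multiexon_isoform_never_increases_monoexonic_count(self):
        genes = genes_frame(
            [
                ("G1", "A", "chr1", 1, 1000, "+", "lncRNA", 1000),
                ("G2", "B", "chr1", 1, 1000, "+", "lncRNA", 1000),
            ]
        )
        tx = tx_frame(
            [
                ("T1", "G1", "chr1", 1, 900, "+", 1, 300),
                ("T2", "G2", "chr1", 1, 500, "+", 1, 500),
            ]
        )
        before = ga.architecture_summary(genes, tx).iloc[0]["n_monoexonic_genes"]
        for gid in ("G1", "G2"):
            extra = pd.concat(
                [tx, tx_frame([("TX", gid, "chr1", 1, 800, "+", 4, 400)])], ignore_index=True
            )
            after = ga.architecture_summary(genes, extra).iloc[0]["n_monoexonic_genes"]
            assert after <= before


class TestExtremes:
    def test_longest_and_tie_rule(self):
        genes = genes_frame(
            [
                ("G2", "B", "chr1", 1, 200, "+", "lncRNA", 200),
                ("G1", "A", "chr1", 1, 100, "+", "lncRNA", 100),
            ]
        )
        tx = tx_frame([("T1", "G1", "chr1", 1, 100, "+", 1, 100)])
        assert ga.extremes(genes, tx)["longest_gene"]["gene_id"] == "G2"
        tie = genes_frame(
            [
                ("G2", "B", "chr1", 1, 200, "+", "lncRNA", 200),
                ("G1", "A", "chr1", 1, 200, "+", "lncRNA", 200),
            ]
        )
        assert ga.extremes(tie, tx)["longest_gene"]["gene_id"] == "G1"


class TestAssignPolya:
    def _genes(self):
        return genes_frame(
            [
                ("G1", "A", "chr1", 100, 500, "+", "lncRNA", 401),
                ("G2", "B", "chr1", 150, 450, "-", "lncRNA", 301),
                ("G3", "C", "chr1", 120, 480, "+", "lncRNA", 361),
            ]
        )

    def test_same_strand_overlap_assigned_opposite_not(self):
        feats = [PolyAFeature("polyA_site", "chr1", 200, 201, "+")]
        out = ga.assign_polya(self._genes(), feats)
        assert sorted(out["gene_id"]) == ["G1", "G3"]  # G2 is opposite strand

    def test_feature_outside_span_not_assigned(self):
        feats = [PolyAFeature("polyA_site", "chr1", 600, 601, "+")]
        assert len(ga.assign_polya(self._genes(), feats)) == 0

    def test_linked_mode_uses_annotated_ids(self):
        feats = [
            PolyAFeature("polyA_site", "chr1", 200, 201, "+", linked_id="G1"),
            PolyAFeature("polyA_site", "chr1", 200, 201, "+", linked_id=None),
            PolyAFeature("polyA_site", "chr1", 200, 201, "-", linked_id="G1"),  # strand mismatch
        ]
        out = ga.assign_polya(self._genes(), feats, mode="linked")
        assert out["gene_id"].tolist() == ["G1"]

    def test_nested_genes_both_hit(self):
        genes = genes_frame(
            [
                ("G1", "A", "chr1", 100, 1000, "+", "lncRNA", 901),
                ("G2", "B", "chr1", 300, 400, "+", "lncRNA", 101),
            ]
        )
        feats = [PolyAFeature("polyA_signal", "chr1", 350, 355, "+")]
        assert sorted(ga.assign_polya(genes, feats)["gene_id"]) == ["G1", "G2"]


class TestPairing:
    def _assign(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "biotype", "strand", "kind", "feature_start", "feature_end"],
        )

    def test_plus_strand_spacing(self):
        a = self._assign(
            [
                ("G1", "lncRNA", "+", "polyA_signal", 100, 105),
                ("G1", "lncRNA", "+", "polyA_site", 126, 127),
            ]
        )
        pairs = ga.pair_site_signal(a)
        assert len(pairs) == 1 and pairs["spacing"].iloc[0] == 20

    def test_minus_strand_mirror(self):
        a = self._assign(
            [
                ("G1", "lncRNA", "-", "polyA_site", 73, 74),
                ("G1", "lncRNA", "-", "polyA_signal", 95, 100),
            ]
        )
        pairs = ga.pair_site_signal(a)
        assert len(pairs) == 1 and pairs["spacing"].iloc[0] == 20

    def test_signal_downstream_of_site_not_paired(self):
        a = self._assign(
            [
                ("G1", "lncRNA", "+", "polyA_site", 100, 101),
                ("G1", "lncRNA", "+", "polyA_signal", 150, 155),
            ]
        )
        assert len(ga.pair_site_signal(a)) == 0

    def test_nearest_upstream_signal_wins(self):
        a = self._assign(
            [
                ("G1", "lncRNA", "+", "polyA_signal", 100, 105),
                ("G1", "lncRNA", "+", "polyA_signal", 110, 115),
                ("G1", "lncRNA", "+", "polyA_site", 130, 131),
            ]
        )
        pairs = ga.pair_site_signal(a)
        assert pairs["signal_start"].iloc[0] == 110

    def test_spacing_recovery_on_synthetic_bundle(self, sim_bundle):
        from lnckaryotype.model import genes_to_frame

        assignments = ga.assign_polya(genes_to_frame(sim_bundle.genes), sim_bundle.polya_features)
        pairs = ga.pair_site_signal(assignments)
        truth = sim_bundle.truth_genes["polya_spacing"].dropna()
        assert len(pairs) >= len(truth)  # nested genes may add assignments
        recovered = pairs.drop_duplicates("gene_id").set_index("gene_id")["spacing"]
        common = truth.index.intersection(
            sim_bundle.truth_genes.set_index("gene_id").index
        )
        truth_by_gene = sim_bundle.truth_genes.set_index("gene_id")["polya_spacing"].dropna()
        joined = recovered.to_frame().join(truth_by_gene, how="inner")
        assert abs(joined["spacing"].mean() - joined["polya_spacing"].mean()) <= 1.0


class TestMotifsAndFisher:
    def test_motif_positions(self):
        out = ga.scan_motifs("GGAATAAAGG")
        assert out["polyA_signal"] == [3]
        assert ga.scan_motifs("CACA")["polyA_site"] == [1, 3]
        assert ga.scan_motifs("AAAAAA") == {"polyA_signal": [], "polyA_site": []}

    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ([[2, 0], [0, 2]], 1 / 3),
            ([[5, 5], [5, 5]], 1.0),
            ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
        ],
    )
    def test_fisher_enumerated_values(self, table, expected_p):
        _, p = ga.fisher_exact_2x2(table)
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_fisher_rejects_bad_table(self):
        with pytest.raises(ValueError):
            ga.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
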