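"""Variant-gene intersection, substitution classes, clinical priority,
distribution tables and the goodness-of-fit test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnckaryotype import variant_analysis as va
from lnckaryotype.model import CLINICAL_FLAGS, VariantRecord


def genes_frame(rows):
    cols = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype", "length", "subtype"]
    return pd.DataFrame(rows, columns=cols)


def variant(chrom, pos, vid, ref="A", alts=("G",), flags=frozenset()):
    return VariantRecord(chrom, pos, vid, ref, tuple(alts), frozenset(flags))


class TestIntersect:
    def _genes(self):
        return genes_frame(
            [
                ("G1", "LINC1", "chr1", 101, 200, "+", "lncRNA", 100, "intergenic"),
                ("G2", "A-AS1", "chr1", 150, 250, "-", "lncRNA", 101, "antisense"),
            ]
        )

    def test_inclusive_bounds(self):
        hits = va.intersect([variant("chr1", 150, "rs1")], self._genes())
        assert sorted(hits["gene_id"]) == ["G1", "G2"]
        none = va.intersect([variant("chr1", 100, "rs2")], self._genes())
        assert len(none) == 0
        edge = va.intersect([variant("chr1", 101, "rs3")], self._genes())
        assert edge["gene_id"].tolist() == ["G1"]

    def test_overlapping_genes_two_hits_one_dedup(self):
        hits = va.intersect([variant("chr1", 180, "rs1")], self._genes())
        assert len(hits) == 2
        assert hits["variant_id"].nunique() == 1


class TestSubstitution:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("C", "T", "transition"),
            ("C", "A", "transversion"),
            ("T", "G", "transversion"),
            ("A", "AT", "other"),
            ("AT", "A", "other"),
            ("A", "A", "other"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert va.classify_substitution(ref, alt) == expected

    def test_partition_over_snvs(self):
        """Over single-base biallelic substitutions the transition and
        transversion shares sum to exactly one."""
        rng = np.random.default_rng(5)
        bases = "ACGT"
        rows = []
        for i in range(500):
            r = bases[rng.integers(4)]
            a = bases[rng.integers(4)]
            if a == r:
                a = bases[(bases.index(r) + 1) % 4]
            rows.append({"variant_id": f"v{i}", "chrom": "chr1", "ref": r, "alts": a})
        classes = va.substitution_classes(pd.DataFrame(rows))
        shares = va.titv_shares(classes)
        assert shares["transition_share"] + shares["transversion_share"] == pytest.approx(1.0)

    def test_multiallelic_one_class_per_alt(self):
        df = pd.DataFrame([{"variant_id": "v", "chrom": "chr1", "ref": "A", "alts": "G,C"}])
        classes = va.substitution_classes(df)
        assert classes["substitution"].tolist() == ["transition", "transversion"]


class TestClinicalPriority:
    def test_priority_chain(self):
        assert va.resolve_clinical({"Pathogenic", "VUS"}) == "pathogenic"
        assert va.resolve_clinical({"Likely_benign"}) == "likely_benign"
        assert va.resolve_clinical(set()) == "unclassified"

    def test_adding_lower_priority_flag_never_changes_result(self):
        for i, top in enumerate(CLINICAL_FLAGS):
            base = va.resolve_clinical({top})
            for lower in CLINICAL_FLAGS[i + 1 :]:
                assert va.resolve_clinical({top, lower}) == base

    def test_synthetic_class_probabilities_recovered(self, sim_bundle):
        """Observed clinical-class shares sit inside 99% binomial intervals
        of the shares implied by the independent-flag generator."""
        truth = sim_bundle.truth_variants
        n = len(truth)
        probs = sim_bundle.config.clinical_flag_probs
        # P(resolved class = c) = P(flag c) * prod_{higher} (1 - P(higher))
        expected = {}
        acc = 1.0
        for flag, cls in zip(CLINICAL_FLAGS, va.CLINICAL_CLASSES):
            expected[cls] = probs[flag] * acc
            acc *= 1 - probs[flag]
        observed = truth["clinical_class"].value_counts()
        for cls, p in expected.items():
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= observed.get(cls, 0) <= hi


class TestDistributionTables:
    def test_single_subtype_row(self):
        hits = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(10)],
                "chrom": ["chr2"] * 10,
                "subtype": ["antisense"] * 10,
                "clinical_class": ["VUS"] * 10,
            }
        )
        tabs = va.distribution_tables(hits)
        row = tabs["subtype_by_chromosome"].set_index("chrom").loc["chr2"]
        assert row["antisense"] == 10

    def test_pathogenic_fraction_fixture(self):
        """26 of 27 pathogenic variants on one chromosome dominate its
        pathogenicity fraction."""
        rows = []
        for i in range(26):
            rows.append({"variant_id": f"y{i}", "chrom": "chrY", "subtype": "name_assigned", "clinical_class": "pathogenic"})
        rows.append({"variant_id": "y26", "chrom": "chrY", "subtype": "name_assigned", "clinical_class": "likely_pathogenic"})
        rows.append({"variant_id": "x0", "chrom": "chr1", "subtype": "novel", "clinical_class": "pathogenic"})
        tabs = va.distribution_tables(pd.DataFrame(rows))
        frac = tabs["pathogenicity_fractions"].set_index("chrom").loc["chrY", "pathogenic"]
        assert frac == pytest.approx(26 / 27)

    def test_count_conservation(self, sim_bundle):
        """Subtype counts per chromosome sum to the deduplicated lncG-hit
        totals on that chromosome."""
        from lnckaryotype.model import genes_to_frame
        from lnckaryotype.subtype_classifier import classify_genes

        genes = classify_genes(genes_to_frame(g for g in sim_bundle.genes if g.biotype == "lncRNA"))
        from lnckaryotype.model import variants_to_frame

        vdf = va.add_clinical_class(variants_to_frame(sim_bundle.variants))
        hits = va.intersect(vdf, genes)
        tabs = va.distribution_tables(hits)
        by_sub = tabs["subtype_by_chromosome"].set_index("chrom")
        # per-(chrom, subtype) counts deduplicate on variant id, so summing
        # rows can only reach or exceed the per-chromosome dedup totals
        totals = tabs["per_chromosome_totals"].set_index("chrom")["n_variants"]
        for chrom in by_sub.index:
            assert by_sub.loc[chrom].sum() >= totals[chrom]


class TestChiSquare:
    def test_observed_equals_expected(self):
        res = va.chisq_observed_expected([5, 5, 5], [1, 1, 1])
        assert res["X2"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_direct_formula_value(self):
        res = va.chisq_observed_expected([10, 0], [1, 1])
        assert res["X2"] == pytest.approx(10.0) and res["df"] == 1

    def test_weight_rescaling(self):
        res = va.chisq_observed_expected([8, 4], [2, 1])
        assert res["X2"] == pytest.approx(0.0)

    def test_matches_direct_evaluation_and_survival_function(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            k = int(rng.integers(2, 7))
            obs = rng.integers(0, 50, size=k).astype(float)
            w = rng.random(k) + 0.1
            res = va.chisq_observed_expected(obs, w)
            exp = w / w.sum() * obs.sum()
            assert res["X2"] == pytest.approx(float(((obs - exp) ** 2 / exp).sum()), abs=1e-10)
            assert res["p"] == pytest.approx(float(stats.chi2.sf(res["X2"], k - 1)), abs=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            va.chisq_observed_expected([1, 2], [0, 1])


class TestCrossref:
    def _hits(self):
        return pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "chrom": ["chr1", "chr1"], "pos": [150, 300],
             "gene_id": ["G1", "G1"], "biotype": ["lncRNA"] * 2}
        )

    def test_exact_coordinate_join(self):
        validated = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [150]})
        out = va.crossref_validated(self._hits(), validated)
        assert out["validated"].tolist() == [True, False]

    def test_off_by_one_not_flagged(self):
        validated = pd.DataFrame({"chrom": ["chr1"], "start": [151], "end": [151]})
        assert not va.crossref_validated(self._hits(), validated)["validated"].any()

    def test_duplicate_validated_rows_collapse(self):
        validated = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [150, 150], "end": [150, 150]})
        out = va.crossref_validated(self._hits(), validated)
        assert int(out["validated"].sum()) == 1
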