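"""Counts, densities, window tracks and quantile peak calling."""

import math

import numpy as np
import pandas as pd
import pytest

from lnckaryotype import karyotype_density as kd
from lnckaryotype.model import GenomeAssembly


def frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype", "length"])


def gene(i, chrom, start, end, biotype="lncRNA"):
    return (f"G{i}", None, chrom, start, end, "+", biotype, end - start + 1)


@pytest.fixture
def assembly():
    return GenomeAssembly(names=("chr1", "chr2"), lengths={"chr1": 3_000_000, "chr2": 2_000_000})


class TestCounts:
    def test_zero_filled_counts(self, assembly):
        genes = frame([gene(1, "chr1", 10, 20), gene(2, "chr1", 30, 40), gene(3, "chr1", 50, 60)])
        out = kd.count_by_chromosome(genes, assembly)
        by = out.set_index("chrom")["count"]
        assert by["chr1"] == 3 and by["chr2"] == 0

    def test_density_arithmetic(self, assembly):
        genes = frame([gene(i, "chr2", 1000 * i, 1000 * i + 10) for i in range(1, 11)])
        out = kd.count_by_chromosome(genes, assembly)
        row = out[out["chrom"] == "chr2"].iloc[0]
        assert row["density_per_mb"] == pytest.approx(5.0)


class TestPearson:
    def test_perfect_and_inverse(self):
        assert kd.pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert kd.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 5/ (n); Sxx = 42/9 * n; Syy = 6 -> r = 5 / sqrt(28)
        assert kd.pearson_r([1, 2, 4], [2, 2, 5]) == pytest.approx(5 / math.sqrt(28))

    def test_zero_variance_signaled(self):
        with pytest.raises(kd.DegenerateInputError):
            kd.pearson_r([1, 1, 1], [1, 2, 3])


class TestWindowedDensity:
    def test_anchor_window_assignment(self):
        assert kd.window_index(1_500_000) == 1
        assert kd.window_index(1) == 0
        assert kd.window_index(1_000_000) == 0
        assert kd.window_index(1_000_001) == 1

    def test_counts_tile_chromosome(self, assembly):
        genes = frame([gene(i, "chr1", 500_000 + i, 500_100 + i) for i in range(5)])
        track = kd.windowed_density(genes, assembly)
        chr1 = track[track["chrom"] == "chr1"]
        assert chr1["count"].tolist() == [5, 0, 0]

    def test_conservation_on_synthetic_bundle(self, sim_bundle):
        from lnckaryotype.model import genes_to_frame

        genes = genes_to_frame(sim_bundle.genes)
        track = kd.windowed_density(genes, sim_bundle.config.assembly)
        summed = track.groupby(["chrom", "biotype"])["count"].sum()
        direct = genes.groupby(["chrom", "biotype"]).size()
        for key, n in direct.items():
            assert summed[key] == n

    def test_hotspot_window_contains_injected_excess(self, sim_bundle):
        from lnckaryotype.model import genes_to_frame

        genes = genes_to_frame(sim_bundle.genes)
        track = kd.windowed_density(genes, sim_bundle.config.assembly)
        hot = sim_bundle.config.hotspots[0]
        row = track[
            (track["chrom"] == hot.chrom)
            & (track["biotype"] == "lncRNA")
            & (track["window_index"] == hot.window_index)
        ]
        truth = sim_bundle.truth_genes
        background = truth[
            (truth["biotype"] == "lncRNA")
            & (truth["chrom"] == hot.chrom)
            & (~truth["hotspot"])
            & (truth["start"].between(hot.window_index * 1_000_000 + 1, (hot.window_index + 1) * 1_000_000))
        ]
        assert int(row["count"].iloc[0]) == len(background) + hot.extra_genes


class TestCallPeaks:
    def _track(self, counts, chrom="chr1", biotype="lncRNA"):
        n = len(counts)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "biotype": biotype,
                "window_index": range(n),
                "window_start": [i * 1_000_000 + 1 for i in range(n)],
                "window_end": [(i + 1) * 1_000_000 for i in range(n)],
                "count": counts,
                "density": [float(c) for c in counts],
            }
        )

    def test_single_window_is_true_peak(self):
        out = kd.call_peaks(self._track([7]))
        assert out["is_true_peak"].all() and out["threshold"].iloc[0] == 7

    def test_type7_quantile_on_1_to_100(self):
        out = kd.call_peaks(self._track(list(range(1, 101))))
        # h = (n-1)q + 1 = 95.05 -> threshold 95.05; counts 96..100 are TRUE
        assert out["threshold"].iloc[0] == pytest.approx(95.05)
        assert out["is_true_peak"].sum() == 5
        assert sorted(out.loc[out["is_true_peak"], "count"]) == [96, 97, 98, 99, 100]

    def test_all_equal_all_true(self):
        out = kd.call_peaks(self._track([4] * 10))
        assert out["is_true_peak"].all()

    def test_brute_force_equivalence_tie_free(self):
        """On tie-free densities the quantile rule selects exactly the
        sort-and-slice top 5% (plus the interpolation boundary window)."""
        rng = np.random.default_rng(42)
        for n in (20, 100, 333, 1000):
            dens = rng.permutation(n).astype(float) + rng.random(n)  # tie-free
            out = kd.call_peaks(self._track(dens))
            called = set(out.loc[out["is_true_peak"], "window_index"])
            order = np.argsort(dens)[::-1]
            k = int(np.ceil(0.05 * (n - 1)))  # windows strictly above the h-th order stat
            brute = set(order[: max(k, 1)])
            assert brute == called

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            kd.call_peaks(pd.DataFrame())
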