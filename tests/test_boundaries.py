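"""Boundary extents, eligibility filters and the permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stressweave.boundaries import (
    FIVE,
    THREE,
    boundary_change_test,
    classify_direction,
    estimate_extents,
    filter_boundary_genes,
    format_empirical_p,
    null_range,
)
from stressweave.genome import Annotation, Gene
from stressweave.simulate import SimulationConfig, simulate_extent_table
from stressweave.transcription import TranscribedLocus


def one_sample_sheet():
    return pd.DataFrame(
        {"strain": ["WT"], "timepoint": [0], "replicate": [1]}, index=["s1"]
    )


def locus(start, end, strand="+", labels=(), chrom="chr1"):
    return TranscribedLocus(chrom, strand, start, end, peak_height=5,
                            labels=list(labels))


class TestEstimateExtents:
    def test_locus_coinciding_with_cds(self):
        ann = Annotation(
            [Gene("g", "chr1", 100, 600, "+", "coding", cds_start=150, cds_end=500)],
            {"chr1": 1000},
        )
        ext = estimate_extents({"s1": [locus(150, 500, labels=["g"])]}, ann,
                               one_sample_sheet())
        vals = ext.set_index("end")["extent"]
        assert vals[FIVE] == 0.0 and vals[THREE] == 0.0

    def test_plus_strand_coordinate_arithmetic(self):
        ann = Annotation(
            [Gene("g", "chr1", 120, 620, "+", "coding", cds_start=150, cds_end=500)],
            {"chr1": 1000},
        )
        ext = estimate_extents({"s1": [locus(100, 600, labels=["g"])]}, ann,
                               one_sample_sheet())
        vals = ext.set_index("end")["extent"]
        assert vals[FIVE] == 50.0 and vals[THREE] == 100.0

    def test_minus_strand_swaps_ends(self):
        ann = Annotation(
            [Gene("g", "chr1", 120, 620, "-", "coding", cds_start=150, cds_end=500)],
            {"chr1": 1000},
        )
        ext = estimate_extents({"s1": [locus(100, 600, "-", labels=["g"])]}, ann,
                               one_sample_sheet())
        vals = ext.set_index("end")["extent"]
        assert vals[FIVE] == 100.0 and vals[THREE] == 50.0

    def test_missing_when_no_locus_covers_cds(self):
        ann = Annotation(
            [Gene("g", "chr1", 100, 600, "+", "coding", cds_start=150, cds_end=500)],
            {"chr1": 1000},
        )
        ext = estimate_extents({"s1": [locus(700, 900)]}, ann, one_sample_sheet())
        assert ext.empty


class TestNullRange:
    def test_zero_variance(self):
        L = null_range("g", FIVE, [100, 100, 100])
        assert (L.lower, L.upper) == (100.0, 100.0)

    def test_arithmetic(self):
        """y=[90,110,100,100,100,100]: mean 100, sd sqrt(40)."""
        L = null_range("g", FIVE, [90, 110, 100, 100, 100, 100])
        sd = math.sqrt(200 / 5)
        assert L.lower == pytest.approx(100 - 2 * sd)
        assert L.upper == pytest.approx(100 + 2 * sd)
        assert L.contains(100) and not L.contains(120)

    def test_translation_equivariance(self, rng):
        y = rng.uniform(50, 150, size=8)
        L1 = null_range("g", FIVE, y)
        L2 = null_range("g", FIVE, y + 17)
        assert L2.lower == pytest.approx(L1.lower + 17)
        assert L2.upper == pytest.approx(L1.upper + 17)

    def test_lower_clamped_at_zero(self):
        L = null_range("g", FIVE, [1.0, 9.0])
        assert L.lower == 0.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            null_range("g", FIVE, [5.0])


def extent_rows(gene, end, extents_by_tp, strain="WT"):
    rows = []
    for t, vals in extents_by_tp.items():
        for r, v in enumerate(vals, 1):
            rows.append(dict(gene=gene, end=end, strain=strain, timepoint=t,
                             replicate=r, sample=f"{strain}_t{t}_r{r}",
                             extent=float(v), multi_orf=False))
    return rows


class TestFilters:
    def test_low_expression_removed(self, small_dataset):
        expr = small_dataset.expression
        gene = expr.rpkm.index[0]
        df = pd.DataFrame(extent_rows(gene, FIVE, {0: [50, 50, 50]}))
        low = expr.rpkm.copy()
        low.loc[gene] = 3.0  # log2 rpkm ~ 1.58 < 2
        weak = type(expr)(counts=expr.counts, rpkm=low,
                          feature_lengths=expr.feature_lengths, samples=expr.samples)
        kept, removed = filter_boundary_genes(df, weak)
        assert kept.empty
        assert (removed["reason"] == "low_expression").any()

    def test_multi_orf_removed(self, small_dataset):
        gene = small_dataset.expression.rpkm.index[0]
        df = pd.DataFrame(extent_rows(gene, FIVE, {0: [50, 50, 50]}))
        df["multi_orf"] = True
        kept, removed = filter_boundary_genes(df, small_dataset.expression)
        assert kept.empty
        assert (removed["reason"] == "multi_orf").any()

    def test_single_replicate_timepoint_dropped(self, small_dataset):
        gene = small_dataset.expression.rpkm.index.max()  # well-expressed gene
        df = pd.DataFrame(extent_rows(gene, FIVE, {0: [50, 50, 50], 15: [80]}))
        kept, removed = filter_boundary_genes(df, small_dataset.expression)
        assert set(kept["timepoint"]) == {0}
        assert removed["reason"].str.startswith("insufficient_replicates").any()


class TestBoundaryChangeTest:
    def test_identical_extents_not_significant(self):
        df = pd.DataFrame(
            extent_rows("g", THREE, {t: [60, 60, 60] for t in (0, 15, 30, 60)})
        )
        calls = boundary_change_test(df, n_perm=500, seed=0)
        assert (calls["delta"] == 0).all()
        assert not calls["significant"].any()
        assert (calls["empirical_p"] == 1.0).all()  # ties: all permutations >= 0

    def test_planted_60nt_extension_recovered(self):
        planted = [dict(gene="gene0001", end=THREE, timepoint=15, delta=60)]
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, replicates=3)
            ext = simulate_extent_table(20, cfg, planted=planted, extent_sd=8.0,
                                        rng=np.random.default_rng(seed))
            calls = boundary_change_test(ext, n_perm=1000, seed=seed)
            row = calls[(calls.gene == "gene0001") & (calls.end == THREE)
                        & (calls.timepoint == 15)]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 9

    def test_20nt_extension_never_significant(self):
        """Below the 30-nt rule the call must fail regardless of p."""
        df = pd.DataFrame(
            extent_rows("g", THREE, {0: [50.0, 50.1, 49.9],
                                     15: [70.0, 70.1, 69.9],
                                     30: [50.0, 50.2, 49.8]})
        )
        calls = boundary_change_test(df, n_perm=2000, seed=3)
        row = calls[calls.timepoint == 15].iloc[0]
        assert row["delta"] == pytest.approx(20, abs=0.5)
        assert not row["significant"]

    def test_exhaustive_agreement_small_design(self):
        """<= 8 samples: empirical p within 3 SE of full enumeration."""
        vals = [10.0, 12.0, 11.0, 14.0, 55.0, 49.0, 60.0, 52.0]
        tps = [0, 0, 0, 0, 15, 15, 15, 15]
        df = pd.DataFrame(
            dict(gene="g", end=THREE, strain="WT", timepoint=tps,
                 replicate=[1, 2, 3, 4] * 2,
                 sample=[f"s{i}" for i in range(8)], extent=vals, multi_orf=False)
        )
        arr = np.array(vals)
        obs = arr[4:].mean() - arr[:4].mean()
        perms = list(itertools.permutations(range(8)))
        exact = np.mean(
            [arr[list(p)][4:].mean() - arr[list(p)][:4].mean() >= obs for p in perms]
        )
        calls = boundary_change_test(df, n_perm=10_000, seed=9)
        est = calls["empirical_p"].iloc[0]
        se = math.sqrt(max(exact * (1 - exact), 1e-8) / 10_000)
        assert abs(est - exact) <= 3 * max(se, 1e-4)

    def test_null_calibration(self):
        """Type-I: fraction of p <= 0.05 within binomial CI around 0.05."""
        ext = simulate_extent_table(60, SimulationConfig(seed=5), extent_sd=12.0,
                                    rng=np.random.default_rng(5))
        calls = boundary_change_test(ext, n_perm=1000, seed=6)
        rate = (calls["empirical_p"] <= 0.05).mean()
        n = len(calls)
        half = 1.96 * math.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half - 0.01 <= rate <= 0.05 + half + 0.01

    def test_strand_symmetry(self):
        """Mirroring the genome swaps 5'/3' extents and results exactly."""
        ann_f = Annotation(
            [Gene("g", "chr1", 100, 620, "+", "coding", cds_start=150, cds_end=500)],
            {"chr1": 1000},
        )
        # mirrored: coordinate x -> 1000 - x, strand flipped
        ann_r = Annotation(
            [Gene("g", "chr1", 380, 900, "-", "coding", cds_start=500, cds_end=850)],
            {"chr1": 1000},
        )
        ext_f = estimate_extents({"s1": [locus(110, 600, "+", labels=["g"])]},
                                 ann_f, one_sample_sheet())
        ext_r = estimate_extents({"s1": [locus(400, 890, "-", labels=["g"])]},
                                 ann_r, one_sample_sheet())
        f = ext_f.set_index("end")["extent"]
        r = ext_r.set_index("end")["extent"]
        assert f[FIVE] == r[FIVE] and f[THREE] == r[THREE]


class TestDirectionAndFormatting:
    def test_direction_partition_and_counts(self):
        calls = pd.DataFrame(
            dict(gene=["a", "b", "c"], end=[FIVE, THREE, THREE],
                 strain=["WT"] * 3, timepoint=[15] * 3,
                 delta=[40.0, -35.0, 50.0], min_rep_delta=[35.0, -40.0, 45.0],
                 n_replicates=[3] * 3, empirical_p=[0.001, 0.2, 0.01],
                 beyond_L=[True, False, True], fdr=[0.01, 0.3, 0.02],
                 significant=[True, False, True])
        )
        out, summary = classify_direction(calls)
        assert list(out["direction"]) == ["elongated", "shortened", "elongated"]
        counts = summary.set_index(["end", "direction"])["n_genes"]
        assert counts[(FIVE, "elongated")] == 1
        assert counts[(THREE, "elongated")] == 1

    def test_zero_p_reported_as_resolution_bound(self):
        assert format_empirical_p(0.0, 10_000) == "<0.0001"
        assert format_empirical_p(0.0123, 10_000) == "0.0123"
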