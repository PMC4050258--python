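"""The synthetic-data generator: determinism, layout feasibility, planted
effects recoverable by their estimators, and conservation checks."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from stressweave import io as swio
from stressweave.boundaries import estimate_extents
from stressweave.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_coverage,
    simulate_dataset,
    simulate_extent_table,
    _lagged_smooth,
)
from stressweave.transcription import CoverageTrack, call_transcribed_regions, label_loci


class TestAnnotationLayout:
    def test_requested_counts_produced(self, small_dataset):
        ds = small_dataset
        by_geom = {}
        for p in ds.truth.pairs:
            by_geom[p["geometry"]] = by_geom.get(p["geometry"], 0) + 1
        n_anti, n_conv, n_div = ds.config.pair_geometry_counts
        assert by_geom.get("antisense_overlap", 0) == n_anti
        assert by_geom.get("convergent", 0) == n_conv
        assert by_geom.get("divergent", 0) == n_div
        assert len(ds.annotation.coding_ids()) == ds.config.n_coding
        assert len(ds.annotation.ncrna_ids()) == ds.config.n_ncrna

    def test_isolated_only_layout(self):
        cfg = SimulationConfig(n_coding=10, n_ncrna=0, chrom_length=10_000,
                               pair_geometry_counts=(0, 0, 0))
        ann, truth = simulate_annotation(cfg, np.random.default_rng(0))
        assert len(ann) == 10 and not truth.pairs
        spans = sorted((g.start, g.end) for g in ann)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1  # non-overlapping

    def test_infeasible_layout_rejected(self):
        cfg = SimulationConfig(n_coding=100, n_ncrna=0, chrom_length=2_000,
                               pair_geometry_counts=(0, 0, 0))
        with pytest.raises(ValueError, match="chrom_length"):
            simulate_annotation(cfg, np.random.default_rng(0))

    def test_gff3_byte_identical_under_fixed_seed(self, tmp_path, small_config):
        texts = []
        for run in range(2):
            ann, _ = simulate_annotation(small_config,
                                         np.random.default_rng(small_config.seed))
            p = tmp_path / f"run{run}.gff3"
            swio.write_gff3(ann, p)
            texts.append(p.read_bytes())
        assert texts[0] == texts[1]

    def test_gff3_roundtrip(self, tmp_path, small_dataset):
        p = tmp_path / "ann.gff3"
        swio.write_gff3(small_dataset.annotation, p)
        back = swio.read_gff3(p)
        for g in small_dataset.annotation:
            h = back[g.gene_id]
            assert (h.start, h.end, h.strand, h.biotype) == \
                   (g.start, g.end, g.strand, g.biotype)
            assert (h.cds_start, h.cds_end) == (g.cds_start, g.cds_end)


class TestCoverage:
    def test_zero_depth_means_no_loci(self):
        cfg = SimulationConfig(n_coding=5, n_ncrna=2, chrom_length=6_000,
                               pair_geometry_counts=(0, 0, 0),
                               coverage_depth_mean=0.0, n_planted_extensions=0,
                               n_planted_modules=0, n_repression_pairs=0)
        ds = simulate_dataset(cfg, with_coverage=True)
        sample = next(iter(ds.tracks))
        for (chrom, strand), depth in ds.tracks[sample].items():
            track = CoverageTrack(chrom, strand, depth, sample, 1)
            assert call_transcribed_regions(track) == []

    def test_library_size_equals_total_depth(self, small_dataset):
        ds = small_dataset
        for sample, tracks in list(ds.tracks.items())[:4]:
            total = sum(int(d.sum()) for d in tracks.values())
            assert ds.library_sizes[sample] == total

    def test_planted_extension_recovered_by_estimator(self):
        """Mean estimated extent at the planted timepoint exceeds the t=0
        estimate by about delta."""
        cfg = SimulationConfig(seed=4, n_coding=12, n_ncrna=0, chrom_length=12_000,
                               pair_geometry_counts=(0, 0, 0),
                               n_planted_extensions=2, boundary_jitter_sd=3.0,
                               n_planted_modules=0, n_repression_pairs=0,
                               strains=("WT",))
        ds = simulate_dataset(cfg, with_coverage=True)
        loci = {}
        for sample, tracks in ds.tracks.items():
            per = []
            for (chrom, strand), depth in sorted(tracks.items()):
                t = CoverageTrack(chrom, strand, depth, sample,
                                  ds.library_sizes[sample])
                per += call_transcribed_regions(t)
            loci[sample] = label_loci(per, ds.annotation)
        ext = estimate_extents(loci, ds.annotation,
                               ds.expression.samples.loc[list(loci)])
        for plant in ds.truth.extensions:
            sub = ext[(ext.gene == plant["gene"]) & (ext.end == plant["end"])]
            at_t = sub[sub.timepoint == plant["timepoint"]]["extent"].mean()
            at_0 = sub[sub.timepoint == 0]["extent"].mean()
            assert at_t - at_0 == pytest.approx(plant["delta"], abs=15)


class TestExpressionAndModules:
    def test_module_correlation_near_target(self):
        """Empirical mean rho between ncRNA and in-module genes within
        +-0.1 of the target, averaged over seeds."""
        rhos = []
        for seed in range(6):
            ds = simulate_dataset(SimulationConfig(seed=seed))
            lfc = ds.profiles["log2fc"]["WT"]
            for m in ds.truth.modules:
                nc = lfc.loc[m["ncrna"]].to_numpy()
                for g in m["members"]:
                    rhos.append(np.corrcoef(nc, lfc.loc[g])[0, 1])
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.1)

    def test_flat_feature_zero_log2fc(self, small_dataset):
        lfc = small_dataset.profiles["log2fc"]["WT"]
        flat = [g for g in lfc.index if g not in small_dataset.truth.responsive
                and not any(g in m["members"] or g == m["ncrna"]
                            for m in small_dataset.truth.modules)]
        assert (lfc.loc[flat] == 0).all().all()

    def test_rpkm_invariant_to_depth_scaling(self):
        """Scaling coverage depth by 10 leaves RPKM expectations unchanged
        (library-size normalisation)."""
        from stressweave.transcription import quantify_loci

        rpkms = []
        for depth in (4.0, 40.0):
            cfg = SimulationConfig(seed=9, n_coding=10, n_ncrna=0,
                                   chrom_length=10_000,
                                   pair_geometry_counts=(0, 0, 0),
                                   coverage_depth_mean=depth,
                                   n_planted_extensions=0, n_planted_modules=0,
                                   n_repression_pairs=0, strains=("WT",),
                                   boundary_jitter_sd=0.0, frac_responsive=0.0)
            ds = simulate_dataset(cfg, with_coverage=True)
            expr = quantify_loci(ds.tracks, ds.annotation, ds.library_sizes,
                                 ds.expression.samples.loc[list(ds.tracks)])
            rpkms.append(expr.rpkm.mean(axis=1))
        ratio = (rpkms[1] / rpkms[0]).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestProtein:
    def test_replicate_count(self, small_dataset):
        ds = small_dataset
        per = ds.protein_samples.groupby(["strain", "timepoint"]).size()
        assert (per == ds.config.protein_replicates).all()

    def test_lag_transform_noise_free_limit(self):
        """With zero noise the protein log2FC equals the lagged smoothed
        transcript transform exactly."""
        lfc = np.array([0.0, 2.0, 2.0, 1.0, 0.0, 0.0])
        alpha = 0.5
        out = _lagged_smooth(lfc, alpha)
        expected = [0.0]
        for i in range(1, 6):
            expected.append(alpha * expected[-1] + (1 - alpha) * lfc[i - 1])
        assert out == pytest.approx(expected)
        assert out[1] == 0.0  # delayed: no response at the first stressed point

    def test_determinism_of_full_dataset(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a.expression.rpkm, b.expression.rpkm)
        pd.testing.assert_frame_equal(a.protein, b.protein)
        assert a.truth.to_dict() == b.truth.to_dict()


class TestExtentTable:
    def test_planted_delta_shifts_mean(self):
        planted = [dict(gene="gene0001", end="three_prime", timepoint=30, delta=50)]
        df = simulate_extent_table(5, SimulationConfig(seed=2), planted=planted,
                                   extent_sd=5.0, rng=np.random.default_rng(2))
        sub = df[(df.gene == "gene0001") & (df.end == "three_prime")]
        d = sub[sub.timepoint == 30].extent.mean() - sub[sub.timepoint == 0].extent.mean()
        assert d == pytest.approx(50, abs=12)

    def test_extents_nonnegative(self):
        df = simulate_extent_table(10, SimulationConfig(seed=3), extent_sd=80.0,
                                   rng=np.random.default_rng(3))
        assert (df.extent >= 0).all()
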