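"""Pair discovery geometry, profile correlation and the dosage/protein test."""

import numpy as np
import pandas as pd
import pytest

from stressweave.genome import Annotation, Gene
from stressweave.pairs import (
    ANTISENSE,
    ANTISENSE_EXCEEDS,
    CONVERGENT,
    DIVERGENT,
    SENSE_EXCEEDS,
    cesr_overlap_enrichment,
    convergent_divergent_correlation_summary,
    correlate_pair_profiles,
    dosage_vs_protein,
    find_pairs,
)
from stressweave.simulate import SimulationConfig, simulate_dataset


def two_gene_annotation(a_span, a_strand, b_span, b_strand, chrom_len=3000):
    def mk(name, span, strand):
        s, e = span
        third = (e - s) // 3
        return Gene(name, "chr1", s, e, strand, "coding",
                    cds_start=s + third, cds_end=e - third)
    return Annotation(
        [mk("A", a_span, a_strand), mk("B", b_span, b_strand)], {"chr1": chrom_len}
    )


class TestFindPairs:
    def test_antisense_overlap_with_bp(self):
        ann = two_gene_annotation((0, 1000), "+", (500, 1500), "-")
        pairs = find_pairs(ann)
        row = pairs.iloc[0]
        assert row["geometry"] == ANTISENSE
        assert row["overlap_bp"] == 500
        assert row["pair_class"] == "mRNA:mRNA"

    def test_convergent_orientation(self):
        ann = two_gene_annotation((0, 1000), "+", (1200, 2000), "-")
        pairs = find_pairs(ann)
        assert list(pairs["geometry"]) == [CONVERGENT]

    def test_divergent_orientation(self):
        ann = two_gene_annotation((0, 1000), "-", (1200, 2000), "+")
        pairs = find_pairs(ann)
        assert list(pairs["geometry"]) == [DIVERGENT]

    def test_gap_beyond_max_not_paired(self):
        ann = two_gene_annotation((0, 500), "+", (1700, 2200), "-")
        assert find_pairs(ann, max_gap=1000).empty

    def test_extension_turns_convergent_into_overlap(self):
        ann = two_gene_annotation((0, 1000), "+", (1100, 2000), "-")
        ext = {("A", "three_prime"): 150.0}  # + strand 3' end pushes right
        pairs = find_pairs(ann, boundary_extensions=ext)
        row = pairs.iloc[0]
        assert row["geometry"] == ANTISENSE
        assert row["from_convergent"]
        assert row["overlap_bp"] == 50

    def test_overlap_bp_equals_bruteforce_intersection(self, rng):
        for _ in range(20):
            a = sorted(rng.integers(0, 1500, size=2).tolist())
            b = sorted(rng.integers(0, 1500, size=2).tolist())
            if a[1] - a[0] < 60 or b[1] - b[0] < 60:
                continue
            ann = two_gene_annotation(tuple(a), "+", tuple(b), "-")
            pairs = find_pairs(ann, max_gap=10_000)
            brute = len(set(range(*a)) & set(range(*b)))
            if brute >= 1:
                assert pairs.iloc[0]["overlap_bp"] == brute
            else:
                assert (pairs["geometry"] != ANTISENSE).all()

    def test_strand_flip_symmetry(self):
        """Mirroring all strands maps convergent <-> divergent and keeps
        antisense overlaps with identical overlap size."""
        cases = [((0, 1000), "+", (1200, 2000), "-"),
                 ((0, 1000), "+", (600, 1600), "-")]
        flip = {"+": "-", "-": "+"}
        for a_span, a_s, b_span, b_s in cases:
            p1 = find_pairs(two_gene_annotation(a_span, a_s, b_span, b_s))
            p2 = find_pairs(two_gene_annotation(a_span, flip[a_s], b_span, flip[b_s]))
            g1, g2 = p1.iloc[0]["geometry"], p2.iloc[0]["geometry"]
            mirrored = {CONVERGENT: DIVERGENT, DIVERGENT: CONVERGENT,
                        ANTISENSE: ANTISENSE}
            assert g2 == mirrored[g1]
            assert p1.iloc[0]["overlap_bp"] == p2.iloc[0]["overlap_bp"]

    def test_planted_geometries_recovered(self, small_dataset):
        pairs = find_pairs(small_dataset.annotation)
        found = {(r["gene_a"], r["gene_b"]): r["geometry"] for _, r in pairs.iterrows()}
        for p in small_dataset.truth.pairs:
            assert found.get((p["gene_a"], p["gene_b"])) == p["geometry"]


class TestCorrelateProfiles:
    def test_identical_and_negated_profiles(self, small_dataset):
        expr = small_dataset.expression
        pairs = find_pairs(small_dataset.annotation)
        cors, excluded = correlate_pair_profiles(
            pairs, expr, strains=["WT", "mutant"], expression_floor_log2=2.0
        )
        assert ((cors["rho"] >= -1) & (cors["rho"] <= 1)).all()
        # exclusions carry reasons
        assert set(excluded.columns) == {"gene_a", "gene_b", "reason"}

    def test_perfect_correlation_of_self_pair(self, small_dataset):
        """A pair of a feature with itself has rho exactly 1."""
        expr = small_dataset.expression
        g = expr.rpkm.index[5]
        pairs = pd.DataFrame([dict(gene_a=g, gene_b=g, geometry=ANTISENSE,
                                   overlap_bp=1, pair_class="mRNA:mRNA",
                                   from_convergent=False, contains_cesr=False)])
        cors, _ = correlate_pair_profiles(pairs, expr, strains=["WT"],
                                          expression_floor_log2=-10)
        assert cors["rho"].iloc[0] == pytest.approx(1.0)


class TestCesrEnrichment:
    def test_zero_overlap_gives_p_one(self):
        res = cesr_overlap_enrichment(["a", "b"], ["c", "d"],
                                      ["a", "b", "c", "d", "e"])
        assert res.p_value == pytest.approx(1.0)
        assert res.overlap == 0

    def test_matches_enumeration_table(self):
        # 4-number table: universe 10, family 5, selected 4, overlap 4
        uni = [f"g{i}" for i in range(10)]
        res = cesr_overlap_enrichment(uni[:4], uni[:5], uni)
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_planted_enrichment_detected(self):
        """CESR genes planted opposite responsive antisense at 5x the
        background rate yield small p in most seeds."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_coding=120, n_ncrna=40,
                                   chrom_length=70_000,
                                   pair_geometry_counts=(30, 0, 0),
                                   n_repression_pairs=30,
                                   n_planted_modules=0, n_planted_extensions=0,
                                   cesr_fraction=0.08, cesr_enrichment_factor=5.0)
            ds = simulate_dataset(cfg)
            opposite = [r["coding"] for r in ds.truth.repression]
            res = cesr_overlap_enrichment(opposite, ds.truth.cesr,
                                          ds.annotation.coding_ids())
            hits += res.p_value < 0.01
        assert hits >= 7


@pytest.fixture(scope="module")
def dosage_run():
    cfg = SimulationConfig(seed=21, n_coding=60, n_ncrna=35,
                           chrom_length=45_000, pair_geometry_counts=(30, 0, 0),
                           n_repression_pairs=15, n_planted_modules=0,
                           n_planted_extensions=0)
    ds = simulate_dataset(cfg)
    pairs = find_pairs(ds.annotation)
    assign, summary, fam = dosage_vs_protein(
        pairs, ds.annotation, ds.expression, ds.protein, ds.protein_samples,
        strain="WT", families=ds.families,
    )
    return ds, assign, summary, fam


class TestDosageVsProtein:

    def test_groups_partition_pairs(self, dosage_run):
        _, assign, _, _ = dosage_run
        per_obs = assign.groupby(["pair", "timepoint"])["group"].nunique()
        assert (per_obs == 1).all()
        assert set(assign["group"]) <= {SENSE_EXCEEDS, ANTISENSE_EXCEEDS}

    def test_planted_repression_recovered(self, dosage_run):
        ds, assign, summary, _ = dosage_run
        assert summary["p_value"] < 0.01
        assert summary["mean_difference"] == pytest.approx(
            ds.config.repression_effect, abs=0.35
        )
        med = assign.groupby("group")["protein_log2fc"].median()
        assert med[ANTISENSE_EXCEEDS] < med[SENSE_EXCEEDS]

    def test_repression_pairs_assigned_antisense_exceeds(self, dosage_run):
        ds, assign, _, _ = dosage_run
        rep = {r["coding"] for r in ds.truth.repression if r["kind"] == "repression"}
        grp = assign[assign["coding_gene"].isin(rep)]
        assert (grp["group"] == ANTISENSE_EXCEEDS).mean() > 0.9

    def test_family_enrichment_table_shape(self, dosage_run):
        ds, _, _, fam = dosage_run
        assert set(fam["family"]) == set(ds.families.families)
        assert ((fam["p_value"] >= 0) & (fam["p_value"] <= 1)).all()

    def test_null_effect_gives_moderate_t(self):
        cfg = SimulationConfig(seed=77, n_coding=60, n_ncrna=35,
                               chrom_length=45_000, pair_geometry_counts=(30, 0, 0),
                               n_repression_pairs=15, repression_effect=0.0,
                               n_planted_modules=0, n_planted_extensions=0)
        ds = simulate_dataset(cfg)
        pairs = find_pairs(ds.annotation)
        _, summary, _ = dosage_vs_protein(
            pairs, ds.annotation, ds.expression, ds.protein, ds.protein_samples,
            strain="WT", per_pair_aggregate=True,
        )
        assert abs(summary["mean_difference"]) < 0.3


class TestStrataSummary:
    def test_partition_and_medians(self):
        cors = pd.DataFrame(
            dict(gene_a=["a", "c", "e"], gene_b=["b", "d", "f"],
                 geometry=[CONVERGENT, CONVERGENT, DIVERGENT],
                 rho=[-0.8, 0.1, 0.9], cluster_id=[1, 1, 2])
        )
        merged, summary = convergent_divergent_correlation_summary(cors, {"a"})
        assert summary["n"].sum() == len(cors)  # strata partition the pairs
        cesr_conv = summary[(summary.geometry == CONVERGENT) & summary.contains_cesr]
        assert cesr_conv["median_rho"].iloc[0] == pytest.approx(-0.8)

    def test_empty_input(self):
        cors = pd.DataFrame(columns=["gene_a", "gene_b", "geometry", "rho"])
        merged, summary = convergent_divergent_correlation_summary(cors, set())
        assert summary.empty and merged.empty
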