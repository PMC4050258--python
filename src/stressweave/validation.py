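"""Self-validation runs: each function recomputes, from scratch, one of the
package's headline performance quantities on freshly generated synthetic
data (segmentation exactness, statistical-oracle agreement, permutation
calibration, planted-effect recovery, determinism). Used by the acceptance
script and the acceptance test suite.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline
from .boundaries import boundary_change_test, estimate_extents
from .pairs import dosage_vs_protein, find_pairs
from .simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_extent_table,
)
from .stats import hypergeometric_overrep
from .transcription import CoverageTrack, call_transcribed_regions, label_loci


# ---------------------------------------------------------------------------
# segmentation exactness on constructed tracks


def segmentation_exactness(rng: np.random.Generator, n_cases: int = 50) -> dict:
    """Fraction of constructed coverage tracks whose called loci equal the
    planted transcripts exactly (inter-transcript gaps > merge threshold),
    plus the behaviour of the 50-vs-51-base gap boundary case."""
    ok = 0
    for _ in range(n_cases):
        n_tx = int(rng.integers(1, 6))
        depth = np.zeros(5000, dtype=int)
        planted = []
        cursor = int(rng.integers(0, 100))
        for _ in range(n_tx):
            width = int(rng.integers(30, 300))
            end = min(cursor + width, 5000)
            if end - cursor < 5:
                break
            depth[cursor:end] = int(rng.integers(2, 9))
            planted.append((cursor, end))
            cursor = end + int(rng.integers(51, 200))  # gap strictly > 50
            if cursor >= 4900:
                break
        track = CoverageTrack("c", "+", depth, "s", 1)
        called = [(l.start, l.end) for l in call_transcribed_regions(track)]
        ok += called == planted

    # boundary case: exactly 50 merges, 51 splits
    d50 = np.zeros(400, dtype=int)
    d50[50:100] = 3
    d50[150:200] = 3
    merged = call_transcribed_regions(CoverageTrack("c", "+", d50, "s", 1))
    d51 = np.zeros(400, dtype=int)
    d51[50:100] = 3
    d51[151:200] = 3
    split = call_transcribed_regions(CoverageTrack("c", "+", d51, "s", 1))
    boundary_ok = ([(l.start, l.end) for l in merged] == [(50, 200)]
                   and [(l.start, l.end) for l in split] == [(50, 100), (151, 200)])
    return dict(rate=ok / n_cases if boundary_ok else 0.0, n=n_cases + 2)


# ---------------------------------------------------------------------------
# hypergeometric oracle agreement


def _exact_tail(k: int, s: int, f: int, u: int) -> float:
    total = Fraction(0)
    for i in range(k, min(s, f) + 1):
        total += Fraction(math.comb(f, i) * math.comb(u - f, s - i), math.comb(u, s))
    return float(total)


def hypergeom_oracle_agreement(max_universe: int = 20) -> dict:
    """Max |p - exact| over all consistent parameter combinations with
    universe size <= ``max_universe`` (exact counting oracle)."""
    worst = 0.0
    n = 0
    for u in range(1, max_universe + 1):
        for f in range(0, u + 1):
            for s in range(0, u + 1):
                for k in range(max(0, s + f - u), min(s, f) + 1):
                    err = abs(hypergeometric_overrep(k, s, f, u) - _exact_tail(k, s, f, u))
                    worst = max(worst, err)
                    n += 1
    return dict(max_abs_error=worst, n=n)


# ---------------------------------------------------------------------------
# permutation-test calibration (null extents)


def permutation_calibration(seed: int, n_genes: int = 200, n_perm: int = 1000) -> dict:
    """Fraction of null (no planted extension) boundary tests with
    empirical p <= 0.05 on the full study design (two strain courses,
    3 replicates x 6 timepoints).

    Also returns the exact null expectation of that fraction for the
    plain-proportion estimator on the n_perm grid,
    P(Binomial(n_perm, U) <= floor(0.05 n_perm)) = (k+1)/(n_perm+1),
    which is the correct centre for a calibration band (the proportion
    estimator is discretely anticonservative by half a grid step)."""
    cfg = SimulationConfig(seed=seed)
    extents = simulate_extent_table(n_genes, cfg, extent_sd=12.0,
                                    rng=np.random.default_rng(seed),
                                    strains=cfg.strains)
    calls = boundary_change_test(extents, n_perm=n_perm, seed=seed + 1)
    rate = float((calls["empirical_p"] <= 0.05).mean())
    expected = (math.floor(0.05 * n_perm) + 1) / (n_perm + 1)
    return dict(rate=rate, expected=expected, n=len(calls))


# ---------------------------------------------------------------------------
# boundary recovery from coverage


def boundary_recovery(seed: int, n_seeds: int = 20, n_perm: int = 1000) -> dict:
    """Sensitivity for planted 50-60 nt extensions (coverage depth 5) under
    the >=30-nt + p<0.05 call rule, and false significant calls among
    unplanted genes, averaged over seeds."""
    sens_num = sens_den = false_calls = 0
    for i in range(n_seeds):
        s = seed + 1000 + i
        cfg = SimulationConfig(
            seed=s, n_coding=30, n_ncrna=0, chrom_length=25_000,
            pair_geometry_counts=(0, 0, 0), n_planted_extensions=10,
            n_planted_modules=0, n_repression_pairs=0, strains=("WT",),
            coverage_depth_mean=5.0, boundary_jitter_sd=8.0,
            frac_responsive=0.0,
        )
        ds = simulate_dataset(cfg, with_coverage=True)
        loci = {}
        for sample, tracks in ds.tracks.items():
            per = []
            for (chrom, strand), depth in sorted(tracks.items()):
                track = CoverageTrack(chrom, strand, depth, sample,
                                      ds.library_sizes[sample])
                per += call_transcribed_regions(track)
            loci[sample] = label_loci(per, ds.annotation)
        extents = estimate_extents(loci, ds.annotation,
                                   ds.expression.samples.loc[list(loci)])
        calls = boundary_change_test(extents, n_perm=n_perm, seed=s + 1)
        planted = {(e["gene"], e["end"], e["timepoint"]) for e in ds.truth.extensions}
        planted_genes = {g for g, _, _ in planted}
        sig = calls[calls["significant"]]
        hit = {(r["gene"], r["end"], r["timepoint"]) for _, r in sig.iterrows()}
        sens_num += len(planted & hit)
        sens_den += len(planted)
        false_calls += sum(1 for g, _, _ in hit if g not in planted_genes)
    return dict(sensitivity=sens_num / sens_den, false_calls=false_calls,
                n=sens_den)


# ---------------------------------------------------------------------------
# exhaustive-permutation agreement


def exhaustive_permutation_agreement(seed: int, n_perm: int = 10_000) -> dict:
    """|empirical p - exact p| in units of the binomial standard error on a
    design small enough (8 samples) to enumerate completely."""
    rng = np.random.default_rng(seed)
    vals = np.round(rng.normal(20, 6, size=8), 2)
    vals[4:] += 10.0
    tps = [0, 0, 0, 0, 15, 15, 15, 15]
    df = pd.DataFrame(
        dict(gene="g", end="three_prime", strain="WT", timepoint=tps,
             replicate=[1, 2, 3, 4] * 2, sample=[f"s{i}" for i in range(8)],
             extent=vals, multi_orf=False)
    )
    obs = vals[4:].mean() - vals[:4].mean()
    exact = float(np.mean([
        vals[list(p)][4:].mean() - vals[list(p)][:4].mean() >= obs
        for p in itertools.permutations(range(8))
    ]))
    calls = boundary_change_test(df, n_perm=n_perm, seed=seed + 1)
    est = float(calls["empirical_p"].iloc[0])
    se = math.sqrt(max(exact * (1 - exact), 1e-8) / n_perm)
    return dict(z=abs(est - exact) / max(se, 1e-4), empirical_p=est,
                exact_p=exact, n=n_perm)


# ---------------------------------------------------------------------------
# dosage-effect recovery and type-I error


def _dosage_config(seed: int, effect: float) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_coding=40, n_ncrna=24, chrom_length=32_000,
        pair_geometry_counts=(20, 0, 0), n_repression_pairs=10,
        repression_effect=effect, n_planted_modules=0, n_planted_extensions=0,
        n_families=3,
    )


def dosage_effect_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Mean recovered group difference (antisense-exceeds minus
    sense-exceeds protein log2FC) and the worst Welch p across seeds, with
    a planted repression of -1 log2 unit."""
    diffs, worst_p = [], 0.0
    for i in range(n_seeds):
        ds = simulate_dataset(_dosage_config(seed + 2000 + i, effect=-1.0))
        pairs = find_pairs(ds.annotation)
        _, summary, _ = dosage_vs_protein(
            pairs, ds.annotation, ds.expression, ds.protein, ds.protein_samples,
            strain="WT",
        )
        diffs.append(summary["mean_difference"])
        worst_p = max(worst_p, summary["p_value"])
    diffs = np.asarray(diffs)
    return dict(mean_difference=float(diffs.mean()),
                sd_over_seeds=float(diffs.std(ddof=1)),
                max_p=worst_p, n=n_seeds)


def dosage_null_type1(seed: int, n_seeds: int = 100) -> dict:
    """Type-I error of the dosage t-test (per-pair aggregated observations)
    with zero planted effect."""
    hits = 0
    for i in range(n_seeds):
        ds = simulate_dataset(_dosage_config(seed + 3000 + i, effect=0.0))
        pairs = find_pairs(ds.annotation)
        _, summary, _ = dosage_vs_protein(
            pairs, ds.annotation, ds.expression, ds.protein, ds.protein_samples,
            strain="WT", per_pair_aggregate=True,
        )
        hits += summary["p_value"] < 0.05
    return dict(rate=hits / n_seeds, n=n_seeds)


# ---------------------------------------------------------------------------
# association recovery and null FP rate


def association_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of planted ncRNA-family modules (rho ~0.9, 80% of a
    50-gene family) called significant at FDR 5%."""
    from .association import associate_ncrnas

    hits = total = 0
    for i in range(n_seeds):
        ds = simulate_dataset(SimulationConfig(seed=seed + 4000 + i))
        expr = ds.expression
        nc_ids = [m["ncrna"] for m in ds.truth.modules]
        nc_prof = expr.log2fc_profiles(nc_ids, "WT")
        cod_prof = expr.log2fc_profiles(sorted(ds.annotation.coding_ids()), "WT")
        mat = associate_ncrnas(nc_prof, cod_prof, ds.families)
        for m in ds.truth.modules:
            total += 1
            hits += mat.cell(m["family"], m["ncrna"]) != 0
    return dict(rate=hits / total, n=total)


def association_null_fp(seed: int, n_draws: int = 60) -> dict:
    """Per-family false-positive rate at FDR 5% when correlated sets are
    drawn uniformly at random from the universe."""
    from .association import annotate_ncrna, build_association_matrix
    from .stats import GeneFamilyCollection

    rng = np.random.default_rng(seed + 5000)
    uni = [f"g{i}" for i in range(200)]
    fams = GeneFamilyCollection(
        families={f"f{j}": frozenset(rng.choice(uni, 25, replace=False))
                  for j in range(8)},
        universe=frozenset(uni),
    )
    fp = n = 0
    for _ in range(n_draws):
        sel = set(rng.choice(uni, 20, replace=False))
        tests = annotate_ncrna("nc", fams, sel, set())
        mat = build_association_matrix(tests, sorted(fams.families), ["nc"])
        fp += int((mat.matrix.to_numpy() != 0).sum())
        n += len(fams.families)
    return dict(rate=fp / n, n=n)


# ---------------------------------------------------------------------------
# RPKM closed form and determinism


def rpkm_checks() -> dict:
    from .transcription import compute_rpkm

    unit = compute_rpkm(1000, 1000, 1_000_000)
    scale_ok = all(
        math.isclose(compute_rpkm(c * k, l, lib * k), compute_rpkm(c, l, lib),
                     rel_tol=1e-12)
        for c, l, lib, k in [(10, 500, 2_000_000, 7), (3, 80, 55_000, 13)]
    )
    return dict(unit_case=unit, scale_invariant=bool(scale_ok), n=3)


def determinism_check(seed: int, work_dir: str | Path) -> dict:
    """Two full pipeline runs under one manifest seed: 1.0 when every
    numeric output is byte-identical."""
    work_dir = Path(work_dir)
    cfg = SimulationConfig(
        seed=seed, n_coding=24, n_ncrna=14, chrom_length=25_000,
        pair_geometry_counts=(6, 3, 3), n_planted_extensions=3,
        n_planted_modules=1, module_family_size=10, n_repression_pairs=3,
        n_families=3,
    )
    digests = []
    patterns = ("*.tsv", "*.bedgraph", "*.bed", "*.gff3", "*.gmt",
                "truth.json", "*ttest.json", "report.txt")
    for run in ("a", "b"):
        run_dir = work_dir / f"determinism_{run}"
        pipeline.run_pipeline(run_dir, cfg, n_perm=300, resume=False)
        files = {}
        for pat in patterns:
            for p in sorted(run_dir.rglob(pat)):
                files[str(p.relative_to(run_dir))] = p.read_bytes()
        digests.append(files)
    identical = (set(digests[0]) == set(digests[1])
                 and all(digests[0][k] == digests[1][k] for k in digests[0]))
    return dict(identical=float(identical), n=len(digests[0]))
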