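"""End-to-end orchestration of the analysis stages on a directory layout.

Stages run in dependency order (simulate -> segment -> boundaries -> pairs
-> associate -> report); each writes its outputs under the run directory
and registers them, with checksums, in the run manifest. Re-invoking a run
skips stages whose registered outputs are present and unchanged.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import association, boundaries, io, pairs, simulate, transcription
from .genome import Annotation

STAGES = ("simulate", "segment", "boundaries", "pairs", "associate", "report")


class StageError(RuntimeError):
    """Failure inside one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-run record of config, seed and output checksums."""

    def __init__(self, run_dir: Path, config: dict, seed: int):
        self.path = run_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = dict(config=config, seed=seed, stages={})
        self.data["config"] = config
        self.data["seed"] = seed

    def stage_done(self, stage: str, run_dir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec:
            return False
        for rel, digest in rec["outputs"].items():
            p = run_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, run_dir: Path, outputs: list[Path]) -> None:
        self.data["stages"][stage] = dict(
            outputs={str(p.relative_to(run_dir)): _sha256(p) for p in outputs},
            finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stage implementations


def stage_simulate(run_dir: Path, config: simulate.SimulationConfig) -> list[Path]:
    ds = simulate.simulate_dataset(config, with_coverage=True)
    out = []

    def w(name: str, fn) -> Path:
        p = run_dir / name
        fn(p)
        out.append(p)
        return p

    w("annotation.gff3", lambda p: io.write_gff3(ds.annotation, p))
    w("gene_sets.gmt", lambda p: io.write_gmt(ds.families, p))
    w("truth.json", lambda p: io.write_json(ds.truth.to_dict(), p))
    samples = ds.expression.samples.copy()
    samples["library_size"] = pd.Series(ds.library_sizes)
    w("samples.tsv", lambda p: io.write_tsv(samples, p))
    w("rpkm.tsv", lambda p: io.write_tsv(ds.expression.rpkm, p))
    w("counts.tsv", lambda p: io.write_tsv(ds.expression.counts, p))
    w("feature_lengths.tsv", lambda p: io.write_tsv(ds.expression.feature_lengths.to_frame(), p))
    w("protein.tsv", lambda p: io.write_tsv(ds.protein, p))
    w("protein_samples.tsv", lambda p: io.write_tsv(ds.protein_samples, p))
    w("de_flags.tsv", lambda p: io.write_tsv(ds.de_flags(), p, index=False))
    cov = run_dir / "coverage"
    cov.mkdir(exist_ok=True)
    for sample, tracks in sorted(ds.tracks.items()):
        for (chrom, strand), depth in sorted(tracks.items()):
            suffix = "plus" if strand == "+" else "minus"
            p = cov / f"{sample}.{suffix}.bedgraph"
            io.write_bedgraph(depth, chrom, p)
            out.append(p)
    return out


def _load_coverage(run_dir: Path, annotation: Annotation) -> tuple[dict, dict, pd.DataFrame]:
    samples = pd.read_csv(run_dir / "samples.tsv", sep="\t", index_col=0)
    tracks: dict[str, dict] = {}
    for sample in samples.index:
        per = {}
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            path = run_dir / "coverage" / f"{sample}.{suffix}.bedgraph"
            if not path.exists():
                raise FileNotFoundError(f"missing coverage file: {path}")
            for chrom, depth in io.read_bedgraph(path, annotation.chrom_lengths).items():
                per[(chrom, strand)] = depth
        tracks[sample] = per
    lib = samples["library_size"].astype(int).to_dict()
    return tracks, lib, samples


def stage_segment(run_dir: Path, min_peak: int = 2, merge_gap: int = 50) -> list[Path]:
    annotation = io.read_gff3(run_dir / "annotation.gff3")
    tracks, lib, samples = _load_coverage(run_dir, annotation)
    loci_dir = run_dir / "loci"
    loci_dir.mkdir(exist_ok=True)
    out = []
    loci_by_sample = {}
    for sample in samples.index:
        loci = []
        for (chrom, strand), depth in sorted(tracks[sample].items()):
            track = transcription.CoverageTrack(chrom, strand, depth, sample, lib[sample])
            loci += transcription.call_transcribed_regions(track, min_peak, merge_gap)
        loci = transcription.label_loci(sorted(loci, key=lambda l: (l.chromosome, l.start)),
                                        annotation)
        loci_by_sample[sample] = loci
        p = loci_dir / f"{sample}.loci.bed"
        io.write_loci_bed(loci, p)
        out.append(p)
    expr = transcription.quantify_loci(tracks, annotation, lib,
                                       samples[["strain", "timepoint", "replicate"]])
    p = run_dir / "expression_cds.tsv"
    io.write_tsv(expr.rpkm, p)
    out.append(p)
    return out


def stage_boundaries(run_dir: Path, n_perm: int, seed: int,
                     min_delta: float = 30.0) -> list[Path]:
    annotation = io.read_gff3(run_dir / "annotation.gff3")
    tracks, lib, samples = _load_coverage(run_dir, annotation)
    loci_by_sample = {
        s: io.read_loci_bed(run_dir / "loci" / f"{s}.loci.bed") for s in samples.index
    }
    expr = transcription.quantify_loci(tracks, annotation, lib,
                                       samples[["strain", "timepoint", "replicate"]])
    extents = boundaries.estimate_extents(loci_by_sample, annotation,
                                          samples[["strain", "timepoint", "replicate"]])
    kept, removed = boundaries.filter_boundary_genes(extents, expr)
    calls = boundaries.boundary_change_test(kept, n_perm=n_perm, seed=seed,
                                            min_delta=min_delta)
    calls, summary = boundaries.classify_direction(calls)
    out = []
    for name, df, idx in (("extents.tsv", extents, False),
                          ("boundary_filtered_out.tsv", removed, False),
                          ("boundary_calls.tsv", calls, False),
                          ("boundary_summary.tsv", summary, False)):
        p = run_dir / name
        io.write_tsv(df, p, index=idx)
        out.append(p)
    return out


def stage_pairs(run_dir: Path, max_gap: int = 1_000) -> list[Path]:
    annotation = io.read_gff3(run_dir / "annotation.gff3")
    expr = _read_expression(run_dir)
    families = io.read_gmt(run_dir / "gene_sets.gmt")
    cesr = families.families.get("CESR", frozenset())
    calls = pd.read_csv(run_dir / "boundary_calls.tsv", sep="\t")
    ext = {
        (r["gene"], r["end"]): r["delta"]
        for _, r in calls[calls["significant"].astype(bool)].iterrows()
    }
    pair_table = pairs.find_pairs(annotation, boundary_extensions=ext,
                                  max_gap=max_gap, cesr_set=cesr)
    strains = sorted(expr.samples["strain"].unique())
    cors, excluded = pairs.correlate_pair_profiles(pair_table, expr, strains)
    protein = io.read_matrix_tsv(run_dir / "protein.tsv")
    psamples = pd.read_csv(run_dir / "protein_samples.tsv", sep="\t", index_col=0)
    assign, ttest, fam_table = pairs.dosage_vs_protein(
        pair_table, annotation, expr, protein, psamples, strain=strains[0],
        families=families,
    )
    _, strata = pairs.convergent_divergent_correlation_summary(cors, cesr)
    out = []
    for name, df, idx in (("pairs.tsv", pair_table, False),
                          ("pair_correlations.tsv", cors, False),
                          ("pair_excluded.tsv", excluded, False),
                          ("dosage_groups.tsv", assign, False),
                          ("dosage_family_enrichment.tsv", fam_table, False),
                          ("correlation_strata.tsv", strata, False)):
        p = run_dir / name
        io.write_tsv(df, p, index=idx)
        out.append(p)
    p = run_dir / "dosage_ttest.json"
    io.write_json(ttest, p)
    out.append(p)
    return out


def _read_expression(run_dir: Path) -> transcription.ExpressionMatrix:
    rpkm = io.read_matrix_tsv(run_dir / "rpkm.tsv")
    counts = io.read_matrix_tsv(run_dir / "counts.tsv")
    lengths = io.read_matrix_tsv(run_dir / "feature_lengths.tsv").iloc[:, 0]
    samples = pd.read_csv(run_dir / "samples.tsv", sep="\t", index_col=0)
    return transcription.ExpressionMatrix(
        counts=counts, rpkm=rpkm, feature_lengths=lengths,
        samples=samples[["strain", "timepoint", "replicate"]],
    )


def stage_associate(run_dir: Path, rho: float = 0.7, fdr: float = 0.05) -> list[Path]:
    expr = _read_expression(run_dir)
    annotation = io.read_gff3(run_dir / "annotation.gff3")
    families = io.read_gmt(run_dir / "gene_sets.gmt")
    de = pd.read_csv(run_dir / "de_flags.tsv", sep="\t")
    nc_ids = sorted(set(annotation.ncrna_ids())
                    & set(de.loc[de["significant"], "feature"]))
    coding = sorted(set(annotation.coding_ids()) & set(expr.rpkm.index))
    out = []
    matrices = {}
    for strain in sorted(expr.samples["strain"].unique()):
        nc_prof = expr.log2fc_profiles(nc_ids, strain)
        cod_prof = expr.log2fc_profiles(coding, strain)
        mat = association.associate_ncrnas(nc_prof, cod_prof, families,
                                           rho_threshold=rho, fdr_threshold=fdr)
        matrices[strain] = mat
        p = run_dir / f"association_{strain}.tsv"
        io.write_tsv(mat.matrix, p)
        out.append(p)
        p = run_dir / f"association_tests_{strain}.tsv"
        io.write_tsv(mat.tests, p, index=False)
        out.append(p)
        p = run_dir / f"association_order_{strain}.json"
        io.write_json(dict(rows=list(mat.row_order), cols=list(mat.col_order)), p)
        out.append(p)
    strains = sorted(matrices)
    if len(strains) >= 2:
        # canonical order: WT first when present
        a = "WT" if "WT" in strains else strains[0]
        b = next(s for s in strains if s != a)
        changes = association.compare_strain_associations(
            matrices[a], matrices[b], name_a=a, name_b=b
        )
        p = run_dir / "association_changes.tsv"
        io.write_tsv(changes, p, index=False)
        out.append(p)
    return out


def stage_report(run_dir: Path) -> list[Path]:
    from .report import render_report

    text = render_report(run_dir)
    p = run_dir / "report.txt"
    p.write_text(text)
    return [p]


def run_pipeline(
    out_dir: str | Path,
    config: simulate.SimulationConfig | None = None,
    seed: int | None = None,
    n_perm: int = 2_000,
    resume: bool = True,
) -> Path:
    """Run all stages under ``out_dir``; returns the run directory.

    All randomness derives from the single manifest seed (the config seed,
    overridable with ``seed``). With ``resume`` stages whose recorded
    outputs are intact are skipped.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config = config or simulate.SimulationConfig()
    if seed is not None:
        config = simulate.SimulationConfig(**{**asdict(config), "seed": seed})
    manifest = Manifest(run_dir, asdict(config), config.seed)

    def run_stage(name: str, fn):
        if resume and manifest.stage_done(name, run_dir):
            return
        try:
            outputs = fn()
        except Exception as exc:  # tag failures with the stage
            raise StageError(name, exc) from exc
        manifest.record(name, run_dir, outputs)

    run_stage("simulate", lambda: stage_simulate(run_dir, config))
    run_stage("segment", lambda: stage_segment(run_dir))
    run_stage("boundaries", lambda: stage_boundaries(run_dir, n_perm=n_perm,
                                                     seed=config.seed + 1))
    run_stage("pairs", lambda: stage_pairs(run_dir))
    run_stage("associate", lambda: stage_associate(run_dir))
    run_stage("report", lambda: stage_report(run_dir))
    return run_dir
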