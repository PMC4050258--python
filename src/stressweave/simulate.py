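"""Synthetic data with planted ground truth for every pipeline stage.

Emulates the structure of a two-strain (WT, mutant) osmotic-stress time
course: 6 timepoints (0, 15, 30, 60, 120, 180 min) x 3 replicates of
stranded per-base coverage, a matched protein matrix with 5 technical
replicates, a GFF3 annotation with antisense-overlapping / convergent /
divergent opposite-strand gene pairs, gene-set families, and planted
effects -- UTR boundary extensions, correlated ncRNA-family modules and
antisense-excess -> protein-repression pairs -- recorded in a truth table.

Noise model: negative-binomial per-base coverage and per-feature counts,
Gaussian (log2) biological/technical noise on protein abundances, and
Gaussian per-sample jitter of transcript termini. Stress-responsive
transcripts peak transiently at 30 min; protein responses follow a lagged,
exponentially smoothed transform of the transcript profile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .genome import Annotation, Gene
from .stats import GeneFamilyCollection
from .transcription import ExpressionMatrix

TIMEPOINTS = (0, 15, 30, 60, 120, 180)
FIVE, THREE = "five_prime", "three_prime"

# transient transcript induction, peaking at 30 min, per stressed timepoint
RESPONSE_SHAPE = {15: 0.55, 30: 1.0, 60: 0.65, 120: 0.3, 180: 0.15}


@dataclass
class SimulationConfig:
    """All knobs of the generator. Defaults reproduce the study design
    (2 strains x 6 timepoints x 3 replicates; 5 protein replicates) at a
    desk scale of 200 coding genes / 60 ncRNAs on a 100 kb chromosome."""

    seed: int = 0
    n_coding: int = 200
    n_ncrna: int = 60
    chrom_length: int = 100_000
    chromosome: str = "chrI"
    timepoints: tuple[int, ...] = TIMEPOINTS
    replicates: int = 3
    protein_replicates: int = 5
    strains: tuple[str, ...] = ("WT", "mutant")
    # layout
    cds_range: tuple[int, int] = (100, 200)
    utr_range: tuple[int, int] = (20, 50)
    ncrna_length_range: tuple[int, int] = (80, 200)
    gap_range: tuple[int, int] = (150, 200)
    pair_geometry_counts: tuple[int, int, int] = (30, 15, 15)  # antisense, conv, div
    # coverage noise
    coverage_depth_mean: float = 5.0
    dispersion: float = 0.1  # NB: var = m + dispersion * m^2
    boundary_jitter_sd: float = 10.0
    # expression
    frac_responsive: float = 0.3
    response_amplitude_log2: float = 2.0
    baseline_log2_rpkm_mean: float = 11.0
    baseline_log2_rpkm_sd: float = 1.0
    count_dispersion: float = 0.05
    library_size: int = 1_000_000
    # planted effects
    n_planted_extensions: int = 10
    extension_delta_range: tuple[int, int] = (50, 60)
    extension_timepoint: int = 30
    n_planted_modules: int = 2
    module_rho: float = 0.9
    module_fraction: float = 0.8
    module_family_size: int = 50
    n_repression_pairs: int = 10
    repression_effect: float = -1.0
    # protein
    protein_lag_alpha: float = 0.5
    protein_bio_sd: float = 0.15
    protein_tech_sd: float = 0.05
    # gene sets
    n_families: int = 8
    cesr_fraction: float = 0.1
    cesr_enrichment_factor: float = 5.0

    def stressed_timepoints(self) -> list[int]:
        return [t for t in self.timepoints if t != 0]


@dataclass
class TruthTable:
    """Planted ground truth, one record per planted entity."""

    transcripts: dict[str, tuple[int, int]] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)
    extensions: list[dict] = field(default_factory=list)
    modules: list[dict] = field(default_factory=list)
    repression: list[dict] = field(default_factory=list)
    responsive: dict[str, float] = field(default_factory=dict)
    cesr: list[str] = field(default_factory=list)
    families: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draws with var = m + dispersion m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> tuple[Annotation, TruthTable]:
    """Lay out genes with the requested pair geometries on one chromosome.

    Blocks (isolated genes and pairs) are placed left to right in shuffled
    order, separated by gaps well above the segmentation merge threshold so
    that, at zero noise, called loci equal planted transcripts. Raises if
    the layout exceeds ``chrom_length``.
    """
    n_anti, n_conv, n_div = config.pair_geometry_counts
    if 2 * (n_conv + n_div) + n_anti > config.n_coding:
        raise ValueError("pair geometry counts exceed n_coding")
    if n_anti > config.n_ncrna:
        raise ValueError("antisense pair count exceeds n_ncrna")

    truth = TruthTable()
    genes: list[Gene] = []
    coding_iter = iter([f"gene{i:04d}" for i in range(1, config.n_coding + 1)])
    ncrna_iter = iter([f"ncrna{i:04d}" for i in range(1, config.n_ncrna + 1)])

    def draw(rg):
        return int(rng.integers(rg[0], rg[1] + 1))

    def new_coding(start: int, strand: str) -> Gene:
        u5, u3 = draw(config.utr_range), draw(config.utr_range)
        cds = draw(config.cds_range)
        gid = next(coding_iter)
        g = Gene(gid, config.chromosome, start, start + u5 + cds + u3, strand,
                 "coding", cds_start=start + u5, cds_end=start + u5 + cds)
        truth.transcripts[gid] = (g.start, g.end)
        return g

    def new_ncrna(start: int, strand: str, length: int | None = None) -> Gene:
        length = length or draw(config.ncrna_length_range)
        gid = next(ncrna_iter)
        g = Gene(gid, config.chromosome, start, start + length, strand, "ncRNA")
        truth.transcripts[gid] = (g.start, g.end)
        return g

    # build block specs, then shuffle their order
    blocks = (["antisense"] * n_anti + ["convergent"] * n_conv + ["divergent"] * n_div
              + ["coding"] * (config.n_coding - n_anti - 2 * (n_conv + n_div))
              + ["ncrna"] * (config.n_ncrna - n_anti))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    cursor = draw(config.gap_range)
    flip = 0
    for kind in blocks:
        strand = "+" if flip % 2 == 0 else "-"
        flip += 1
        if kind == "coding":
            g = new_coding(cursor, strand)
            genes.append(g)
            cursor = g.end
        elif kind == "ncrna":
            g = new_ncrna(cursor, strand)
            genes.append(g)
            cursor = g.end
        elif kind == "antisense":
            # ncRNA antisense over the 3' half of a coding gene
            g = new_coding(cursor, "+")
            nc_len = draw(config.ncrna_length_range)
            nc_start = max(g.start + g.length // 2, g.end + 40 - nc_len)
            nc = new_ncrna(nc_start, "-", nc_len)
            genes += [g, nc]
            truth.pairs.append(dict(gene_a=g.gene_id, gene_b=nc.gene_id,
                                    geometry="antisense_overlap",
                                    pair_class="mRNA:ncRNA"))
            cursor = max(g.end, nc.end)
        elif kind in ("convergent", "divergent"):
            left_strand, right_strand = ("+", "-") if kind == "convergent" else ("-", "+")
            g1 = new_coding(cursor, left_strand)
            inner_gap = int(rng.integers(80, 151))
            g2 = new_coding(g1.end + inner_gap, right_strand)
            genes += [g1, g2]
            truth.pairs.append(dict(gene_a=g1.gene_id, gene_b=g2.gene_id,
                                    geometry=kind, pair_class="mRNA:mRNA"))
            cursor = g2.end
        cursor += draw(config.gap_range)

    if cursor > config.chrom_length:
        raise ValueError(
            f"layout needs {cursor} nt but chrom_length is {config.chrom_length}"
        )
    annotation = Annotation(genes, {config.chromosome: config.chrom_length})
    return annotation, truth


# ---------------------------------------------------------------------------
# planted-effect planning


def plan_truth(config: SimulationConfig, annotation: Annotation,
               truth: TruthTable, rng: np.random.Generator) -> TruthTable:
    """Choose which genes carry each planted effect and record it.

    Extension genes are isolated coding genes (no pair membership, so the
    extension cannot create spurious pair geometry); module ncRNAs are
    non-antisense ncRNAs; repression pairs are the first mRNA:ncRNA
    antisense pairs; remaining antisense pairs act as sense-exceeds
    controls. Stress-responsive features are drawn from the rest.
    """
    paired = {g for p in truth.pairs for g in (p["gene_a"], p["gene_b"])}
    iso_coding = [g for g in annotation.coding_ids() if g not in paired]
    iso_nc = [g for g in annotation.ncrna_ids() if g not in paired]

    # boundary extensions
    ext_genes = list(rng.choice(iso_coding, size=min(config.n_planted_extensions,
                                                     len(iso_coding)), replace=False))
    lo, hi = config.extension_delta_range
    for i, gene in enumerate(sorted(ext_genes)):
        truth.extensions.append(dict(
            gene=gene, end=THREE if i % 2 == 0 else FIVE,
            timepoint=int(config.extension_timepoint),
            delta=int(rng.integers(lo, hi + 1)),
        ))

    # modules: ncRNA correlated with a dedicated gene family
    mod_nc = [g for g in iso_nc][: config.n_planted_modules]
    remaining_coding = [g for g in annotation.coding_ids()
                        if g not in set(ext_genes)]
    used: set[str] = set()
    for i, nc in enumerate(mod_nc):
        pool = [g for g in remaining_coding if g not in used]
        fam = sorted(rng.choice(pool, size=min(config.module_family_size, len(pool)),
                                replace=False))
        used |= set(fam)
        n_in = int(round(config.module_fraction * len(fam)))
        members = sorted(rng.choice(fam, size=n_in, replace=False))
        name = f"module_family_{i + 1}"
        truth.families[name] = fam
        truth.modules.append(dict(ncrna=nc, family=name, rho_target=config.module_rho,
                                  members=members))

    # repression pairs among antisense mRNA:ncRNA pairs
    anti = [p for p in truth.pairs if p["geometry"] == "antisense_overlap"]
    for i, p in enumerate(anti):
        kind = "repression" if i < config.n_repression_pairs else "control"
        truth.repression.append(dict(
            coding=p["gene_a"], ncrna=p["gene_b"], kind=kind,
            effect=config.repression_effect if kind == "repression" else 0.0,
        ))

    # stress-responsive features (transient peak at 30 min)
    special = (set(ext_genes) | used | set(mod_nc)
               | {r["coding"] for r in truth.repression}
               | {r["ncrna"] for r in truth.repression})
    eligible = [g.gene_id for g in annotation if g.gene_id not in special]
    n_resp = int(round(config.frac_responsive * len(eligible)))
    for gid in sorted(rng.choice(eligible, size=n_resp, replace=False)):
        sign = 1.0 if rng.random() < 0.8 else -1.0
        truth.responsive[gid] = float(sign * config.response_amplitude_log2
                                      * (0.5 + rng.random()))
    # antisense partners of repression pairs respond strongly (drives dosage flip)
    for r in truth.repression:
        if r["kind"] == "repression":
            truth.responsive[r["ncrna"]] = 3.5
    return truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(config: SimulationConfig, annotation: Annotation,
                       truth: TruthTable, rng: np.random.Generator) -> GeneFamilyCollection:
    """Gene families over the coding universe: the planted module families,
    random background families, and a CESR set enriched (by
    ``cesr_enrichment_factor``) among genes opposite responsive antisense."""
    universe = frozenset(annotation.coding_ids())
    families: dict[str, frozenset[str]] = {
        name: frozenset(members) for name, members in truth.families.items()
    }
    pool = sorted(universe)
    n_back = max(0, config.n_families - len(families))
    for i in range(n_back):
        size = int(rng.integers(15, 41))
        families[f"family_{i + 1:02d}"] = frozenset(
            rng.choice(pool, size=min(size, len(pool)), replace=False)
        )

    anti_coding = {r["coding"] for r in truth.repression}
    base_p = config.cesr_fraction
    boosted = min(1.0, base_p * config.cesr_enrichment_factor)
    cesr = [g for g in pool
            if rng.random() < (boosted if g in anti_coding else base_p)]
    families["CESR"] = frozenset(cesr)
    truth.cesr = sorted(cesr)
    truth.families = {n: sorted(m) for n, m in families.items()}
    return GeneFamilyCollection(families=families, universe=universe)


# ---------------------------------------------------------------------------
# expression profiles


def simulate_expression_profiles(
    config: SimulationConfig, annotation: Annotation, truth: TruthTable,
    rng: np.random.Generator,
) -> dict:
    """Per-strain true log2 fold-change profiles and baseline RPKM.

    Responsive features follow the transient peak-at-30-min shape scaled by
    their amplitude. Module ncRNAs get a standardized latent profile over
    the stressed timepoints; in-module genes mix that latent with
    independent noise (weights rho, sqrt(1-rho^2)) so the expected
    correlation with the ncRNA hits the target. Repression-pair ncRNAs are
    strongly induced over a depressed baseline so antisense RPKM exceeds
    sense at every stressed timepoint; their sense members stay flat (the
    protein effect is then attributable to the planted repression alone).

    Returns {"log2fc": {strain: feature x timepoint DataFrame},
             "baseline_rpkm": Series}.
    """
    feats = sorted(g.gene_id for g in annotation)
    tps = list(config.timepoints)
    stress = config.stressed_timepoints()
    base = pd.Series(
        2.0 ** rng.normal(config.baseline_log2_rpkm_mean,
                          config.baseline_log2_rpkm_sd, len(feats)),
        index=feats, name="baseline_rpkm",
    )
    # dosage-pair baselines: control ncRNA low, repression ncRNA moderate
    for r in truth.repression:
        base[r["coding"]] = 2.0 ** config.baseline_log2_rpkm_mean  # fixed, mid-scale
        base[r["ncrna"]] = base[r["coding"]] * (0.3 if r["kind"] == "repression" else 0.05)

    shape = np.array([RESPONSE_SHAPE[t] for t in stress])
    flat_sense = {r["coding"] for r in truth.repression}
    rep_nc = {r["ncrna"] for r in truth.repression if r["kind"] == "repression"}

    log2fc: dict[str, pd.DataFrame] = {}
    for strain in config.strains:
        mat = pd.DataFrame(0.0, index=pd.Index(feats, name="feature"), columns=tps)
        for gid, amp in truth.responsive.items():
            if gid in flat_sense:
                continue
            if gid in rep_nc:
                mat.loc[gid, stress] = amp  # sustained induction
            else:
                mat.loc[gid, stress] = amp * shape
        # planted modules: shared latent over stressed timepoints
        for mod in truth.modules:
            z = rng.standard_normal(len(stress))
            z = (z - z.mean()) / z.std()
            amp = 1.5
            mat.loc[mod["ncrna"], stress] = amp * z
            rho = mod["rho_target"]
            for g in mod["members"]:
                eps = rng.standard_normal(len(stress))
                eps = (eps - eps.mean()) / eps.std()
                mat.loc[g, stress] = amp * (rho * z + np.sqrt(1 - rho ** 2) * eps)
        log2fc[strain] = mat
    return dict(log2fc=log2fc, baseline_rpkm=base)


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for strain in config.strains:
        for t in config.timepoints:
            for r in range(1, config.replicates + 1):
                rows.append(dict(sample=f"{strain}_t{t:03d}_r{r}",
                                 strain=strain, timepoint=t, replicate=r))
    return pd.DataFrame(rows).set_index("sample")


def simulate_expression_matrix(
    config: SimulationConfig, annotation: Annotation, profiles: dict,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Replicate-level counts/RPKM drawn around the true profiles.

    Expected counts follow the RPKM identity at the configured library
    size; observed counts are negative-binomial around them, RPKM is then
    recomputed from the observed counts so the two stay consistent.
    """
    samples = sample_sheet(config)
    feats = sorted(g.gene_id for g in annotation)
    lengths = pd.Series({g.gene_id: (g.cds_length if g.biotype == "coding" else g.length)
                         for g in annotation}).loc[feats]
    base = profiles["baseline_rpkm"].loc[feats]
    counts = {}
    for sample, meta in samples.iterrows():
        lfc = profiles["log2fc"][meta["strain"]][meta["timepoint"]].loc[feats]
        rpkm_true = base * 2.0 ** lfc
        expected = rpkm_true * (lengths / 1_000) * (config.library_size / 1_000_000)
        counts[sample] = _nb_draw(rng, expected.to_numpy(), config.count_dispersion)
    counts = pd.DataFrame(counts, index=pd.Index(feats, name="feature"))
    rpkm = counts.div(lengths / 1_000, axis=0) / (config.library_size / 1_000_000)
    return ExpressionMatrix(counts=counts, rpkm=rpkm,
                            feature_lengths=lengths, samples=samples)


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(
    config: SimulationConfig, annotation: Annotation, truth: TruthTable,
    profiles: dict, rng: np.random.Generator,
) -> tuple[dict[str, dict[tuple[str, str], np.ndarray]], dict[str, int]]:
    """Stranded per-base coverage per sample, with planted extensions.

    Each transcript contributes negative-binomial depth over its span,
    with per-sample Gaussian jitter of both termini (biological boundary
    variation) and, for planted (gene, end, timepoint) extensions, the
    configured extra delta at every replicate of that timepoint. Inter-gene
    baseline depth is zero. Returns (tracks_by_sample, library_sizes)
    where a track key is (chromosome, strand).
    """
    samples = sample_sheet(config)
    chrom, L = config.chromosome, config.chrom_length
    ext_lookup = {(e["gene"], e["end"], e["timepoint"]): e["delta"]
                  for e in truth.extensions}
    tracks: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    lib: dict[str, int] = {}
    for sample, meta in samples.iterrows():
        strain, tp = meta["strain"], int(meta["timepoint"])
        depth = {(chrom, "+"): np.zeros(L, dtype=np.int64),
                 (chrom, "-"): np.zeros(L, dtype=np.int64)}
        lfc = profiles["log2fc"][strain][tp]
        scale = profiles["baseline_rpkm"] * 2.0 ** lfc
        scale = scale / scale.mean()
        for g in annotation:
            start, end = g.start, g.end
            j5 = int(round(rng.normal(0, config.boundary_jitter_sd)))
            j3 = int(round(rng.normal(0, config.boundary_jitter_sd)))
            d5 = ext_lookup.get((g.gene_id, FIVE, tp), 0)
            d3 = ext_lookup.get((g.gene_id, THREE, tp), 0)
            if g.strand == "+":
                start = start - j5 - d5
                end = end + j3 + d3
            else:
                start = start - j3 - d3
                end = end + j5 + d5
            if g.biotype == "coding":  # terminus never retreats past the CDS
                start = min(start, g.cds_start)
                end = max(end, g.cds_end)
            start, end = max(0, start), min(L, end)
            m = config.coverage_depth_mean * float(scale[g.gene_id])
            depth[(chrom, g.strand)][start:end] += _nb_draw(
                rng, np.full(end - start, m), config.dispersion
            )
        tracks[sample] = depth
        lib[sample] = int(sum(d.sum() for d in depth.values()))
    return tracks, lib


# ---------------------------------------------------------------------------
# protein


def _lagged_smooth(lfc: np.ndarray, alpha: float) -> np.ndarray:
    """One-step-lagged exponential smoothing: delayed, persistent response."""
    out = np.zeros_like(lfc)
    for i in range(1, lfc.size):
        out[i] = alpha * out[i - 1] + (1 - alpha) * lfc[i - 1]
    return out


def simulate_protein(
    config: SimulationConfig, annotation: Annotation, truth: TruthTable,
    profiles: dict, rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein abundances for all coding genes.

    The true protein log2FC is a lagged, smoothed transform of the
    transcript log2FC; repression-pair coding genes additionally receive
    the planted negative effect at every stressed timepoint (where their
    antisense is in excess by construction). Technical replicates share one
    biological draw per (protein, strain, timepoint).

    Returns (abundance matrix protein x sample, protein sample sheet).
    """
    coding = sorted(annotation.coding_ids())
    tps = list(config.timepoints)
    rows = []
    for strain in config.strains:
        for t in tps:
            for r in range(1, config.protein_replicates + 1):
                rows.append(dict(sample=f"{strain}_t{t:03d}_p{r}",
                                 strain=strain, timepoint=t, replicate=r))
    psamples = pd.DataFrame(rows).set_index("sample")
    base = pd.Series(2.0 ** rng.normal(10, 1, len(coding)), index=coding)
    effect = {r["coding"]: r["effect"] for r in truth.repression}

    cols = {}
    for strain in config.strains:
        lfc = profiles["log2fc"][strain].loc[coding, tps].to_numpy()
        true = np.vstack([_lagged_smooth(row, config.protein_lag_alpha) for row in lfc])
        for gi, g in enumerate(coding):
            if g in effect and effect[g] != 0.0:
                true[gi, 1:] += effect[g]
        bio = rng.normal(0, config.protein_bio_sd, true.shape)
        for ti, t in enumerate(tps):
            mean_log2 = np.log2(base.to_numpy()) + true[:, ti] + bio[:, ti]
            for r in range(1, config.protein_replicates + 1):
                tech = rng.normal(0, config.protein_tech_sd, len(coding))
                cols[f"{strain}_t{t:03d}_p{r}"] = 2.0 ** (mean_log2 + tech)
    protein = pd.DataFrame(cols, index=pd.Index(coding, name="protein"))
    return protein[list(psamples.index)], psamples


# ---------------------------------------------------------------------------
# direct extent tables (for permutation-test calibration and power studies)


def simulate_extent_table(
    n_genes: int,
    config: SimulationConfig | None = None,
    planted: list[dict] | None = None,
    extent_sd: float = 10.0,
    rng: np.random.Generator | None = None,
    strains: tuple[str, ...] = ("WT",),
) -> pd.DataFrame:
    """Boundary-extent long table drawn directly from the noise model.

    Each (gene, end) has a latent mean extent; every sample observes it
    plus Gaussian noise (sd ``extent_sd``), exchangeable across the time
    course unless a planted record (gene/end/timepoint/delta) shifts it.
    Bypasses coverage simulation for fast, tie-free permutation studies.
    """
    cfg = config or SimulationConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    planted_lookup = {(p["gene"], p["end"], p["timepoint"]): p["delta"]
                      for p in (planted or [])}
    rows = []
    for i in range(1, n_genes + 1):
        gene = f"gene{i:04d}"
        for end in (FIVE, THREE):
            mu = float(rng.uniform(40, 150))
            for strain in strains:
                for t in cfg.timepoints:
                    delta = planted_lookup.get((gene, end, t), 0.0)
                    for r in range(1, cfg.replicates + 1):
                        rows.append(dict(
                            gene=gene, end=end, strain=strain, timepoint=int(t),
                            replicate=r, sample=f"{strain}_t{t:03d}_r{r}",
                            extent=max(0.0, mu + delta + float(rng.normal(0, extent_sd))),
                            multi_orf=False,
                        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: Annotation
    truth: TruthTable
    families: GeneFamilyCollection
    profiles: dict
    expression: ExpressionMatrix
    protein: pd.DataFrame
    protein_samples: pd.DataFrame
    tracks: dict[str, dict[tuple[str, str], np.ndarray]] | None = None
    library_sizes: dict[str, int] | None = None

    def de_flags(self) -> pd.DataFrame:
        """DE-flag table from truth: feature, strain, significant, max |log2FC|."""
        rows = []
        for strain in self.config.strains:
            lfc = self.profiles["log2fc"][strain]
            for gid in lfc.index:
                m = float(lfc.loc[gid].abs().max())
                rows.append(dict(feature=gid, strain=strain,
                                 significant=bool(m > 0), max_abs_log2fc=m))
        return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig, with_coverage: bool = False) -> SimulatedDataset:
    """Run the whole generator under one seed; fully deterministic."""
    rng = np.random.default_rng(config.seed)
    annotation, truth = simulate_annotation(config, rng)
    truth = plan_truth(config, annotation, truth, rng)
    families = simulate_gene_sets(config, annotation, truth, rng)
    profiles = simulate_expression_profiles(config, annotation, truth, rng)
    expression = simulate_expression_matrix(config, annotation, profiles, rng)
    protein, psamples = simulate_protein(config, annotation, truth, profiles, rng)
    tracks = lib = None
    if with_coverage:
        tracks, lib = simulate_coverage(config, annotation, truth, profiles, rng)
    return SimulatedDataset(
        config=config, annotation=annotation, truth=truth, families=families,
        profiles=profiles, expression=expression, protein=protein,
        protein_samples=psamples, tracks=tracks, library_sizes=lib,
    )
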