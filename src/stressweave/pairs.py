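"""Sense-antisense and adjacent gene-pair analysis.

Discovers opposite-strand gene pairs from annotation (optionally with
re-mapped transcript boundaries enlarging the spans), classifies their
geometry (antisense overlap, convergent, divergent), correlates paired
time-course expression profiles, and tests whether loci where antisense
transcription exceeds sense show reduced protein levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genome import Annotation, Gene
from .stats import (
    EnrichmentResult,
    GeneFamilyCollection,
    ZeroVarianceError,
    enrichment_table,
    hierarchical_cluster,
    hypergeometric_overrep,
    pearson_correlation,
    two_group_ttest,
)
from .transcription import ExpressionMatrix

ANTISENSE, CONVERGENT, DIVERGENT = "antisense_overlap", "convergent", "divergent"

PAIR_COLUMNS = ["gene_a", "gene_b", "geometry", "overlap_bp", "pair_class",
                "from_convergent", "contains_cesr"]


def _extended_span(
    gene: Gene, extensions: Mapping[tuple[str, str], float] | None
) -> tuple[int, int]:
    """Transcript span enlarged by re-mapped boundary extensions (nt)."""
    start, end = gene.start, gene.end
    if extensions:
        e5 = extensions.get((gene.gene_id, "five_prime"), 0)
        e3 = extensions.get((gene.gene_id, "three_prime"), 0)
        if gene.strand == "+":
            start -= int(max(0, e5))
            end += int(max(0, e3))
        else:
            start -= int(max(0, e3))
            end += int(max(0, e5))
    return max(0, start), end


def _pair_class(a: Gene, b: Gene) -> str:
    kinds = sorted(("mRNA" if g.biotype == "coding" else "ncRNA") for g in (a, b))
    return f"{kinds[0]}:{kinds[1]}"


def find_pairs(
    annotation: Annotation,
    boundary_extensions: Mapping[tuple[str, str], float] | None = None,
    max_gap: int = 1_000,
    cesr_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Discover opposite-strand gene pairs and classify their geometry.

    Pairs whose (optionally extended) transcript spans overlap by >= 1 bp
    are ``antisense_overlap`` with the per-base overlap recorded; pairs that
    were convergent by annotation but overlap only after boundary extension
    carry ``from_convergent=True``. Non-overlapping opposite-strand
    neighbours within ``max_gap`` nt are ``convergent`` (3' ends facing) or
    ``divergent`` (5' ends facing). ``gene_a`` is always the leftmost
    member. ``contains_cesr`` flags pairs with a member in ``cesr_set``.
    """
    cesr = set(cesr_set or ())
    rows = []
    seen: set[tuple[str, str]] = set()
    for chrom in annotation.chromosomes:
        plus = annotation.on_strand(chrom, "+")
        minus = annotation.on_strand(chrom, "-")
        if not plus or not minus:
            continue
        # overlap pass (on extended spans)
        spans_minus = [(g, *_extended_span(g, boundary_extensions)) for g in minus]
        for ga in plus:
            a_lo, a_hi = _extended_span(ga, boundary_extensions)
            for gb, b_lo, b_hi in spans_minus:
                ov = min(a_hi, b_hi) - max(a_lo, b_lo)
                if ov >= 1:
                    left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
                    annotated_overlap = min(ga.end, gb.end) - max(ga.start, gb.start)
                    from_conv = annotated_overlap < 1 and left.strand == "+"
                    rows.append(
                        dict(
                            gene_a=left.gene_id, gene_b=right.gene_id,
                            geometry=ANTISENSE, overlap_bp=int(ov),
                            pair_class=_pair_class(ga, gb),
                            from_convergent=bool(from_conv),
                            contains_cesr=bool(cesr & {ga.gene_id, gb.gene_id}),
                        )
                    )
                    seen.add((left.gene_id, right.gene_id))
        # adjacency pass: nearest opposite-strand neighbour, annotated spans
        everything = sorted(plus + minus, key=lambda g: (g.start, g.end))
        for i, left in enumerate(everything):
            for right in everything[i + 1:]:
                if right.start - left.end > max_gap:
                    break
                if right.strand == left.strand:
                    continue
                gap = right.start - left.end
                if gap < 1:  # overlapping: handled above
                    continue
                key = (left.gene_id, right.gene_id)
                if key in seen:
                    continue
                geometry = CONVERGENT if left.strand == "+" else DIVERGENT
                rows.append(
                    dict(
                        gene_a=left.gene_id, gene_b=right.gene_id,
                        geometry=geometry, overlap_bp=0,
                        pair_class=_pair_class(left, right),
                        from_convergent=False,
                        contains_cesr=bool(cesr & {left.gene_id, right.gene_id}),
                    )
                )
                seen.add(key)
                break  # only the nearest opposite-strand neighbour
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.sort_values(["gene_a", "gene_b"], ignore_index=True)


def correlate_pair_profiles(
    pairs: pd.DataFrame,
    expression: ExpressionMatrix,
    strains: Sequence[str],
    expression_floor_log2: float = 2.0,
    pseudocount: float = 1.0,
    n_clusters: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of paired log2FC time-course profiles.

    Profiles of the two members are correlated over the concatenated
    per-strain time courses. Pairs where a member fails the expression
    floor (mean log2 RPKM below ``expression_floor_log2`` in every strain
    course) or has a zero-variance profile are excluded with a reason.
    Surviving pairs are clustered (complete linkage on the joined member
    profiles) into ``n_clusters`` groups.

    Returns (correlations, exclusions).
    """
    members = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    members = [m for m in members if m in expression.rpkm.index]
    floor_pass: dict[str, bool] = {}
    prof: dict[str, np.ndarray] = {}
    profiles_by_strain = {
        s: expression.log2fc_profiles(members, s, pseudocount) for s in strains
    }
    with np.errstate(divide="ignore"):
        for m in members:
            ok = False
            for s in strains:
                vals = expression.rpkm.loc[m, expression.strain_samples(s)]
                mean_log2 = np.log2(vals.mean()) if vals.mean() > 0 else -np.inf
                ok = ok or mean_log2 >= expression_floor_log2
            floor_pass[m] = ok
            prof[m] = np.concatenate(
                [profiles_by_strain[s].loc[m].to_numpy() for s in strains]
            )

    rows, excl = [], []
    for _, p in pairs.iterrows():
        a, b = p["gene_a"], p["gene_b"]
        if a not in prof or b not in prof:
            excl.append(dict(gene_a=a, gene_b=b, reason="not_quantified"))
            continue
        if not (floor_pass[a] and floor_pass[b]):
            excl.append(dict(gene_a=a, gene_b=b, reason="below_expression_floor"))
            continue
        try:
            rho = pearson_correlation(prof[a], prof[b])
        except ZeroVarianceError:
            excl.append(dict(gene_a=a, gene_b=b, reason="zero_variance_profile"))
            continue
        rows.append(dict(gene_a=a, gene_b=b, geometry=p["geometry"], rho=rho))
    cors = pd.DataFrame(rows, columns=["gene_a", "gene_b", "geometry", "rho"])
    if len(cors) >= 2:
        mat = np.vstack(
            [np.concatenate([prof[a], prof[b]]) for a, b in zip(cors["gene_a"], cors["gene_b"])]
        )
        _, tree = hierarchical_cluster(mat)
        cors["cluster_id"] = hierarchy.fcluster(
            tree, t=min(n_clusters, len(cors)), criterion="maxclust"
        )
    else:
        cors["cluster_id"] = 1 if len(cors) else pd.Series(dtype=int)
    return cors, pd.DataFrame(excl, columns=["gene_a", "gene_b", "reason"])


def cesr_overlap_enrichment(
    opposite_genes: Iterable[str], cesr_set: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Over-representation of CESR genes among genes opposite responsive
    antisense transcripts (hypergeometric upper tail)."""
    uni = set(universe)
    sel = set(opposite_genes) & uni
    fam = set(cesr_set) & uni
    k = len(sel & fam)
    p = hypergeometric_overrep(k, len(sel), len(fam), len(uni))
    return EnrichmentResult(
        family="CESR", overlap=k, selected_size=len(sel),
        family_size=len(fam), universe_size=len(uni), p_value=p,
    )


SENSE_EXCEEDS, ANTISENSE_EXCEEDS = "sense_exceeds", "antisense_exceeds"


def dosage_vs_protein(
    pairs: pd.DataFrame,
    annotation: Annotation,
    expression: ExpressionMatrix,
    protein: pd.DataFrame,
    protein_samples: pd.DataFrame,
    strain: str,
    families: GeneFamilyCollection | None = None,
    per_pair_aggregate: bool = False,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Antisense dosage versus protein-level change.

    For every mRNA:ncRNA antisense pair whose coding member has protein
    data, each stressed timepoint is assigned to ``sense_exceeds`` or
    ``antisense_exceeds`` by comparing replicate-mean RPKM of the coding
    (sense) and non-coding (antisense) members; ties are excluded. The
    protein log2 fold change of the coding member at the matching timepoint
    (replicate-mean abundance relative to t=0) is collected per group and
    the groups compared with a two-sided Welch t-test. With
    ``per_pair_aggregate`` the comparison uses one mean value per pair
    instead of one per (pair, timepoint).

    Returns (assignments, t-test summary dict, per-family enrichment of
    antisense-exceeds coding genes — empty without ``families``).
    """
    prot_cols = protein_samples[protein_samples["strain"] == strain]
    if prot_cols.empty:
        raise ValueError(f"no protein samples for strain {strain!r}")
    tps = sorted(t for t in prot_cols["timepoint"].unique())
    if 0 not in tps:
        raise ValueError("protein matrix lacks t=0 samples")
    prot_mean = {
        t: protein[list(prot_cols[prot_cols["timepoint"] == t].index)].mean(axis=1)
        for t in tps
    }
    stress_tps = [t for t in tps if t != 0]

    rows, skipped = [], []
    anti_pairs = pairs[(pairs["geometry"] == ANTISENSE) & (pairs["pair_class"] == "mRNA:ncRNA")]
    for _, p in anti_pairs.iterrows():
        a, b = p["gene_a"], p["gene_b"]
        coding, nc = (a, b) if annotation[a].biotype == "coding" else (b, a)
        if coding not in protein.index:
            skipped.append(dict(pair=f"{a}|{b}", reason="no_protein"))
            continue
        if coding not in expression.rpkm.index or nc not in expression.rpkm.index:
            skipped.append(dict(pair=f"{a}|{b}", reason="not_quantified"))
            continue
        base = prot_mean[0].loc[coding]
        for t in stress_tps:
            sense = expression.mean_rpkm(coding, strain, t)
            anti = expression.mean_rpkm(nc, strain, t)
            if sense == anti:
                continue  # tie: excluded from both groups
            group = SENSE_EXCEEDS if sense > anti else ANTISENSE_EXCEEDS
            if base <= 0 or prot_mean[t].loc[coding] <= 0:
                skipped.append(dict(pair=f"{a}|{b}", reason="nonpositive_abundance"))
                continue
            rows.append(
                dict(
                    pair=f"{a}|{b}", coding_gene=coding, ncrna=nc, timepoint=int(t),
                    group=group,
                    protein_log2fc=float(np.log2(prot_mean[t].loc[coding] / base)),
                )
            )
    assign = pd.DataFrame(
        rows, columns=["pair", "coding_gene", "ncrna", "timepoint", "group", "protein_log2fc"]
    )

    if per_pair_aggregate and len(assign):
        work = (
            assign.groupby(["pair", "coding_gene", "group"], as_index=False)["protein_log2fc"]
            .mean()
        )
    else:
        work = assign
    ga = work.loc[work["group"] == ANTISENSE_EXCEEDS, "protein_log2fc"].to_numpy()
    gs = work.loc[work["group"] == SENSE_EXCEEDS, "protein_log2fc"].to_numpy()
    summary: dict = dict(
        n_antisense_exceeds=int(ga.size), n_sense_exceeds=int(gs.size),
        mean_antisense_exceeds=float(ga.mean()) if ga.size else float("nan"),
        mean_sense_exceeds=float(gs.mean()) if gs.size else float("nan"),
    )
    if ga.size >= 2 and gs.size >= 2:
        t_stat, p = two_group_ttest(ga, gs)
        summary.update(t_statistic=t_stat, p_value=p,
                       mean_difference=float(ga.mean() - gs.mean()))
    else:
        summary.update(t_statistic=float("nan"), p_value=float("nan"),
                       mean_difference=float("nan"))

    fam_table = pd.DataFrame()
    if families is not None and len(assign):
        universe = sorted(set(assign["coding_gene"]) & families.universe)
        selected = sorted(
            set(assign.loc[assign["group"] == ANTISENSE_EXCEEDS, "coding_gene"]) & set(universe)
        )
        results = []
        for name in sorted(families.families):
            fam = families.families[name] & set(universe)
            k = len(fam & set(selected))
            pv = hypergeometric_overrep(k, len(selected), len(fam), len(universe))
            results.append(
                EnrichmentResult(family=name, overlap=k, selected_size=len(selected),
                                 family_size=len(fam), universe_size=len(universe),
                                 p_value=pv)
            )
        fam_table = enrichment_table(results)
    return assign, summary, fam_table


def convergent_divergent_correlation_summary(
    correlations: pd.DataFrame,
    cesr_set: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation distributions stratified by geometry and CESR membership.

    Strata partition the correlated pairs (geometry x whether a member is a
    CESR gene). Returns (long per-pair table, per-stratum summary with
    counts and median rho).
    """
    cesr = set(cesr_set)
    merged = correlations.copy()
    if not len(merged):
        merged["contains_cesr"] = pd.Series(dtype=bool)
        return merged, pd.DataFrame(columns=["geometry", "contains_cesr", "n", "median_rho"])
    merged["contains_cesr"] = [
        bool(cesr & {a, b}) for a, b in zip(merged["gene_a"], merged["gene_b"])
    ]
    summary = (
        merged.groupby(["geometry", "contains_cesr"])["rho"]
        .agg(n="size", median_rho="median")
        .reset_index()
    )
    return merged, summary
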