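"""Boundary dynamics: per-sample 5'/3' transcript extents and the
permutation test for systematic stress-induced boundary change.

The extent of a boundary is the distance (nt) from the transcript terminus
observed in a sample to the CDS edge. For each eligible (gene, end) the
observed change at a stress timepoint is the mean replicate extent minus the
mean t=0 extent of the same time course; significance comes from randomly
relabelling the samples of the whole course (empirical p = proportion of
permutations with an at-least-as-large change, one-sided toward
elongation). A call is significant when the extent changed by at least
``min_delta`` nt (default 30) in every present replicate AND empirical
p < 0.05; BH FDR across all tests is reported alongside, not used as a gate.
The descriptive null range L = [mean(y) - 2 sd, mean(y) + 2 sd] over pooled
t=0 extents is attached as a beyond-L flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Annotation
from .stats import bh_fdr, permuted_group_mean_diffs
from .transcription import ExpressionMatrix, TranscribedLocus

FIVE, THREE = "five_prime", "three_prime"
ENDS = (FIVE, THREE)

EXTENT_COLUMNS = ["gene", "end", "strain", "timepoint", "replicate", "sample",
                  "extent", "multi_orf"]


@dataclass(frozen=True)
class BoundaryNullRange:
    """Expected variation range L of a boundary at t=0."""

    gene: str
    end: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")

    def contains(self, extent: float) -> bool:
        return self.lower <= extent <= self.upper


def null_range(gene: str, end: str, extents_t0: Sequence[float]) -> BoundaryNullRange:
    """L = [mean - 2 sd, mean + 2 sd] over pooled t=0 extents (ddof=1).

    The lower bound is clamped at 0 (an extent cannot be negative).
    Fewer than two pooled values leave the range undefined (ValueError).
    """
    y = np.asarray(extents_t0, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 pooled t=0 extents for L")
    mean, sd = y.mean(), y.std(ddof=1)
    return BoundaryNullRange(gene, end, max(0.0, mean - 2 * sd), mean + 2 * sd)


def estimate_extents(
    loci_by_sample: Mapping[str, Sequence[TranscribedLocus]],
    annotation: Annotation,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene per-sample boundary extents from labelled loci.

    For each coding gene and sample, the same-strand locus overlapping the
    gene's CDS (the one covering most of it, if coverage gaps split the
    locus) defines the observed transcript termini:
    extent_5 = CDS_start - locus_start and extent_3 = locus_end - CDS_end on
    the + strand, swapped on the - strand, clamped at 0. Extents are missing
    (no row) when no locus covers the CDS. Loci labelled with more than one
    coding gene mark the gene/sample as ``multi_orf`` (filtered later).
    """
    rows = []
    coding = [annotation[g] for g in annotation.coding_ids()]
    for sample, loci in loci_by_sample.items():
        meta = samples.loc[sample]
        by_key: dict[tuple[str, str], list[TranscribedLocus]] = {}
        for loc in loci:
            by_key.setdefault((loc.chromosome, loc.strand), []).append(loc)
        for gene in coding:
            cands = [
                loc
                for loc in by_key.get((gene.chromosome, gene.strand), [])
                if loc.start < gene.cds_end and gene.cds_start < loc.end
            ]
            if not cands:
                continue
            best = max(
                cands,
                key=lambda l: min(l.end, gene.cds_end) - max(l.start, gene.cds_start),
            )
            n_orfs = sum(1 for lab in best.labels if annotation[lab].biotype == "coding")
            multi = n_orfs > 1
            left = max(0, gene.cds_start - best.start)
            right = max(0, best.end - gene.cds_end)
            ext5, ext3 = (left, right) if gene.strand == "+" else (right, left)
            for end, ext in ((FIVE, ext5), (THREE, ext3)):
                rows.append(
                    dict(
                        gene=gene.gene_id,
                        end=end,
                        strain=meta["strain"],
                        timepoint=int(meta["timepoint"]),
                        replicate=int(meta["replicate"]),
                        sample=sample,
                        extent=float(ext),
                        multi_orf=multi,
                    )
                )
    return pd.DataFrame(rows, columns=EXTENT_COLUMNS)


def filter_boundary_genes(
    extents: pd.DataFrame,
    expression: ExpressionMatrix,
    min_log2_rpkm: float = 2.0,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility filters and return (kept extents, removal log).

    Removed are (1) gene/samples whose locus spans multiple ORFs, (2) genes
    whose mean CDS expression (log2 RPKM) is below ``min_log2_rpkm``, and
    (3) gene/end/strain/timepoints with fewer than ``min_replicates``
    present replicates.
    """
    reasons = []
    df = extents.copy()

    multi = df["multi_orf"]
    for gene in sorted(df.loc[multi, "gene"].unique()):
        reasons.append(dict(gene=gene, reason="multi_orf"))
    df = df[~multi]

    genes = sorted(df["gene"].unique())
    if genes:
        with np.errstate(divide="ignore"):
            mean_log2 = np.log2(expression.rpkm.loc[genes]).replace(-np.inf, np.nan)
        low = mean_log2.mean(axis=1, skipna=True) < min_log2_rpkm
        low |= mean_log2.isna().all(axis=1)
        for gene in mean_log2.index[low]:
            reasons.append(dict(gene=gene, reason="low_expression"))
        df = df[~df["gene"].isin(set(mean_log2.index[low]))]

    counts = df.groupby(["gene", "end", "strain", "timepoint"])["replicate"].size()
    bad = counts[counts < min_replicates]
    if len(bad):
        bad_idx = set(bad.index)
        key = list(zip(df["gene"], df["end"], df["strain"], df["timepoint"]))
        keep = [k not in bad_idx for k in key]
        for g, e, s, t in sorted(bad_idx):
            reasons.append(dict(gene=g, reason=f"insufficient_replicates:{e}:{s}:{t}"))
        df = df[keep]

    return df.reset_index(drop=True), pd.DataFrame(reasons, columns=["gene", "reason"])


def boundary_change_test(
    extents: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    min_delta: float = 30.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test for boundary change at each stress timepoint.

    ``extents`` is a filtered long table (columns as in EXTENT_COLUMNS).
    Each (gene, end, strain) course is tested at every stress timepoint with
    >= 1 present replicate, provided t=0 extents exist. Returns one row per
    test with observed delta, per-replicate deltas, empirical p (one-sided
    toward elongation), beyond-L flag, BH FDR over all tests and the final
    significance call (|replicate delta| >= min_delta with consistent
    positive sign in all present replicates AND p < alpha).
    """
    if extents.empty:
        return pd.DataFrame(
            columns=["gene", "end", "strain", "timepoint", "delta", "min_rep_delta",
                     "n_replicates", "empirical_p", "beyond_L", "fdr", "significant"]
        )
    rng = np.random.default_rng(seed)
    rows = []
    # L uses t=0 extents pooled across strains
    pooled_t0 = extents[extents["timepoint"] == 0].groupby(["gene", "end"])["extent"]
    L: dict[tuple[str, str], BoundaryNullRange] = {}
    for (gene, end), vals in pooled_t0:
        if len(vals) >= 2:
            L[(gene, end)] = null_range(gene, end, vals.to_numpy())

    for (gene, end, strain), grp in extents.groupby(["gene", "end", "strain"], sort=True):
        t0 = grp.loc[grp["timepoint"] == 0, "extent"].to_numpy(dtype=float)
        if t0.size == 0:
            continue
        stress_tps = sorted(t for t in grp["timepoint"].unique() if t != 0)
        if not stress_tps:
            continue
        values = grp["extent"].to_numpy(dtype=float)
        tp_of = grp["timepoint"].to_numpy()
        group_index = np.searchsorted(np.array([0] + stress_tps), tp_of)
        # group 0 = reference (t=0); groups 1..k = stress timepoints
        perm = permuted_group_mean_diffs(
            values, group_index, reference_group=0,
            test_groups=list(range(1, len(stress_tps) + 1)),
            n_perm=n_perm, rng=rng,
        )
        base = t0.mean()
        for j, t in enumerate(stress_tps):
            reps = grp.loc[grp["timepoint"] == t, "extent"].to_numpy(dtype=float)
            delta = reps.mean() - base
            p = float((perm[:, j] >= delta).mean())
            rep_deltas = reps - base
            all_extended = bool(np.all(rep_deltas >= min_delta))
            rng_L = L.get((gene, end))
            beyond = bool(rng_L is not None and not rng_L.contains(reps.mean()))
            rows.append(
                dict(
                    gene=gene, end=end, strain=strain, timepoint=int(t),
                    delta=float(delta),
                    min_rep_delta=float(rep_deltas.min()),
                    n_replicates=int(reps.size),
                    empirical_p=p,
                    beyond_L=beyond,
                    _all_extended=all_extended,
                )
            )
    calls = pd.DataFrame(rows)
    if calls.empty:
        calls["fdr"] = []
        calls["significant"] = []
        return calls
    calls["fdr"] = bh_fdr(calls["empirical_p"].to_numpy())
    calls["significant"] = calls.pop("_all_extended") & (calls["empirical_p"] < alpha)
    return calls


def classify_direction(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition calls by sign of delta and summarise counts per end.

    Returns (calls with a ``direction`` column, summary of significant
    calls counted per end and direction over unique gene/ends).
    """
    out = calls.copy()
    out["direction"] = np.where(out["delta"] > 0, "elongated",
                                np.where(out["delta"] < 0, "shortened", "unchanged"))
    sig = out[out["significant"]]
    summary = (
        sig.groupby(["end", "direction"])["gene"].nunique().rename("n_genes").reset_index()
        if len(sig)
        else pd.DataFrame(columns=["end", "direction", "n_genes"])
    )
    return out, summary


def format_empirical_p(p: float, n_perm: int) -> str:
    """Report a zero empirical p-value as '< 1/n_perm'."""
    if p == 0.0:
        return f"<{1 / n_perm:g}"
    return f"{p:g}"
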