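"""Transcription map: locus calling from stranded coverage and expression.

Implements the coverage-based segmentation used to build a genome-wide
transcription map: maximal runs of nonzero unique-read coverage are merged
across short zero gaps (<= ``merge_gap`` bases, default 50) into transcribed
loci, loci whose maximum depth falls below ``min_peak_height`` (default 2)
are discarded, and the surviving loci are labelled against annotation.
Expression of a feature is its RPKM (reads per kilobase per million mapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Annotation

TIMEPOINTS = (0, 15, 30, 60, 120, 180)


@dataclass
class CoverageTrack:
    """Per-base unique-read depth for one chromosome strand of one sample."""

    chromosome: str
    strand: str
    depth: np.ndarray
    sample: str
    library_size: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass
class TranscribedLocus:
    """Contiguous transcribed region; [start, end) half-open."""

    chromosome: str
    strand: str
    start: int
    end: int
    peak_height: int
    labels: list[str] = field(default_factory=list)
    antisense_neighbours: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("locus start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def call_transcribed_regions(
    track: CoverageTrack, min_peak_height: int = 2, merge_gap: int = 50
) -> list[TranscribedLocus]:
    """Call transcribed loci on one coverage track.

    Maximal runs of nonzero depth are found; runs whose separating zero gap
    is <= ``merge_gap`` bases are merged (the merged locus spans the gap);
    merged loci with maximum depth < ``min_peak_height`` are dropped.
    Returns loci sorted by start.
    """
    depth = track.depth
    if depth.size == 0 or not depth.any():
        return []
    nz = depth > 0
    padded = np.concatenate(([False], nz, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)

    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    loci = []
    for s, e in merged:
        peak = int(depth[s:e].max())
        if peak >= min_peak_height:
            loci.append(
                TranscribedLocus(
                    chromosome=track.chromosome,
                    strand=track.strand,
                    start=s,
                    end=e,
                    peak_height=peak,
                )
            )
    return loci


def label_loci(loci: Iterable[TranscribedLocus], annotation: Annotation) -> list[TranscribedLocus]:
    """Attach same-strand overlapping gene labels to each locus (in place).

    A locus is labelled with every annotated gene it overlaps by >= 1 bp on
    the same strand, in genomic order. A locus with no same-strand overlap
    keeps an empty label list ("unannotated"); any opposite-strand genes it
    overlaps are noted as antisense neighbours.
    """
    out = []
    for locus in loci:
        if locus.chromosome not in annotation.chrom_lengths:
            raise ValueError(f"locus chromosome {locus.chromosome!r} not in annotation")
        same = annotation.overlapping(locus.chromosome, locus.start, locus.end, locus.strand)
        locus.labels = [g.gene_id for g in same]
        if not same:
            opposite = annotation.overlapping(
                locus.chromosome, locus.start, locus.end,
                "-" if locus.strand == "+" else "+",
            )
            locus.antisense_neighbours = [g.gene_id for g in opposite]
        out.append(locus)
    return out


def compute_rpkm(raw_count: float, feature_length: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return raw_count / (feature_length / 1_000) / (library_size / 1_000_000)


@dataclass
class ExpressionMatrix:
    """Feature x sample raw counts and RPKM with the sample design.

    ``samples`` carries one row per sample id with columns
    ``strain``, ``timepoint`` (minutes) and ``replicate``.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    feature_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.rpkm.columns):
            raise ValueError("counts/rpkm sample axes differ")
        if not self.counts.index.equals(self.rpkm.index):
            raise ValueError("counts/rpkm feature axes differ")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing {sorted(missing)[:3]}...")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def strain_samples(self, strain: str, timepoint: int | None = None) -> list[str]:
        sel = self.samples[self.samples["strain"] == strain]
        if timepoint is not None:
            sel = sel[sel["timepoint"] == timepoint]
        return list(sel.index)

    def timepoints(self, strain: str) -> list[int]:
        return sorted(self.samples.loc[self.samples["strain"] == strain, "timepoint"].unique())

    def mean_rpkm(self, feature: str, strain: str, timepoint: int) -> float:
        """Replicate-mean RPKM of one feature at one timepoint."""
        cols = self.strain_samples(strain, timepoint)
        return float(self.rpkm.loc[feature, cols].mean())

    def log2_fold_change_profile(
        self, feature: str, strain: str, pseudocount: float = 1.0
    ) -> pd.Series:
        """Per-timepoint log2((rpkm_t + c) / (rpkm_0 + c)), replicate means.

        The pseudocount ``c`` (default 1 RPKM unit) guards the ratio for
        weakly expressed features. The t=0 entry is identically 0.
        """
        if feature not in self.rpkm.index:
            raise KeyError(f"feature {feature!r} not in matrix")
        tps = self.timepoints(strain)
        if 0 not in tps:
            raise ValueError(f"strain {strain!r} has no t=0 samples")
        means = {
            t: self.rpkm.loc[feature, self.strain_samples(strain, t)].mean() for t in tps
        }
        base = means[0] + pseudocount
        return pd.Series(
            {t: float(np.log2((means[t] + pseudocount) / base)) for t in tps},
            name=feature,
        )

    def log2fc_profiles(
        self, features: Sequence[str], strain: str, pseudocount: float = 1.0
    ) -> pd.DataFrame:
        """Feature x timepoint log2FC matrix (vectorised over features)."""
        tps = self.timepoints(strain)
        cols = {t: self.strain_samples(strain, t) for t in tps}
        means = pd.DataFrame(
            {t: self.rpkm.loc[features, c].mean(axis=1) for t, c in cols.items()}
        )
        base = means[0] + pseudocount
        return np.log2(means.add(pseudocount).div(base, axis=0))


def quantify_loci(
    tracks_by_sample: dict[str, dict[tuple[str, str], np.ndarray]],
    annotation: Annotation,
    library_sizes: dict[str, int],
    samples: pd.DataFrame,
    region: str = "cds",
) -> ExpressionMatrix:
    """Count coverage inside each annotated feature and convert to RPKM.

    ``tracks_by_sample`` maps sample -> {(chromosome, strand): depth vector}.
    Depth is unique-read coverage; the raw count of a feature is its summed
    per-base depth (one read per covered base). With ``region="cds"`` coding
    genes are counted over their CDS (the expression measure the boundary
    filters use); ncRNAs always over their full span.
    """
    features, lengths = [], []
    spans = []
    for g in sorted(annotation, key=lambda g: g.gene_id):
        if region == "cds" and g.biotype == "coding":
            lo, hi = g.cds_start, g.cds_end
        else:
            lo, hi = g.start, g.end
        features.append(g.gene_id)
        lengths.append(hi - lo)
        spans.append((g.chromosome, g.strand, lo, hi))

    counts = {}
    for sample, tracks in tracks_by_sample.items():
        col = np.zeros(len(features), dtype=np.int64)
        for i, (chrom, strand, lo, hi) in enumerate(spans):
            depth = tracks.get((chrom, strand))
            if depth is not None:
                col[i] = int(depth[lo:hi].sum())
        counts[sample] = col
    counts = pd.DataFrame(counts, index=pd.Index(features, name="feature"))
    lengths = pd.Series(lengths, index=counts.index, name="length")
    lib = pd.Series(library_sizes).reindex(counts.columns)
    rpkm = counts.div(lengths / 1_000, axis=0).div(lib / 1_000_000, axis=1)
    return ExpressionMatrix(
        counts=counts, rpkm=rpkm, feature_lengths=lengths, samples=samples
    )
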