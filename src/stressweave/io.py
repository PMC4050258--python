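"""Readers and writers for the plain-text formats the pipeline speaks.

bedGraph (4-column, one file per strand per sample), GFF3 gene/CDS models
with a ``biotype`` attribute, BED6 locus files, GMT gene-set collections and
the TSV matrices (expression, protein, sample sheet, DE flags).

GFF3 and bedGraph are 1-based-inclusive / 0-based-half-open on disk
respectively per their standards; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Annotation, Gene
from .stats import GeneFamilyCollection

# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(depth: np.ndarray, chromosome: str, path: str | Path) -> None:
    """Run-length encode a per-base depth vector; zero runs are omitted."""
    depth = np.asarray(depth)
    path = Path(path)
    with path.open("w") as fh:
        if depth.size:
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    fh.write(f"{chromosome}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome depth vectors (int64)."""
    out = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom not in out:
                raise ValueError(f"unknown chromosome {chrom!r} in {path}")
            out[chrom][int(start):int(end)] += int(float(value))
    return out


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
        for g in sorted(annotation, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chromosome}\tstressweave\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            if g.biotype == "coding":
                fh.write(
                    f"{g.chromosome}\tstressweave\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> Annotation:
    """Parse gene + CDS features with ID/Parent and biotype attributes."""
    chrom_lengths: dict[str, int] = {}
    genes: dict[str, dict] = {}
    cds: dict[str, tuple[int, int]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                chrom_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            attrs = _gff_attributes(attrs)
            if ftype == "gene":
                gid = attrs["ID"]
                genes[gid] = dict(
                    gene_id=gid,
                    chromosome=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    biotype=attrs.get("biotype", "coding"),
                )
            elif ftype == "CDS":
                parent = attrs.get("Parent") or attrs["ID"].removesuffix(".cds")
                lo, hi = int(start) - 1, int(end)
                if parent in cds:  # multi-exon CDS: keep the hull
                    lo = min(lo, cds[parent][0])
                    hi = max(hi, cds[parent][1])
                cds[parent] = (lo, hi)
    models = []
    for gid, kw in genes.items():
        if gid in cds:
            kw["cds_start"], kw["cds_end"] = cds[gid]
        elif kw["biotype"] == "coding":
            # tolerate coding genes without explicit CDS: whole span codes
            kw["cds_start"], kw["cds_end"] = kw["start"], kw["end"]
        models.append(Gene(**kw))
    return Annotation(models, chrom_lengths or None)


# ---------------------------------------------------------------------------
# BED6 loci


def write_loci_bed(loci: Sequence, path: str | Path) -> None:
    """Write transcribed loci as BED6; score column carries peak height."""
    with Path(path).open("w") as fh:
        for loc in loci:
            name = ",".join(loc.labels) if loc.labels else "unannotated"
            fh.write(
                f"{loc.chromosome}\t{loc.start}\t{loc.end}\t{name}\t"
                f"{int(loc.peak_height)}\t{loc.strand}\n"
            )


def read_loci_bed(path: str | Path):
    from .transcription import TranscribedLocus  # local import to avoid cycle

    loci = []
    with Path(path).open() as fh:
        for line in fh:
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            labels = [] if name == "unannotated" else name.split(",")
            loci.append(
                TranscribedLocus(
                    chromosome=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                    peak_height=int(score),
                    labels=labels,
                )
            )
    return loci


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(collection: GeneFamilyCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.families):
            members = "\t".join(sorted(collection.families[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneFamilyCollection:
    """Read a GMT file; universe defaults to the union of all families."""
    families: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            families[fields[0]] = frozenset(g for g in fields[2:] if g)
    if universe is None:
        uni = frozenset().union(*families.values()) if families else frozenset()
    else:
        uni = frozenset(universe)
        families = {n: m & uni for n, m in families.items()}
    return GeneFamilyCollection(families=families, universe=uni)


# ---------------------------------------------------------------------------
# TSV matrices


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
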