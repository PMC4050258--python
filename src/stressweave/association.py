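"""Guilt-by-association functional annotation of stress-responsive ncRNAs.

Each candidate ncRNA's time-course expression profile is correlated with
the CDS-region profiles of all coding genes; genes with Pearson rho above
+threshold (default 0.7, strict) form the positively correlated set and
below -threshold the negatively correlated set. Each set is tested for
over-representation of every gene family (hypergeometric upper tail), the
tests are BH-corrected jointly across all (ncRNA, family, direction)
combinations, and significant calls are assembled into a signed
family x ncRNA association matrix, clustered by Euclidean distance and
complete linkage on a +1/-1/0 encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import (
    GeneFamilyCollection,
    bh_fdr,
    hierarchical_cluster,
    hypergeometric_overrep,
)

POSITIVE, NEGATIVE = "positive", "negative"

TEST_COLUMNS = ["ncrna", "family", "direction", "overlap", "selected_size",
                "family_size", "universe_size", "p_value"]


def correlated_gene_sets(
    ncrna_profile: pd.Series,
    coding_profiles: pd.DataFrame,
    threshold: float = 0.7,
) -> tuple[set[str], set[str], list[str]]:
    """Split coding genes by profile correlation with one ncRNA.

    Correlations use the shared sample/timepoint axis of ``ncrna_profile``
    and the rows of ``coding_profiles``. Strict inequalities as printed:
    rho > threshold -> positive set, rho < -threshold -> negative set;
    |rho| exactly at the threshold is excluded. Zero-variance profiles
    (either side) are excluded and reported.

    Returns (positive_set, negative_set, excluded_gene_ids).
    """
    x = ncrna_profile.to_numpy(dtype=float)
    mat = coding_profiles.to_numpy(dtype=float)
    if mat.shape[1] != x.size:
        raise ValueError("profile axes differ between ncRNA and coding genes")
    if np.ptp(x) == 0:
        # ncRNA itself uninformative: everything excluded
        return set(), set(), list(coding_profiles.index)
    xc = x - x.mean()
    xn = np.sqrt((xc ** 2).sum())
    mc = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((mc ** 2).sum(axis=1))
    degenerate = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc @ xc) / (norms * xn)
    genes = coding_profiles.index.to_numpy()
    positive = set(genes[(~degenerate) & (rho > threshold)])
    negative = set(genes[(~degenerate) & (rho < -threshold)])
    excluded = list(genes[degenerate])
    return positive, negative, excluded


def annotate_ncrna(
    ncrna: str,
    families: GeneFamilyCollection,
    positive_set: set[str],
    negative_set: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of every family in each
    correlated set (no FDR here; corrected jointly across ncRNAs later).

    The universe is ``families.universe`` (restrict it to usable coding
    genes before calling). Empty correlated sets yield no tests.
    """
    rows = []
    uni_n = len(families.universe)
    for direction, selected in ((POSITIVE, positive_set), (NEGATIVE, negative_set)):
        sel = selected & families.universe
        if not sel:
            continue
        for name in sorted(families.families):
            fam = families.families[name]
            k = len(fam & sel)
            p = hypergeometric_overrep(k, len(sel), len(fam), uni_n)
            rows.append(
                dict(ncrna=ncrna, family=name, direction=direction, overlap=k,
                     selected_size=len(sel), family_size=len(fam),
                     universe_size=uni_n, p_value=p)
            )
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


@dataclass
class AssociationMatrix:
    """Signed family x ncRNA association calls with clustering orders.

    ``matrix`` holds +1 (positive association), -1 (negative) or 0 (none);
    ``tests`` the long-form table with p-values and joint BH FDR;
    ``row_order``/``col_order`` the dendrogram leaf orders (family and
    ncRNA labels respectively).
    """

    matrix: pd.DataFrame
    tests: pd.DataFrame
    fdr_threshold: float
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)

    def cell(self, family: str, ncrna: str) -> int:
        return int(self.matrix.loc[family, ncrna])

    def significant_families(self, ncrna: str) -> dict[str, int]:
        col = self.matrix[ncrna]
        return {fam: int(v) for fam, v in col.items() if v != 0}


def build_association_matrix(
    tests: pd.DataFrame,
    families: Sequence[str],
    ncrnas: Sequence[str],
    fdr_threshold: float = 0.05,
) -> AssociationMatrix:
    """Assemble the signed association matrix from pooled tests.

    BH FDR is applied jointly across all (ncRNA, family, direction) rows;
    a cell is non-zero only when its best direction reaches
    fdr < ``fdr_threshold``, signed by that direction. Rows and columns are
    ordered by complete-linkage clustering of the +1/-1/0 encoding
    (deterministic for the given input order).
    """
    tests = tests.copy()
    mat = pd.DataFrame(0, index=pd.Index(families, name="family"),
                       columns=pd.Index(ncrnas, name="ncrna"), dtype=int)
    if len(tests):
        tests["fdr"] = bh_fdr(tests["p_value"].to_numpy())
        sig = tests[tests["fdr"] < fdr_threshold]
        # keep the most significant direction per (family, ncrna)
        sig = sig.sort_values("p_value").drop_duplicates(["ncrna", "family"])
        for _, r in sig.iterrows():
            mat.loc[r["family"], r["ncrna"]] = 1 if r["direction"] == POSITIVE else -1
    else:
        tests["fdr"] = pd.Series(dtype=float)

    row_order = list(mat.index)
    col_order = list(mat.columns)
    if mat.shape[0] >= 2:
        order, _ = hierarchical_cluster(mat.to_numpy(dtype=float))
        row_order = [mat.index[i] for i in order]
    if mat.shape[1] >= 2:
        order, _ = hierarchical_cluster(mat.to_numpy(dtype=float).T)
        col_order = [mat.columns[i] for i in order]
    return AssociationMatrix(matrix=mat, tests=tests, fdr_threshold=fdr_threshold,
                             row_order=row_order, col_order=col_order)


def associate_ncrnas(
    ncrna_profiles: pd.DataFrame,
    coding_profiles: pd.DataFrame,
    families: GeneFamilyCollection,
    rho_threshold: float = 0.7,
    fdr_threshold: float = 0.05,
    combined_absolute_set: bool = False,
) -> AssociationMatrix:
    """Full guilt-by-association pass over a set of candidate ncRNAs.

    Profiles are log2FC time courses (rows = features, columns = the shared
    sample axis). With ``combined_absolute_set`` a single |rho|>threshold
    set is tested per ncRNA instead of signed sets (the sign column then
    reports 'positive' for all calls).
    """
    usable = families.restrict(set(coding_profiles.index) & families.universe)
    all_tests = []
    for ncrna in ncrna_profiles.index:
        pos, neg, _ = correlated_gene_sets(
            ncrna_profiles.loc[ncrna], coding_profiles, rho_threshold
        )
        if combined_absolute_set:
            pos, neg = pos | neg, set()
        all_tests.append(annotate_ncrna(ncrna, usable, pos, neg))
    tests = (
        pd.concat(all_tests, ignore_index=True)
        if all_tests else pd.DataFrame(columns=TEST_COLUMNS)
    )
    return build_association_matrix(
        tests, sorted(usable.families), list(ncrna_profiles.index), fdr_threshold
    )


def compare_strain_associations(
    matrix_a: AssociationMatrix, matrix_b: AssociationMatrix,
    name_a: str = "WT", name_b: str = "mutant",
) -> pd.DataFrame:
    """Per-ncRNA families gained or lost between two strains' matrices.

    ncRNAs absent from either matrix are dropped (with the shared columns
    compared); family rows must match. 'gained' means significant in
    ``matrix_b`` but not ``matrix_a``; 'lost' the reverse; 'sign_flip' a
    significant call whose sign differs.
    """
    if list(matrix_a.matrix.index) != list(matrix_b.matrix.index):
        raise ValueError("family rows differ between matrices")
    shared = [c for c in matrix_a.matrix.columns if c in matrix_b.matrix.columns]
    rows = []
    for nc in shared:
        a = matrix_a.matrix[nc]
        b = matrix_b.matrix[nc]
        for fam in matrix_a.matrix.index:
            va, vb = int(a[fam]), int(b[fam])
            if va == vb:
                continue
            if va == 0:
                change = "gained"
            elif vb == 0:
                change = "lost"
            else:
                change = "sign_flip"
            rows.append(dict(ncrna=nc, family=fam, change=change,
                             **{name_a: va, name_b: vb}))
    return pd.DataFrame(rows, columns=["ncrna", "family", "change", name_a, name_b])


def neglog10_profiles(
    tests_a: pd.DataFrame, tests_b: pd.DataFrame, ncrna: str,
) -> pd.DataFrame:
    """Paired -log10 p profiles of one ncRNA across families and strains
    (best direction per family), for plotting strain comparisons."""
    out = []
    for label, tests in (("a", tests_a), ("b", tests_b)):
        sub = tests[tests["ncrna"] == ncrna]
        if len(sub):
            best = sub.sort_values("p_value").drop_duplicates("family")
            for _, r in best.iterrows():
                out.append(dict(strain=label, family=r["family"],
                                neglog10_p=float(-np.log10(max(r["p_value"], 1e-300)))))
    return pd.DataFrame(out, columns=["strain", "family", "neglog10_p"])
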