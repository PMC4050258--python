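"""Statistical primitives shared by every pipeline stage.

Thin, validated wrappers around scipy/statsmodels for the standard tests
(Pearson correlation, hypergeometric over-representation, Benjamini-Hochberg
FDR, Welch t-test, complete-linkage clustering) plus a hand-rolled label
permutation engine used by the boundary-dynamics stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


class ZeroVarianceError(ValueError):
    """A series required to have nonzero variance is constant."""


@dataclass(frozen=True)
class GeneFamilyCollection:
    """Named gene families (e.g. GO Slim terms) over a testing universe.

    Every family must be a subset of the universe and family names must be
    unique (guaranteed by the dict keys).
    """

    families: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must not be empty")
        for name, members in self.families.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"family {name!r} has {len(extra)} members outside the universe"
                )

    def restrict(self, universe: Iterable[str]) -> "GeneFamilyCollection":
        """Intersect all families with a new universe (e.g. expressed genes)."""
        uni = frozenset(universe)
        if not uni:
            raise ValueError("restricted universe is empty")
        fams = {n: m & uni for n, m in self.families.items()}
        return GeneFamilyCollection(families=fams, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric over-representation test."""

    family: str
    overlap: int
    selected_size: int
    family_size: int
    universe_size: int
    p_value: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.overlap > min(self.selected_size, self.family_size):
            raise ValueError("overlap exceeds min(selected_size, family_size)")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length series.

    Raises :class:`ZeroVarianceError` when either series is constant
    (the caller decides whether to exclude such features) and ``ValueError``
    on a length mismatch or fewer than three observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant input series")
    return float(sps.pearsonr(x, y).statistic)


def hypergeometric_overrep(
    overlap: int, selected_size: int, family_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts family members in a draw of ``selected_size`` genes without
    replacement from a universe of ``universe_size`` genes of which
    ``family_size`` belong to the family.
    """
    if overlap < 0 or selected_size < 0 or family_size < 0 or universe_size <= 0:
        raise ValueError("counts must be non-negative and universe positive")
    if overlap > min(selected_size, family_size):
        raise ValueError("overlap exceeds min(selected_size, family_size)")
    if max(selected_size, family_size) > universe_size:
        raise ValueError("selected/family size exceeds universe")
    # sf(k-1) = P(X >= k)
    return float(sps.hypergeom.sf(overlap - 1, universe_size, family_size, selected_size))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ZeroVarianceError("both groups constant with different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def permutation_engine(
    observed_stat: float,
    statistic_fn: Callable[[np.ndarray], float],
    labels: Sequence,
    n_perm: int,
    seed: int | np.random.Generator,
    plus_one: bool = False,
) -> float:
    """Empirical p-value from random label permutations.

    ``statistic_fn`` receives a permuted copy of ``labels`` (a numpy array)
    and must return a scalar; the p-value is the proportion of permutations
    whose statistic is >= ``observed_stat``. With ``plus_one`` the
    (obs+1)/(n+1) smoothed estimator is returned instead of the plain
    proportion. Permutations are drawn independently (duplicates allowed),
    which keeps the estimator unbiased.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    if len(np.unique(labels.astype(str))) < 2:
        raise ValueError("need at least two distinct labels to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        stat = statistic_fn(rng.permutation(labels))
        if stat >= observed_stat:
            hits += 1
    if plus_one:
        return (hits + 1) / (n_perm + 1)
    return hits / n_perm


def permuted_group_mean_diffs(
    values: np.ndarray,
    group_index: np.ndarray,
    reference_group: int,
    test_groups: Sequence[int],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised null distribution of mean(group) - mean(reference).

    One row per permutation, one column per entry of ``test_groups``. All
    test-group statistics within a row come from the same permutation of
    ``values``, mirroring a single relabelling of the whole time course.
    Used by the boundary-dynamics permutation test where calling the scalar
    engine per (gene, end, timepoint) would be needlessly slow.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n != group_index.size:
        raise ValueError("values and group_index must align")
    # matrix of permuted values: n_perm x n
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = values[idx]
    ref_mask = group_index == reference_group
    if ref_mask.sum() == 0:
        raise ValueError("reference group empty")
    ref_mean = perm[:, ref_mask].mean(axis=1)
    out = np.empty((n_perm, len(test_groups)))
    for j, g in enumerate(test_groups):
        mask = group_index == g
        if mask.sum() == 0:
            out[:, j] = np.nan
        else:
            out[:, j] = perm[:, mask].mean(axis=1) - ref_mean
    return out


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage hierarchical clustering of rows.

    Returns ``(leaf_order, merge_tree)`` where ``leaf_order`` is the
    dendrogram leaf ordering (original row indices) and ``merge_tree`` the
    scipy linkage matrix. Deterministic for a fixed input row order; rows
    containing NaN are rejected (impute upstream).
    """
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values")
    tree = hierarchy.linkage(values, method=linkage, metric=distance)
    order = hierarchy.leaves_list(tree)
    return order, tree


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Long-form DataFrame for a batch of enrichment results, FDR attached."""
    if not results:
        return pd.DataFrame(
            columns=["family", "overlap", "selected_size", "family_size",
                     "universe_size", "p_value", "fdr"]
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df
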