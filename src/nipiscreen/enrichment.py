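"""Gene-class enrichment, biclustering, foundling genes and complex coverage.

Over-representation of a gene class within the hit list is scored with the
one-sided Fisher exact test, i.e. the hypergeometric upper tail
``P(X >= k)`` for an overlap of ``k`` hits with a class of size ``K`` drawn
in a query of size ``n`` from a universe of ``N`` genes, Bonferroni-corrected
by the number of classes actually tested.  An optional penalized variant
(the EASE-score convention) substitutes ``k - 1`` for ``k``, damping
significance for small overlaps.

"Foundling" genes are hits that belong to no significantly enriched class --
screen hits about which the annotation corpus is silent.  Gene x class
membership matrices are biclustered under the 1 - Pearson correlation
distance with average linkage; protein complexes are reported when at least
``min_size`` members exist and the screen recovered strictly more than half
of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

from .screen_io import AnnotationClass, ComplexRecord


@dataclass(slots=True)
class EnrichmentResult:
    """One class's overlap counts and raw/corrected p-values."""

    class_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_corrected: float
    mode: str
    significant: bool = False


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def hypergeom_upper(k: int, K: int, n: int, N: int, mode: str = "fisher") -> float:
    """Upper-tail overlap probability ``P(X >= k)``.

    ``X`` counts class members in a draw of ``n`` genes without replacement
    from ``N``, of which ``K`` are in the class.  ``mode="ease"`` applies the
    penalized convention (``k - 1`` in place of ``k``, floored at ``k = 0``).
    """
    _check_counts(k, K, n, N)
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    k_eff = k if mode == "fisher" else max(k - 1, 0)
    # sf(k_eff - 1) = P(X >= k_eff)
    return float(hypergeom.sf(k_eff - 1, N, K, n))


def enrich_all(
    query: Iterable[str],
    classes: Sequence[AnnotationClass],
    universe: Iterable[str] | None = None,
    alpha: float = 1e-3,
    mode: str = "fisher",
) -> list[EnrichmentResult]:
    """Test every class for over-representation in the query gene set.

    The universe defaults to the union of all class genes plus the query.
    Query genes outside an explicit universe are dropped with a warning.
    Bonferroni multiplies by the number of classes actually tested (those
    with at least one universe gene).  Results are sorted by corrected
    p-value, ties broken by class id, and flagged significant at
    ``p_corrected < alpha``.
    """
    query = set(query)
    if universe is None:
        universe = set().union(*(c.genes for c in classes)) | query if classes else set(query)
    else:
        universe = set(universe)
        stray = query - universe
        if stray:
            warnings.warn(
                f"{len(stray)} query genes outside the universe were dropped",
                stacklevel=2,
            )
            query &= universe
    if not universe:
        raise ValueError("empty gene universe")
    n, N = len(query), len(universe)

    tested = []
    for cls in classes:
        class_genes = cls.genes & universe
        if not class_genes:
            continue
        K = len(class_genes)
        k = len(query & class_genes)
        tested.append((cls.class_id, k, K))
    m = len(tested)
    results = []
    for class_id, k, K in tested:
        p_raw = hypergeom_upper(k, K, n, N, mode=mode)
        p_corr = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(class_id, k, K, n, N, p_raw, p_corr, mode,
                             significant=p_corr < alpha)
        )
    results.sort(key=lambda r: (r.p_corrected, r.class_id))
    return results


def foundlings(
    query: Iterable[str],
    results: Sequence[EnrichmentResult],
    classes: Sequence[AnnotationClass],
) -> set[str]:
    """Query genes belonging to no significantly enriched class."""
    significant_ids = {r.class_id for r in results if r.significant}
    covered: set[str] = set()
    for cls in classes:
        if cls.class_id in significant_ids:
            covered |= cls.genes
    return set(query) - covered


# ---------------------------------------------------------------------------
# clustering under 1 - Pearson correlation
# ---------------------------------------------------------------------------

def correlation_distance_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` between rows; constant rows sit at distance 1.

    Pearson correlation is undefined for zero-variance rows, so the fixed
    convention here places constant rows at distance 1 (the uncorrelated
    value) from everything, including each other.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    sd = data.std(axis=1)
    constant = sd == 0
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    dist = 1.0 - unit @ unit.T
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    # numerical guard: clip to the valid [0, 2] range and symmetrize
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


def _condensed(dist: np.ndarray) -> np.ndarray:
    return dist[np.triu_indices_from(dist, k=1)]


def correlation_linkage(data: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration under the 1 - Pearson distance."""
    return hierarchy.linkage(_condensed(correlation_distance_matrix(data)),
                             method="average")


def bicluster(
    matrix: pd.DataFrame,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Hierarchically cluster the rows and the columns of a membership matrix.

    Returns ``(row order, column order, row linkage, column linkage)`` with
    leaf orders that are deterministic for a fixed input.  Requires at least
    two rows with nonzero variance.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("bicluster needs at least a 2 x 2 matrix")
    values = matrix.to_numpy(dtype=float)
    if (values.std(axis=1) > 0).sum() < 2:
        raise ValueError("bicluster needs at least 2 non-constant rows")
    row_linkage = correlation_linkage(values)
    col_linkage = correlation_linkage(values.T)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_linkage)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    return row_order, col_order, row_linkage, col_linkage


def membership_matrix(
    genes: Sequence[str], classes: Sequence[AnnotationClass]
) -> pd.DataFrame:
    """Binary genes x classes membership matrix (1 = gene in class)."""
    data = {
        cls.class_id: [1 if g in cls.genes else 0 for g in genes]
        for cls in classes
    }
    return pd.DataFrame(data, index=list(genes))


def complex_coverage(
    complexes: Sequence[ComplexRecord],
    hits: Iterable[str],
    min_size: int = 3,
    min_fraction: float = 0.5,
) -> list[tuple[str, int, int, float]]:
    """Complexes of size >= ``min_size`` with strictly more than
    ``min_fraction`` of their members among the hits.

    Returns ``(complex_id, covered, size, fraction)`` sorted by descending
    fraction, ties broken by complex id.
    """
    hits = set(hits)
    retained = []
    for rec in complexes:
        size = len(rec.members)
        if size < min_size:
            continue
        covered = len(rec.members & hits)
        fraction = covered / size
        if fraction > min_fraction:
            retained.append((rec.complex_id, covered, size, fraction))
    retained.sort(key=lambda t: (-t[3], t[0]))
    return retained
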