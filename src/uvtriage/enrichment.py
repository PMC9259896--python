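"""Local gene-set over-representation analysis and term-membership
clustering.

This is a desk-scale stand-in for web enrichment services: a one-sided
upper-tail hypergeometric test of a candidate gene list against local
term -> gene tables (GMT or TSV), with Benjamini-Hochberg or Bonferroni
correction, plus plain k-means clustering of genes on their binary
term-membership vectors. P-values from hosted tools depend on the
annotation-database release and proprietary corrections (g:SCS) and are
not reproduced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

Term = tuple[str, str, frozenset[str]]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    universe_size: int
    term_size: int
    query_size: int
    overlap: int
    p_value: float
    adjusted_p: float
    overlap_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.term_size, self.query_size):
            raise ValueError("overlap out of bounds")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p out of [0, 1]")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: term size, n: query size, k: observed overlap.
    Computed via the scipy survival function (log-space internally, so
    stable for extreme tails).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: Iterable[str],
    terms: Sequence[Term],
    universe: Optional[Iterable[str]] = None,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Over-representation of a gene list against a term table.

    The universe defaults to every gene appearing in the term table.
    Query genes outside the universe are dropped with a warning; term
    gene sets are restricted to the universe. One result per term with
    overlap >= 1, corrected over ALL tested terms (including zero-overlap
    ones), sorted by adjusted p then term id.
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"correction must be 'bh' or 'bonferroni', got {correction!r}")
    if universe is None:
        universe_set = frozenset(g for _, _, genes in terms for g in genes)
    else:
        universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty gene universe")

    query_set = frozenset(query)
    dropped = query_set - universe_set
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe dropped", stacklevel=2
        )
        query_set -= dropped

    N, n = len(universe_set), len(query_set)
    rows = []
    for term_id, term_name, genes in terms:
        term_genes = frozenset(genes) & universe_set
        overlap = term_genes & query_set
        p = hypergeom_upper_tail(N, len(term_genes), n, len(overlap))
        rows.append((term_id, term_name, term_genes, overlap, p))

    pvals = np.array([r[4] for r in rows]) if rows else np.array([])
    if len(pvals):
        method = "fdr_bh" if correction == "bh" else "bonferroni"
        _, adjusted, _, _ = multipletests(pvals, method=method)
    else:
        adjusted = pvals

    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=term_name,
            universe_size=N,
            term_size=len(term_genes),
            query_size=n,
            overlap=len(overlap),
            p_value=float(p),
            adjusted_p=float(max(adj, p)),
            overlap_genes=overlap,
        )
        for (term_id, term_name, term_genes, overlap, p), adj in zip(rows, adjusted)
        if overlap
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term_id))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "N": [r.universe_size for r in results],
            "K": [r.term_size for r in results],
            "n": [r.query_size for r in results],
            "k": [r.overlap for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "genes": [";".join(sorted(r.overlap_genes)) for r in results],
        }
    )


def gene_term_matrix(genes: Sequence[str], terms: Sequence[Term]) -> pd.DataFrame:
    """Binary gene x term membership matrix (rows in given gene order)."""
    data = {
        term_id: [1 if g in term_genes else 0 for g in genes]
        for term_id, _, term_genes in terms
    }
    return pd.DataFrame(data, index=list(genes), dtype=float)


@dataclass
class GeneClustering:
    k: int
    labels: dict[str, int]
    seed: int
    inertia: float

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, label in self.labels.items():
            out.setdefault(label, []).append(gene)
        return out


def cluster_genes(
    gene_term_matrix: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
) -> GeneClustering:
    """K-means on binary term-membership rows (Euclidean), k-means++
    seeding, deterministic given the seed.

    Guarantees exactly ``k`` non-empty clusters when there are at least
    ``k`` genes: if duplicate rows collapse clusters, surplus genes are
    reassigned in gene order with a warning.
    """
    genes = list(gene_term_matrix.index)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    X = gene_term_matrix.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on duplicate-point convergence
        km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-6)
        labels = km.fit_predict(X)
    labels = _ensure_k_clusters(labels, k)
    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    inertia = float(sum(((X[labels == c] - centers[c]) ** 2).sum() for c in range(k)))
    return GeneClustering(
        k=k,
        labels={g: int(l) for g, l in zip(genes, labels)},
        seed=seed,
        inertia=inertia,
    )


def _ensure_k_clusters(labels: np.ndarray, k: int) -> np.ndarray:
    labels = labels.copy()
    present = set(int(l) for l in labels)
    missing = [c for c in range(k) if c not in present]
    if not missing:
        return labels
    warnings.warn(
        f"{len(missing)} empty clusters re-filled deterministically by gene order",
        stacklevel=2,
    )
    # move genes (in order) out of over-full clusters into the empty ones
    counts = {c: int((labels == c).sum()) for c in range(k)}
    for target in missing:
        for i in range(len(labels)):
            donor = int(labels[i])
            if counts[donor] > 1:
                counts[donor] -= 1
                labels[i] = target
                counts[target] = counts.get(target, 0) + 1
                break
    return labels
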