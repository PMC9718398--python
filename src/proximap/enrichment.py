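"""Overrepresentation analysis (ORA) of prey sets against GMT gene-set collections.

For a query of n genes drawn from a universe of N, a term annotating K
universe genes, and an observed overlap of k, the enrichment p-value is the
upper tail of the hypergeometric distribution, P(X >= k). Benjamini-Hochberg
FDR q-values are computed across all tested terms. Only over-representation
(one-sided) is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ingest import normalize_symbol


@dataclass
class GeneSetCollection:
    """Named gene sets: term id -> (term name, member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    source: str = "custom"

    def __post_init__(self) -> None:
        normalized = {}
        for term, (name, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            normalized[term] = (name, frozenset(normalize_symbol(g) for g in genes))
        self.sets = normalized

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path: str | Path, source: str = "custom") -> GeneSetCollection:
    """Parse a GMT file (term, description, member genes...).

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields raises :class:`ValueError` with its line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {line_no} has {len(fields)} field(s); "
                "GMT requires term, description and at least one gene"
            )
        term, name = fields[0], fields[1]
        genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path}: line {line_no} ({term}) has no genes")
        sets[term] = (name, genes)
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([term, name, *sorted(genes)])
        for term, (name, genes) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: overlap counts, hypergeometric p and BH q."""

    term: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    fdr_method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of ``query`` in each term of the collection.

    Query genes outside the universe are dropped with a warning; terms with
    zero overlap with the universe are skipped. Results are sorted by p-value
    then term id.
    """
    universe_set = {normalize_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = {normalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("query is empty")
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query gene(s) outside the universe",
            stacklevel=2,
        )
        query_set -= outside
    if not query_set:
        raise ValueError("query is empty after restricting to the universe")

    N = len(universe_set)
    n = len(query_set)
    rows: list[tuple[str, str, int, int]] = []
    for term, (name, genes) in collection.sets.items():
        in_universe = genes & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query_set)
        rows.append((term, name, k, K))
    if not rows:
        return []
    pvals = [float(hypergeom.sf(k - 1, N, K, n)) for _, _, k, K in rows]
    qvals = multipletests(pvals, method=fdr_method)[1]
    results = [
        EnrichmentResult(
            term=term,
            name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=float(min(max(p, 1e-300), 1.0)),
            q_value=float(min(max(q, 1e-300), 1.0)),
        )
        for (term, name, k, K), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Results as a table (term, name, k, K, n, N, p_value, q_value)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )


def dotplot_export(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Dot-plot export: term, -log10 p, overlap count (mirrors pathway dot plots)."""
    import numpy as np

    df = enrichment_table(results)
    if df.empty:
        return pd.DataFrame(columns=["term", "name", "neg_log10_p", "overlap"])
    return pd.DataFrame(
        {
            "term": df["term"],
            "name": df["name"],
            "neg_log10_p": -np.log10(df["p_value"]),
            "overlap": df["k"],
        }
    )
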