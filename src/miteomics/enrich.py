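"""Hypergeometric over-representation testing of gene sets.

A single upper-tail hypergeometric engine serves every enrichment use in
the pipeline (network clusters, profile classes, arbitrary gene lists
against GO/KEGG-style term maps). For a universe of N genes, a term with K
genes and a query set of n genes sharing k, the p-value is
P(X >= k | N, K, n); q-values are Benjamini-Hochberg across the tested
terms. Term maps are used flat — no ontology-graph ancestor propagation.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .expression import bh_adjust


def enrich(gene_set, term_map: dict[str, set], universe,
           alpha: float = 0.05, min_term_size: int = 3) -> pd.DataFrame:
    """Over-representation of each term in ``gene_set``.

    Genes outside the universe are dropped with a warning; terms smaller
    than ``min_term_size`` (after intersection with the universe) are
    skipped. Results are sorted by (q, p) and carry a ``significant``
    column at FDR ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not term_map:
        raise ValueError("empty term map")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe dropped",
                      stacklevel=2)
        gene_set &= universe

    big_n, n = len(universe), len(gene_set)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & universe
        big_k = len(term_genes)
        if big_k < min_term_size:
            continue
        k = len(term_genes & gene_set)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term_id": term, "k": k, "K": big_k, "n": n, "N": big_n,
                     "pvalue": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term_id", "k", "K", "n", "N",
                                     "pvalue", "qvalue", "significant"])
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < alpha
    return df.sort_values(["qvalue", "pvalue"], kind="stable").reset_index(drop=True)


def read_term_map(path) -> dict[str, set]:
    """Read a 2-column TSV (term_id, gene_id) into a term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", names=["term_id", "gene_id"], dtype=str,
                     header=None, skiprows=_has_header(path))
    out: dict[str, set] = {}
    for term, gid in zip(df["term_id"], df["gene_id"]):
        out.setdefault(term, set()).add(gid)
    return out


def _has_header(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("term_id\t") else 0
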