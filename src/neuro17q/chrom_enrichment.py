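"""Per-chromosome hypergeometric enrichment of a gene list.

Tests whether a gene list (e.g. MNA-selective essential genes) is
over-represented on particular chromosomes relative to the autosomal
protein-coding annotation. For each chromosome with n protein-coding genes,
k of which are in the list, the p-value is the upper tail
P(X >= k) of a hypergeometric(N, K, n) draw, where N is the total
protein-coding gene count and K the total list size over the included
chromosomes. Tail probabilities are accumulated in log space; chromosome-17
enrichment of neuroblastoma essential genes reaches magnitudes around 1e-22.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneAnnotation

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: Published per-chromosome protein-coding gene counts and MNA-selective
#: neuroblastoma essential gene counts (autosomes). Used as the reference
#: input for reproducing the chromosome-distribution test of the
#: neuroblastoma essential-gene screen; population and success totals are
#: the column sums (19,046 genes, 175 hits).
NEUROBLASTOMA_ESSENTIAL_COUNTS = pd.DataFrame(
    {
        "chromosome": [f"chr{i}" for i in range(1, 23)],
        "n_genes": [2048, 1247, 1075, 751, 886, 1047, 917, 683, 781, 731,
                    1311, 1035, 321, 612, 599, 853, 1188, 268, 1471, 546,
                    232, 444],
        "n_hits": [22, 17, 4, 5, 4, 6, 4, 3, 5, 4, 6, 10, 3, 0, 7, 5, 52,
                   3, 9, 2, 0, 4],
    }
)


class EnrichmentError(ValueError):
    """Inconsistent enrichment counts."""


def hypergeom_upper_tail(N: int, K: int, n: int, k: int,
                         inclusive: bool = True) -> float:
    """Over-representation p-value P(X >= k) (or P(X > k) if not inclusive).

    X ~ hypergeometric(population N, successes K, draws n). Computed via the
    log survival function for numerical safety in far tails.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}")
    if k > K:
        raise EnrichmentError(f"observed hits k={k} exceed total hits K={K}")
    threshold = k - 1 if inclusive else k
    if threshold < 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(threshold, N, K, n)))


def enrichment_from_counts(counts: pd.DataFrame,
                           inclusive: bool = True) -> pd.DataFrame:
    """Enrichment rows from a pre-counted (chromosome, n_genes, n_hits) table.

    Population N and success total K are the column sums; percentages are
    100 * k / K per chromosome.
    """
    required = {"chromosome", "n_genes", "n_hits"}
    if not required <= set(counts.columns):
        raise EnrichmentError(f"counts table needs columns {sorted(required)}")
    if (counts["n_hits"] > counts["n_genes"]).any():
        raise EnrichmentError("n_hits exceeds n_genes on some chromosome")
    N = int(counts["n_genes"].sum())
    K = int(counts["n_hits"].sum())
    if K == 0:
        raise EnrichmentError("no hits: nothing to test")
    out = counts[["chromosome", "n_genes", "n_hits"]].copy()
    out["pct_distribution"] = 100.0 * out["n_hits"] / K
    out["p_value"] = [
        hypergeom_upper_tail(N, K, int(n), int(k), inclusive=inclusive)
        for n, k in zip(out["n_genes"], out["n_hits"])
    ]
    return out.reset_index(drop=True)


def per_chromosome_enrichment(hits, annotation: GeneAnnotation,
                              biotype_filter: str | None = "protein_coding",
                              chromosomes=AUTOSOMES,
                              inclusive: bool = True) -> pd.DataFrame:
    """Per-chromosome enrichment of ``hits`` against a gene annotation.

    The population is the annotation restricted to ``biotype_filter`` and
    ``chromosomes`` (autosomes by default); hit genes outside that universe
    are logged and dropped.
    """
    sub = annotation.subset(
        biotype=biotype_filter,
        chromosomes=chromosomes if chromosomes is not None else None)
    universe = set(sub.df["gene_id"])
    hits = set(hits)
    dropped = hits - universe
    if dropped:
        logger.warning("%d hit genes outside the filtered annotation dropped",
                       len(dropped))
    hits &= universe
    by_chrom = sub.df.groupby("chromosome")["gene_id"]
    order = [c for c in (chromosomes or by_chrom.groups) if c in by_chrom.groups]
    counts = pd.DataFrame({
        "chromosome": order,
        "n_genes": [by_chrom.get_group(c).size for c in order],
        "n_hits": [sum(g in hits for g in by_chrom.get_group(c))
                   for c in order],
    })
    return enrichment_from_counts(counts, inclusive=inclusive)
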